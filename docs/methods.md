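# Methods

## Model and sampling scheme

The package simulates single-lineage protein-domain evolution by Gibbs
sampling from a Potts model. A sequence `a` of length `N` over `q = 21`
states (20 amino acids plus the gap character `-`, treated as an ordinary
state with no special semantics) has unnormalised log probability

    E(a) = Σ_{i<j} J_ij(a_i, a_j) + Σ_i h_i(a_i).

One **generation** is one attempted substitution: a site is drawn
uniformly, and its residue is redrawn from the single-site conditional,
which is proportional to `exp(h_s(a) + Σ_{j≠s} J_sj(a, a_j))` under the
coupled regime (CE), to `exp(h_s(a))` under the independent regime (IE),
and uniform under the neutral null (UE). A generation is *not* a sweep of
N attempts; quantities per site are obtained by dividing generations by
N. The proposal may equal the current residue; such generations count as
tested-but-unsubstituted, which is why the UE acceptance rate is 20/21
rather than 1.

The conditional is evaluated in log space with max-subtraction before
exponentiation; couplings and fields are never clipped. The coupling
tensor is stored fully symmetric (`J_ij(a,b) = J_ji(b,a)`, zero diagonal
blocks), symmetrised at load time with a warning when the input's
asymmetry exceeds 1e-8. The Hamiltonian sums pairs `i<j` once; the
conditional sums all partners `j ≠ s`.

## Random-number construction

Each replicate derives two named streams from
`SeedSequence([master_seed, replicate_id, stream_id])`:

* stream 0 — **site selection**, drawn once per replicate and shared by
  all three regimes, so the tested-position series is identical across
  CE, IE and UE in every generation;
* stream 1 — **residue sampling**. Each regime gets its own generator
  seeded identically, and every regime consumes exactly one uniform per
  generation through inverse-CDF sampling of its conditional. Regimes
  whose conditionals coincide (e.g. CE with all parameters zero vs UE)
  therefore produce bit-identical traces, and the UE draw is routed
  through the same softmax/scan arithmetic as CE/IE (with zero logits) to
  keep that identity exact at the floating-point level.

Per-replicate seeds are derived independently of execution order, so
results are invariant to parallelisation or reordering of replicates.

## Simulation protocol

Default configuration: 500 replicates × 30,000 generations with the
first 5,000 discarded as burn-in (run under each regime's own dynamics;
the UE burn-in fully randomises the sequence, which is the intended null
behaviour). The sequence at the end of burn-in is the **reference
sequence**; every later generation records the tested site, the prior and
proposed residues, and the acceptance flag (acceptance ⇔ proposed ≠
prior). Replaying accepted proposals onto the reference reproduces the
final state exactly, which the test suite asserts. The hot loop is a
numba-compiled kernel (~2M generations/s on one core); tests and examples
use scaled-down runs (N≈25–60, 10–500 replicates, 400–30,000 tracked
generations) chosen so each check retains clear statistical margins.

## Invariant-site statistics

A site is invariant at tracked generation `g` if no substitution was
*accepted* at it in generations 1..g; a site that substitutes away and
back to the reference residue is not invariant. `I_adj` additionally
requires the site to have been tested at least once, removing sites that
only look invariant because the sampler never visited them. Both counts
are computed exactly per replicate from first-test/first-accept
generations, then aggregated as mean and SD across replicates.

The excess over the neutral null decomposes as combined `ɛ = CE − UE`,
local `ℓ = IE − UE`, and epistasis-only `ε = ɛ − ℓ` (an identity, checked
exactly), with the epistatic share `ε/ɛ` reported only where `ɛ > 0` and
flagged NaN otherwise. Excess *fractions* are taken relative to sequence
length N. The decomposition is evaluated on three grids: per generation;
at matched time (generation = round(t·N) for t generations/site, an error
if beyond the tracked window); and at matched divergence, where for each
replicate and regime the first generation with cumulative accepted
substitutions ≥ d·N is located without interpolation (counts are
integers, so no interpolation rule is imposed). A replicate in which any
regime never reaches d is excluded from that grid point and counted;
headline statistics default to `I_adj`, with `I_all` always reported
alongside.

## Rates and selection decomposition

The evolutionary rate of a regime is accepted substitutions per tracked
generation, averaged across replicates (±SD). *Allowed divergence* is the
ratio of a constrained regime's mean rate to the UE mean rate — a ratio
of means, not a mean of ratios, so a single quoted ratio corresponds to
the two quoted rates. Its complement is the purged fraction, which
decomposes exactly: `purged_CE − purged_IE` is the selection due solely
to pairwise epistasis, and its share of `purged_CE` is reported (NaN when
no selection is present).

Per-site rates are acceptance probabilities per test, computed as pooled
accepts/tests per site across replicates — the algebraic simplification
of the interval ratio (mean generations between tests over mean
generations between accepted substitutions). The explicit interval
computation is retained as a cross-check method (`method="intervals"`,
pooling spacings across replicates before the ratio); the two differ only
through each replicate's censored final interval, and the interval form
is numerically fragile for rarely accepted sites. Sites never accepting a
substitution are flagged and assigned rate 0; never-tested sites are NaN.

## Synthetic models

`generate_potts_model` emulates the structure of coupling/field parameter
sets inferred from real domain alignments: a sparse uniform-random subset
of site pairs (default density 0.1) carries dense Gaussian 21×21 coupling
blocks (default SD 1.0), fields are i.i.d. Gaussian (default SD 1.0), and
N defaults to 60 — sized so a full matched CE/IE/UE replicate set runs in
seconds while clearly exhibiting the coupled-evolution signatures (excess
I-sites under CE, reduced allowed divergence, inflated per-site rate
variance). What the generator does **not** emulate: the block structure
of real couplings is not low-rank or contact-map-like, fields are not
matched to residue usage of any family, and no gap-run structure exists —
so passing tests demonstrate correctness of the machinery and the
qualitative mechanism, not quantitative agreement with any particular
domain family.

The native starting sequence is a local maximum of the log weight found
by single-site greedy ascent from a random start (sweep order randomised
by seed; ties keep the current residue, and among strictly better states
the lowest index wins). An exact ground state is deliberately not sought:
it is intractable at realistic N, and real native sequences are not
ground states of their fitted models either.

## Parameter file handling

MATLAB parameter files are read via scipy.io (classic dialect) or h5py
(v7.3/HDF5 dialect). Because the internal axis order of such files is a
file-dialect fact, the loader identifies the two state axes by their size
(q = 21) and normalises to `(N, N, q, q)` and `(N, q)`; numeric native
sequences with values in 1..21 are converted from MATLAB's 1-based state
indices. The package's own container is HDF5 with an embedded JSON header
(format version, dimensions, alphabet). Synthetic models use the fixed
state order `ACDEFGHIKLMNPQRSTVWY-` (gap last).

## Statistical choices in the test suite

Monte-Carlo assertions use 3 standard errors (binomial or empirical
across replicates) on seeded runs. Goodness-of-fit of the coupled chain
against the exactly enumerated Boltzmann distribution is tested by
chi-square on a 10^6-step run *thinned to every 2N-th state*: successive
Gibbs states are strongly autocorrelated, and a chi-square test on raw
steps would not have its nominal distribution. Curve-level checks
(e.g. the closed-form UE decay `E[I_all(g)] = N(1−(20/21)/N)^g`) are
asserted at a spread of representative generations rather than pointwise
over thousands of highly correlated points. Qualitative orderings
(CE > IE > UE I-sites; allowed divergence CE < IE < 100%) are asserted on
window means over 1–4 generations/site.

## Known limitations

* Single lineage only — no phylogeny, no branching, no among-lineage
  comparisons; no nucleotide or codon layer beneath the amino-acid states.
* Parameters are inputs; the package does not infer Potts models from
  alignments (no DCA/plmDCA), and the Frobenius coupling map is a
  visualisation summary, not a contact predictor.
* The fitness interpretation of the Hamiltonian is a modelling premise;
  nothing here validates it against experimental fitness data.
* Divergence matching uses first-crossing generations, which biases the
  matched generation slightly late for coarse grids on short sequences.
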