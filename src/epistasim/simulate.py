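"""Stepwise Gibbs-sampling sequence evolution with matched randomness.

One *generation* is one attempted substitution: a site is drawn uniformly
at random, and its residue is redrawn from the single-site Gibbs
conditional of the active regime (CE / IE / UE).  The proposal may equal
the current residue, in which case the generation counts as tested but
unsubstituted.  A run executes ``burn_in`` generations to reach steady
state, snapshots the *reference sequence*, and then records every tracked
generation (site tested, residue before, residue proposed, accepted flag).

Matched replicates share one site-selection random stream across the
three regimes — the construction that guarantees the same positions are
tested in the same generations under CE, IE and UE — while each regime
consumes exactly one residue-stream uniform per generation (inverse-CDF
sampling), so zero-parameter regimes collapse onto UE bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .potts import EvolutionMode, PottsModel, conditional_distribution

__all__ = [
    "SimulationConfig",
    "EvolutionTrace",
    "MatchedReplicate",
    "step",
    "run_replicate",
    "run_matched_replicates",
]

_MODE_CODE = {EvolutionMode.CE: 0, EvolutionMode.IE: 1, EvolutionMode.UE: 2}
# streams within a replicate: 0 = site selection (shared), 1 = residue
# sampling (same seed across modes, one fresh generator per mode, so that
# regimes with identical conditionals produce bit-identical traces)
_SITE_STREAM_ID = 0
_RESIDUE_STREAM_ID = 1


@dataclass(frozen=True)
class SimulationConfig:
    """Replicate count, chain length and burn-in (defaults: 500 x 30,000/5,000)."""

    total_generations: int = 30_000
    burn_in: int = 5_000
    n_replicates: int = 500
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.total_generations:
            raise ValueError("require 0 <= burn_in < total_generations")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @property
    def tracked_generations(self) -> int:
        return self.total_generations - self.burn_in


@dataclass
class EvolutionTrace:
    """Per-generation record of one replicate under one regime.

    Arrays cover tracked generations 1..G (post burn-in).  ``accepted`` is
    True exactly when the proposed residue differs from the prior one;
    replaying accepted proposals onto ``reference_sequence`` reproduces
    ``final_sequence``.
    """

    mode: EvolutionMode
    n_sites: int
    reference_sequence: np.ndarray
    sites: np.ndarray
    residues_before: np.ndarray
    residues_proposed: np.ndarray
    accepted: np.ndarray
    final_sequence: np.ndarray
    replicate_id: int = 0

    @property
    def n_tracked(self) -> int:
        return len(self.sites)

    def replay(self) -> np.ndarray:
        """Reconstruct the final sequence from the reference + accepted events."""
        seq = self.reference_sequence.copy()
        for g in np.flatnonzero(self.accepted):
            seq[self.sites[g]] = self.residues_proposed[g]
        return seq


@dataclass
class MatchedReplicate:
    """CE/IE/UE trace triple sharing one site-selection stream."""

    replicate_id: int
    traces: dict[EvolutionMode, EvolutionTrace] = field(default_factory=dict)

    def __getitem__(self, mode: EvolutionMode) -> EvolutionTrace:
        return self.traces[mode]


@njit(cache=True)
def _evolve(coupl_t, fields, seq, sites, uniforms, mode_code, burn_in,
            ref_seq, rec_before, rec_proposed, rec_accepted):
    """Run the full chain in place.

    coupl_t is the coupling tensor with swapped state axes,
    coupl_t[i, j, b, a] = J_ij(a, b), so the partner contribution
    coupl_t[site, j, seq[j], :] is a contiguous length-q slice.
    """
    n = fields.shape[0]
    q = fields.shape[1]
    total = sites.shape[0]
    logits = np.empty(q)
    weights = np.empty(q)
    for g in range(total):
        s = sites[g]
        if mode_code == 2:  # UE: uniform conditional
            for a in range(q):
                logits[a] = 0.0
        else:
            for a in range(q):
                logits[a] = fields[s, a]
            if mode_code == 0:  # CE: add coupling context
                for j in range(n):
                    if j != s:
                        row = coupl_t[s, j, seq[j]]
                        for a in range(q):
                            logits[a] += row[a]
        m = logits[0]
        for a in range(1, q):
            if logits[a] > m:
                m = logits[a]
        tot = 0.0
        for a in range(q):
            weights[a] = np.exp(logits[a] - m)
            tot += weights[a]
        u = uniforms[g] * tot
        acc = 0.0
        k = q - 1
        for a in range(q):
            acc += weights[a]
            if u < acc:
                k = a
                break
        prev = seq[s]
        seq[s] = k
        if g >= burn_in:
            t = g - burn_in
            rec_before[t] = prev
            rec_proposed[t] = k
            rec_accepted[t] = prev != k
        if g == burn_in - 1:
            for i in range(n):
                ref_seq[i] = seq[i]


def _transposed_couplings(model: PottsModel) -> np.ndarray:
    return np.ascontiguousarray(model.couplings.transpose(0, 1, 3, 2))


def step(
    seq: np.ndarray,
    model: PottsModel,
    mode: EvolutionMode,
    site_rng: np.random.Generator,
    residue_rng: np.random.Generator,
) -> tuple[np.ndarray, dict]:
    """Advance one generation; returns the new sequence and the event record.

    The site is drawn uniformly from the site stream; the replacement is
    drawn from the regime's single-site conditional by inverse-CDF using a
    single uniform from the residue stream.
    """
    seq = np.asarray(seq, dtype=np.int8).copy()
    site = int(site_rng.integers(0, model.n_sites))
    u = float(residue_rng.random())
    probs = conditional_distribution(seq, site, model, mode)
    k = int(min(np.searchsorted(np.cumsum(probs), u, side="right"), model.n_states - 1))
    record = {
        "site": site,
        "residue_before": int(seq[site]),
        "residue_proposed": k,
        "accepted": k != int(seq[site]),
    }
    seq[site] = k
    return seq, record


def run_replicate(
    model: PottsModel,
    start_seq: np.ndarray,
    config: SimulationConfig,
    mode: EvolutionMode,
    site_stream: np.random.Generator,
    residue_stream: np.random.Generator,
    replicate_id: int = 0,
    sites: np.ndarray | None = None,
) -> EvolutionTrace:
    """Run one replicate chain and return its trace.

    ``sites`` may be passed pre-drawn (shared across regimes for matched
    replicates); otherwise it is drawn from ``site_stream``.
    """
    start_seq = np.asarray(start_seq, dtype=np.int8)
    if start_seq.shape != (model.n_sites,):
        raise ValueError("start sequence length does not match model")
    total, burn = config.total_generations, config.burn_in
    if sites is None:
        sites = site_stream.integers(0, model.n_sites, size=total, dtype=np.int64)
    uniforms = residue_stream.random(total)
    seq = start_seq.copy()
    ref = start_seq.copy()  # burn_in == 0 -> reference is the start sequence
    g_track = total - burn
    rec_before = np.empty(g_track, dtype=np.int8)
    rec_proposed = np.empty(g_track, dtype=np.int8)
    rec_accepted = np.empty(g_track, dtype=np.bool_)
    _evolve(
        _transposed_couplings(model), model.fields, seq, sites, uniforms,
        _MODE_CODE[mode], burn, ref, rec_before, rec_proposed, rec_accepted,
    )
    return EvolutionTrace(
        mode=mode,
        n_sites=model.n_sites,
        reference_sequence=ref,
        sites=sites[burn:].astype(np.int32),
        residues_before=rec_before,
        residues_proposed=rec_proposed,
        accepted=rec_accepted,
        final_sequence=seq,
        replicate_id=replicate_id,
    )


def _streams_for(master_seed: int, replicate_id: int, modes):
    site = np.random.default_rng(
        np.random.SeedSequence([master_seed, replicate_id, _SITE_STREAM_ID])
    )
    residues = {
        mode: np.random.default_rng(
            np.random.SeedSequence([master_seed, replicate_id, _RESIDUE_STREAM_ID])
        )
        for mode in modes
    }
    return site, residues


def run_matched_replicates(
    model: PottsModel,
    start_seq: np.ndarray,
    config: SimulationConfig,
    modes: tuple[EvolutionMode, ...] = (EvolutionMode.CE, EvolutionMode.IE, EvolutionMode.UE),
) -> list[MatchedReplicate]:
    """Run all replicates of the CE/IE/UE triple with matched site streams.

    Per replicate, one site-selection stream (seeded from
    (master_seed, replicate_id)) is drawn once and shared by every regime,
    so the tested-position series is identical across CE, IE and UE.  The
    residue streams are likewise synchronized (same seed, one generator
    per regime): every regime consumes exactly one uniform per generation
    through the inverse CDF, so nested regimes with identical conditional
    distributions yield bit-identical traces.  Replicate seeds are derived
    independently, so results do not depend on execution order.
    """
    nested = {mode: model.nested(mode) for mode in modes}
    out = []
    for rid in range(config.n_replicates):
        site_stream, residue_streams = _streams_for(config.master_seed, rid, modes)
        sites = site_stream.integers(0, model.n_sites, size=config.total_generations, dtype=np.int64)
        rep = MatchedReplicate(replicate_id=rid)
        for mode in modes:
            rep.traces[mode] = run_replicate(
                nested[mode], start_seq, config, mode,
                site_stream, residue_streams[mode],
                replicate_id=rid, sites=sites,
            )
        out.append(rep)
    return out
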