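"""Invariant-site (I-site) statistics and the excess decomposition.

A site is *invariant* at tracked generation g if its residue never changed
from the reference (post burn-in) state during generations 1..g — a site
that substitutes away and later returns to the original residue is NOT
invariant, because it accepted substitutions.  Two counts are tracked:

* ``I_all``:  all invariant sites;
* ``I_adj``:  invariant sites that were additionally *tested* (selected
  for a substitution attempt) at least once — removing sites that only
  look invariant because the sampler never visited them.

Subtracting the strictly neutral UE expectation isolates the selective
component, and the nested regimes decompose it:

* combined effects      eps_combined  = CE - UE,
* local-field effects   ell_local     = IE - UE,
* pairwise epistasis    eps_pairwise  = eps_combined - ell_local,

with the epistatic share reported as eps_pairwise / eps_combined wherever
the combined excess is positive.  The decomposition can be evaluated on a
common time grid (generations/site) or at matched sequence divergence
(substitutions/site), which controls for the different substitution rates
of the three regimes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .potts import EvolutionMode
from .simulate import EvolutionTrace, MatchedReplicate

__all__ = [
    "ISiteCurve",
    "ExcessDecomposition",
    "isite_curve",
    "replicate_isite_counts",
    "excess_decomposition",
    "time_matched_excess",
    "divergence_matched_excess",
]


@dataclass
class ISiteCurve:
    """Per-generation I_all / I_adj counts, aggregated over replicates.

    ``i_all``/``i_adj`` are (n_replicates, G) integer matrices; the mean
    and SD across replicates are exposed as properties.
    """

    mode: EvolutionMode
    n_sites: int
    i_all: np.ndarray
    i_adj: np.ndarray

    @property
    def n_replicates(self) -> int:
        return self.i_all.shape[0]

    @property
    def n_generations(self) -> int:
        return self.i_all.shape[1]

    @property
    def generations(self) -> np.ndarray:
        return np.arange(1, self.n_generations + 1)

    @property
    def mean_all(self) -> np.ndarray:
        return self.i_all.mean(axis=0)

    @property
    def mean_adj(self) -> np.ndarray:
        return self.i_adj.mean(axis=0)

    @property
    def sd_all(self) -> np.ndarray:
        return self.i_all.std(axis=0, ddof=1) if self.n_replicates > 1 else np.zeros(self.n_generations)

    @property
    def sd_adj(self) -> np.ndarray:
        return self.i_adj.std(axis=0, ddof=1) if self.n_replicates > 1 else np.zeros(self.n_generations)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "generation": self.generations,
                "mode": self.mode.value,
                "i_all_mean": self.mean_all,
                "i_all_sd": self.sd_all,
                "i_adj_mean": self.mean_adj,
                "i_adj_sd": self.sd_adj,
                "n_replicates": self.n_replicates,
            }
        )


def replicate_isite_counts(trace: EvolutionTrace) -> tuple[np.ndarray, np.ndarray]:
    """Exact I_all(g), I_adj(g) count vectors for a single trace.

    Uses first-test and first-accept generations per site:
    I_all(g) = #{sites whose first accepted substitution is after g};
    I_adj(g) = #{tested by g} - #{accepted by g}  (accept implies tested).
    """
    n, g_total = trace.n_sites, trace.n_tracked
    sites = trace.sites
    gens = np.arange(1, g_total + 1)

    def first_event(mask: np.ndarray) -> np.ndarray:
        first = np.full(n, g_total + 1, dtype=np.int64)
        idx = np.flatnonzero(mask)
        # reversed so earlier generations overwrite later ones
        first[sites[idx[::-1]]] = gens[idx[::-1]]
        return first

    first_test = first_event(np.ones(g_total, dtype=bool))
    first_accept = first_event(np.asarray(trace.accepted, dtype=bool))

    def cum_counts(first: np.ndarray) -> np.ndarray:
        # number of sites with first event <= g, for g = 1..G
        counts = np.bincount(first[first <= g_total], minlength=g_total + 1)
        return np.cumsum(counts)[1:]

    tested_by = cum_counts(first_test)
    accepted_by = cum_counts(first_accept)
    i_all = n - accepted_by
    i_adj = tested_by - accepted_by
    return i_all, i_adj


def isite_curve(traces: list[EvolutionTrace], n_sites: int | None = None) -> ISiteCurve:
    """Aggregate per-replicate I-site counts into a curve for one regime."""
    if not traces:
        raise ValueError("need at least one trace")
    n = traces[0].n_sites if n_sites is None else n_sites
    g = traces[0].n_tracked
    for t in traces:
        if t.n_tracked != g or t.n_sites != n:
            raise ValueError("traces differ in length or number of sites")
    i_all = np.empty((len(traces), g), dtype=np.int64)
    i_adj = np.empty((len(traces), g), dtype=np.int64)
    for r, t in enumerate(traces):
        i_all[r], i_adj[r] = replicate_isite_counts(t)
    return ISiteCurve(mode=traces[0].mode, n_sites=n, i_all=i_all, i_adj=i_adj)


@dataclass
class ExcessDecomposition:
    """Excess I-sites over the UE null, split into combined/local/epistatic.

    All component arrays are site *counts* on the evaluation ``grid``
    (generations, generations/site, or substitutions/site depending on the
    producing function); ``n_sites`` converts them to fractions.  Arrays
    come in an I_all-based and an I_adj-based variant; the epistatic share
    ``ratio_*`` is NaN wherever the combined excess is not positive.
    """

    grid: np.ndarray
    grid_kind: str  # "generation" | "generations_per_site" | "substitutions_per_site"
    n_sites: int
    eps_combined_all: np.ndarray
    ell_local_all: np.ndarray
    eps_combined_adj: np.ndarray
    ell_local_adj: np.ndarray
    n_replicates: int
    n_excluded: np.ndarray | None = None

    @property
    def eps_pairwise_all(self) -> np.ndarray:
        return self.eps_combined_all - self.ell_local_all

    @property
    def eps_pairwise_adj(self) -> np.ndarray:
        return self.eps_combined_adj - self.ell_local_adj

    @staticmethod
    def _ratio(pairwise: np.ndarray, combined: np.ndarray) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(combined > 0, pairwise / combined, np.nan)

    @property
    def ratio_all(self) -> np.ndarray:
        return self._ratio(self.eps_pairwise_all, self.eps_combined_all)

    @property
    def ratio_adj(self) -> np.ndarray:
        return self._ratio(self.eps_pairwise_adj, self.eps_combined_adj)

    def fraction(self, component: np.ndarray) -> np.ndarray:
        """Convert a site-count component to a fraction of sequence length."""
        return component / self.n_sites

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                self.grid_kind: self.grid,
                "eps_combined_all": self.eps_combined_all,
                "ell_local_all": self.ell_local_all,
                "eps_pairwise_all": self.eps_pairwise_all,
                "ratio_all": self.ratio_all,
                "eps_combined_adj": self.eps_combined_adj,
                "ell_local_adj": self.ell_local_adj,
                "eps_pairwise_adj": self.eps_pairwise_adj,
                "ratio_adj": self.ratio_adj,
                "n_replicates": self.n_replicates,
            }
        )


def excess_decomposition(
    ce: ISiteCurve, ie: ISiteCurve, ue: ISiteCurve
) -> ExcessDecomposition:
    """Per-generation decomposition of mean excess I-sites over the UE null."""
    if not (ce.n_generations == ie.n_generations == ue.n_generations):
        raise ValueError("curves are not on an identical generation grid")
    if not (ce.n_sites == ie.n_sites == ue.n_sites):
        raise ValueError("curves come from models of different lengths")
    return ExcessDecomposition(
        grid=ce.generations,
        grid_kind="generation",
        n_sites=ce.n_sites,
        eps_combined_all=ce.mean_all - ue.mean_all,
        ell_local_all=ie.mean_all - ue.mean_all,
        eps_combined_adj=ce.mean_adj - ue.mean_adj,
        ell_local_adj=ie.mean_adj - ue.mean_adj,
        n_replicates=min(ce.n_replicates, ie.n_replicates, ue.n_replicates),
    )


def _curves_by_mode(matched: list[MatchedReplicate]) -> dict[EvolutionMode, ISiteCurve]:
    modes = list(matched[0].traces)
    return {m: isite_curve([rep[m] for rep in matched]) for m in modes}


def time_matched_excess(
    matched: list[MatchedReplicate], time_grid: np.ndarray
) -> ExcessDecomposition:
    """Excess decomposition at fixed evolutionary times (generations/site).

    Each grid value t is mapped to tracked generation round(t * N); raises
    if that exceeds the tracked window.
    """
    curves = _curves_by_mode(matched)
    ce, ie, ue = (curves[m] for m in (EvolutionMode.CE, EvolutionMode.IE, EvolutionMode.UE))
    n = ce.n_sites
    time_grid = np.asarray(time_grid, dtype=float)
    gens = np.rint(time_grid * n).astype(np.int64)
    if gens.max(initial=0) > ce.n_generations:
        raise ValueError(
            f"time grid requires generation {gens.max()} but only "
            f"{ce.n_generations} are tracked"
        )
    full = excess_decomposition(ce, ie, ue)
    idx = gens - 1  # generation g lives at array index g-1
    at = lambda arr: np.where(gens > 0, arr[np.clip(idx, 0, None)], 0.0)
    return ExcessDecomposition(
        grid=time_grid,
        grid_kind="generations_per_site",
        n_sites=n,
        eps_combined_all=at(full.eps_combined_all),
        ell_local_all=at(full.ell_local_all),
        eps_combined_adj=at(full.eps_combined_adj),
        ell_local_adj=at(full.ell_local_adj),
        n_replicates=full.n_replicates,
    )


def divergence_matched_excess(
    matched: list[MatchedReplicate], divergence_grid: np.ndarray
) -> ExcessDecomposition:
    """Excess decomposition at matched sequence divergence (substitutions/site).

    For each replicate and regime, the first tracked generation at which
    cumulative accepted substitutions / N reaches the grid value d is
    located (no interpolation) and the I-site counts are read there.  A
    replicate in which any regime never reaches d is excluded from that
    grid point (and counted in ``n_excluded``); if no replicate reaches d
    a ValueError naming d is raised.
    """
    modes = (EvolutionMode.CE, EvolutionMode.IE, EvolutionMode.UE)
    n = matched[0][modes[0]].n_sites
    divergence_grid = np.asarray(divergence_grid, dtype=float)
    n_grid = len(divergence_grid)

    # per replicate+mode: I-count vectors and cumulative accepted counts
    sums_all = {m: np.zeros(n_grid) for m in modes}
    sums_adj = {m: np.zeros(n_grid) for m in modes}
    n_used = np.zeros(n_grid, dtype=np.int64)
    n_excluded = np.zeros(n_grid, dtype=np.int64)

    for rep in matched:
        counts = {}
        reach_gen = {}
        for m in modes:
            tr = rep[m]
            i_all, i_adj = replicate_isite_counts(tr)
            cum = np.cumsum(tr.accepted.astype(np.int64))
            # first index with cum >= d*n  ->  tracked generation idx+1
            idx = np.searchsorted(cum, divergence_grid * n, side="left")
            counts[m] = (i_all, i_adj)
            reach_gen[m] = idx  # == len(cum) when never reached
        g_len = len(rep[modes[0]].accepted)
        ok = np.ones(n_grid, dtype=bool)
        for m in modes:
            ok &= reach_gen[m] < g_len
        n_used += ok
        n_excluded += ~ok
        for m in modes:
            i_all, i_adj = counts[m]
            gi = reach_gen[m][ok]
            np.add.at(sums_all[m], np.flatnonzero(ok), i_all[gi])
            np.add.at(sums_adj[m], np.flatnonzero(ok), i_adj[gi])

    if (n_used == 0).any():
        bad = divergence_grid[n_used == 0]
        raise ValueError(f"no replicate reaches divergence {bad.tolist()} in every regime")

    mean_all = {m: sums_all[m] / n_used for m in modes}
    mean_adj = {m: sums_adj[m] / n_used for m in modes}
    ce, ie, ue = modes
    return ExcessDecomposition(
        grid=divergence_grid,
        grid_kind="substitutions_per_site",
        n_sites=n,
        eps_combined_all=mean_all[ce] - mean_all[ue],
        ell_local_all=mean_all[ie] - mean_all[ue],
        eps_combined_adj=mean_adj[ce] - mean_adj[ue],
        ell_local_adj=mean_adj[ie] - mean_adj[ue],
        n_replicates=len(matched),
        n_excluded=n_excluded,
    )
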