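"""Evolutionary rates, allowed divergence and the purifying-selection split.

The evolutionary rate of a regime is the number of accepted substitutions
per generation over the tracked (post burn-in) window.  Because each
generation proposes one replacement from 21 equally likely characters,
the strictly neutral UE null accepts 20/21 ≈ 0.952 substitutions per
generation regardless of the model.  *Allowed divergence* is the rate of
a constrained regime relative to that null (CE/UE or IE/UE, in percent);
its complement is the fraction of replacement mutations purged by
purifying selection.  Purged fractions decompose exactly like the I-site
excess: combined (CE) minus local (IE) leaves the share of selection due
solely to pairwise epistasis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .potts import EvolutionMode
from .simulate import EvolutionTrace, MatchedReplicate

__all__ = [
    "RateEstimate",
    "RateSummary",
    "PerSiteRateProfile",
    "evolutionary_rate",
    "allowed_divergence",
    "selection_decomposition",
    "summarize_rates",
    "per_site_rates",
]


@dataclass(frozen=True)
class RateEstimate:
    """Substitutions per generation: mean and SD across replicates."""

    mean: float
    sd: float
    n_replicates: int


def evolutionary_rate(traces: list[EvolutionTrace]) -> RateEstimate:
    """Accepted substitutions per tracked generation, averaged over replicates."""
    if not traces:
        raise ValueError("need at least one trace")
    per_rep = []
    for t in traces:
        if t.n_tracked == 0:
            raise ValueError("empty trace (no tracked generations)")
        per_rep.append(t.accepted.mean())
    per_rep = np.asarray(per_rep)
    sd = float(per_rep.std(ddof=1)) if len(per_rep) > 1 else 0.0
    return RateEstimate(mean=float(per_rep.mean()), sd=sd, n_replicates=len(per_rep))


def allowed_divergence(rate_model: float, rate_ue: float) -> float:
    """Rate ratio constrained/null as a percentage; complement = purged %."""
    if rate_ue <= 0:
        raise ValueError("UE rate must be positive")
    return 100.0 * rate_model / rate_ue


def selection_decomposition(
    allowed_ce: float, allowed_ie: float
) -> tuple[float, float, float, float]:
    """Split total purged percentage into local and epistasis-only parts.

    Returns (purged_combined, purged_local, purged_epistasis, epistatic
    share); e.g. allowed 71.7% / 90.8% -> (28.3, 9.2, 19.1, 0.675).  The
    share is NaN when the combined purged fraction is not positive.
    """
    purged_combined = 100.0 - allowed_ce
    purged_local = 100.0 - allowed_ie
    purged_epistasis = purged_combined - purged_local
    share = purged_epistasis / purged_combined if purged_combined > 0 else float("nan")
    return purged_combined, purged_local, purged_epistasis, share


@dataclass
class RateSummary:
    """Per-regime rates plus the allowed-divergence selection decomposition.

    Ratios are taken between the replicate-mean rates (ratio of means,
    not mean of ratios).
    """

    rates: dict[EvolutionMode, RateEstimate]
    allowed: dict[EvolutionMode, float]
    purged_combined: float
    purged_local: float
    purged_epistasis: float
    epistatic_share: float

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for mode, est in self.rates.items():
            rows.append(
                {
                    "mode": mode.value,
                    "rate_mean": est.mean,
                    "rate_sd": est.sd,
                    "allowed_divergence_pct": self.allowed[mode],
                    "purged_pct": 100.0 - self.allowed[mode],
                    "n_replicates": est.n_replicates,
                }
            )
        return pd.DataFrame(rows)


def summarize_rates(matched: list[MatchedReplicate]) -> RateSummary:
    """Full rate summary from matched CE/IE/UE replicates."""
    modes = (EvolutionMode.CE, EvolutionMode.IE, EvolutionMode.UE)
    rates = {m: evolutionary_rate([rep[m] for rep in matched]) for m in modes}
    ue = rates[EvolutionMode.UE].mean
    allowed = {m: allowed_divergence(rates[m].mean, ue) for m in modes}
    pc, pl, pe, share = selection_decomposition(
        allowed[EvolutionMode.CE], allowed[EvolutionMode.IE]
    )
    return RateSummary(
        rates=rates,
        allowed=allowed,
        purged_combined=pc,
        purged_local=pl,
        purged_epistasis=pe,
        epistatic_share=share,
    )


@dataclass
class PerSiteRateProfile:
    """Per-site substitution rate: acceptance probability per test.

    ``rate`` equals accepts/tests per site (events pooled across
    replicates), the algebraic simplification of the interval ratio
    (mean generations between tests) / (mean generations between accepted
    substitutions).  Sites never accepting a substitution get rate 0 and
    are flagged in ``never_accepted``; sites never tested are NaN and
    flagged in ``never_tested``.
    """

    mode: EvolutionMode
    tests: np.ndarray
    accepts: np.ndarray
    rate: np.ndarray
    never_tested: np.ndarray
    never_accepted: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site": np.arange(len(self.rate)),
                "tests": self.tests,
                "accepts": self.accepts,
                "rate": self.rate,
                "never_tested": self.never_tested,
                "never_accepted": self.never_accepted,
            }
        )


def per_site_rates(
    traces: list[EvolutionTrace], method: str = "counts"
) -> PerSiteRateProfile:
    """Per-site substitution rates for one regime, pooled across replicates.

    ``method="counts"`` (default) computes pooled accepts/tests.
    ``method="intervals"`` computes the interval ratio explicitly — mean
    spacing between tests divided by mean spacing between accepted
    substitutions within each replicate, pooled across replicates before
    the ratio — as a cross-check; the two differ only through the censored
    final interval of each replicate.
    """
    if not traces:
        raise ValueError("need at least one trace")
    n = traces[0].n_sites
    tests = np.zeros(n, dtype=np.int64)
    accepts = np.zeros(n, dtype=np.int64)
    for t in traces:
        tests += np.bincount(t.sites, minlength=n)
        accepts += np.bincount(t.sites[t.accepted], minlength=n)
    never_tested = tests == 0
    never_accepted = (accepts == 0) & ~never_tested

    if method == "counts":
        with np.errstate(invalid="ignore", divide="ignore"):
            rate = np.where(tests > 0, accepts / np.maximum(tests, 1), np.nan)
    elif method == "intervals":
        # explicit spacings between consecutive events within each replicate,
        # pooled across replicates before the ratio; the final (censored)
        # interval of each replicate is dropped, which is where this method
        # departs from plain accepts/tests
        test_sum = np.zeros(n)
        test_n = np.zeros(n, dtype=np.int64)
        acc_sum = np.zeros(n)
        acc_n = np.zeros(n, dtype=np.int64)
        for t in traces:
            gens = np.arange(1, t.n_tracked + 1)
            for sums, counts, mask in (
                (test_sum, test_n, slice(None)),
                (acc_sum, acc_n, t.accepted),
            ):
                ev_sites = t.sites[mask]
                ev_gens = gens[mask]
                order = np.argsort(ev_sites, kind="stable")
                s_sorted, g_sorted = ev_sites[order], ev_gens[order]
                same = s_sorted[1:] == s_sorted[:-1]
                np.add.at(sums, s_sorted[1:][same], (g_sorted[1:] - g_sorted[:-1])[same])
                np.add.at(counts, s_sorted[1:][same], 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_test = np.where(test_n > 0, test_sum / np.maximum(test_n, 1), np.nan)
            mean_acc = np.where(acc_n > 0, acc_sum / np.maximum(acc_n, 1), np.inf)
            rate = mean_test / mean_acc
        rate = np.where(acc_n == 0, 0.0, rate)
        rate = np.where(test_n == 0, np.nan, rate)
    else:
        raise ValueError(f"unknown method {method!r}")
    rate = np.where(never_accepted, 0.0, rate)
    return PerSiteRateProfile(
        mode=traces[0].mode,
        tests=tests,
        accepts=accepts,
        rate=rate,
        never_tested=never_tested,
        never_accepted=never_accepted,
    )
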