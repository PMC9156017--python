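"""Invariant-site curves and the combined/local/epistatic decomposition."""

import numpy as np
import pytest

from epistasim import (
    EvolutionMode,
    EvolutionTrace,
    ISiteCurve,
    SimulationConfig,
    divergence_matched_excess,
    excess_decomposition,
    isite_curve,
    replicate_isite_counts,
    run_matched_replicates,
    run_replicate,
    time_matched_excess,
)
from epistasim.potts import Alphabet, PottsModel

CE, IE, UE = EvolutionMode.CE, EvolutionMode.IE, EvolutionMode.UE


def make_trace(n_sites, events, mode=UE):
    """Build a trace from (site, before, proposed) tuples; accepted inferred."""
    sites = np.array([e[0] for e in events], dtype=np.int32)
    before = np.array([e[1] for e in events], dtype=np.int8)
    proposed = np.array([e[2] for e in events], dtype=np.int8)
    ref = np.zeros(n_sites, dtype=np.int8)
    trace = EvolutionTrace(
        mode=mode, n_sites=n_sites, reference_sequence=ref,
        sites=sites, residues_before=before, residues_proposed=proposed,
        accepted=before != proposed, final_sequence=ref,
    )
    trace.final_sequence = trace.replay()
    return trace


def isite_scan_oracle(trace):
    """Direct O(N*G) per-site re-scan of the invariance definitions."""
    n, g_total = trace.n_sites, trace.n_tracked
    i_all = np.zeros(g_total, dtype=int)
    i_adj = np.zeros(g_total, dtype=int)
    for g in range(1, g_total + 1):
        for site in range(n):
            window = slice(0, g)
            mask = trace.sites[window] == site
            ever_accepted = bool(trace.accepted[window][mask].any())
            ever_tested = bool(mask.any())
            if not ever_accepted:
                i_all[g - 1] += 1
                if ever_tested:
                    i_adj[g - 1] += 1
    return i_all, i_adj


class TestISiteCounts:
    def test_hand_checked_three_site_example(self):
        # gen1: site0 accepts; gen2: site1 rejects; gen3: site0 accepts back
        trace = make_trace(3, [(0, 0, 1), (1, 0, 0), (0, 1, 0)])
        i_all, i_adj = replicate_isite_counts(trace)
        assert i_all.tolist() == [2, 2, 2]
        assert i_adj.tolist() == [0, 1, 1]

    def test_no_accepted_events(self):
        trace = make_trace(4, [(0, 0, 0), (2, 0, 0), (0, 0, 0)])
        i_all, i_adj = replicate_isite_counts(trace)
        assert i_all.tolist() == [4, 4, 4]
        assert i_adj.tolist() == [1, 2, 2]  # distinct tested sites so far

    def test_back_substitution_is_not_invariant(self):
        trace = make_trace(2, [(0, 0, 1), (0, 1, 0)])
        i_all, _ = replicate_isite_counts(trace)
        # site 0 returned to its original residue but accepted substitutions
        assert i_all.tolist() == [1, 1]

    def test_matches_direct_scan_oracle_on_random_trace(self, small_synthetic):
        config = SimulationConfig(total_generations=400, burn_in=100, n_replicates=1, master_seed=0)
        rngs = (np.random.default_rng(1), np.random.default_rng(2))
        trace = run_replicate(small_synthetic, small_synthetic.native_sequence, config, UE, *rngs)
        i_all, i_adj = replicate_isite_counts(trace)
        o_all, o_adj = isite_scan_oracle(trace)
        assert np.array_equal(i_all, o_all)
        assert np.array_equal(i_adj, o_adj)

    def test_curve_monotonicity_and_bounds(self, small_synthetic, short_config):
        matched = run_matched_replicates(small_synthetic, small_synthetic.native_sequence, short_config)
        for mode in (CE, IE, UE):
            curve = isite_curve([rep[mode] for rep in matched])
            assert (np.diff(curve.i_all, axis=1) <= 0).all()
            assert (curve.i_adj <= curve.i_all).all()
            assert (curve.i_all >= 0).all() and (curve.i_all <= curve.n_sites).all()
            # once every site has been tested, the two counts coincide
            assert curve.i_adj[:, -1].tolist() == curve.i_all[:, -1].tolist()

    def test_ue_expected_decay_curve(self):
        """Under UE, E[I_all(g)] = N (1 - (1/N)(20/21))^g."""
        n, reps, gens = 20, 500, 500
        q = 21
        model = PottsModel.from_arrays(
            np.zeros((n, n, q, q)), np.zeros((n, q)), Alphabet.generic(q),
            native_sequence=np.zeros(n, dtype=np.int8),
        )
        config = SimulationConfig(total_generations=gens, burn_in=0,
                                  n_replicates=reps, master_seed=17)
        matched = run_matched_replicates(model, model.native_sequence, config, modes=(UE,))
        curve = isite_curve([rep[UE] for rep in matched])
        g = np.arange(1, gens + 1)
        expected = n * (1 - (1 / n) * (20 / 21)) ** g
        se = curve.sd_all / np.sqrt(reps)
        # I_all is a path statistic, so neighbouring generations are highly
        # correlated; check a spread of representative generations, with the
        # independent-sites binomial SE as a floor where the empirical SD
        # degenerates to zero
        surv = (1 - (1 / n) * (20 / 21)) ** g
        se_floor = np.sqrt(n * surv * (1 - surv) / reps)
        for gen in (10, 25, 50, 100, 250, 500):
            k = gen - 1
            assert abs(curve.mean_all[k] - expected[k]) < 3 * max(se[k], se_floor[k])

    def test_trace_length_mismatch_rejected(self):
        t1 = make_trace(3, [(0, 0, 1)])
        t2 = make_trace(3, [(0, 0, 1), (1, 0, 1)])
        with pytest.raises(ValueError):
            isite_curve([t1, t2])


def _fixed_curve(mode, n_sites, all_counts, adj_counts):
    arr_all = np.asarray([all_counts], dtype=np.int64)
    arr_adj = np.asarray([adj_counts], dtype=np.int64)
    return ISiteCurve(mode=mode, n_sites=n_sites, i_all=arr_all, i_adj=arr_adj)


class TestDecomposition:
    def test_identical_curves_give_zero_and_flagged_ratio(self):
        c = _fixed_curve(CE, 10, [5, 4], [3, 3])
        dec = excess_decomposition(c, _fixed_curve(IE, 10, [5, 4], [3, 3]),
                                   _fixed_curve(UE, 10, [5, 4], [3, 3]))
        assert not dec.eps_combined_all.any() and not dec.ell_local_all.any()
        assert np.isnan(dec.ratio_all).all()

    def test_component_arithmetic(self):
        ce = _fixed_curve(CE, 100, [50], [40])
        ie = _fixed_curve(IE, 100, [43], [33])
        ue = _fixed_curve(UE, 100, [40], [30])
        dec = excess_decomposition(ce, ie, ue)
        assert dec.eps_combined_all[0] == 10
        assert dec.ell_local_all[0] == 3
        assert dec.eps_pairwise_all[0] == 7
        assert dec.ratio_all[0] == pytest.approx(0.7)
        assert dec.fraction(dec.eps_combined_all)[0] == pytest.approx(0.1)

    def test_identity_epsilon_equals_combined_minus_local(self, small_synthetic, short_config):
        matched = run_matched_replicates(small_synthetic, small_synthetic.native_sequence, short_config)
        curves = {m: isite_curve([rep[m] for rep in matched]) for m in (CE, IE, UE)}
        dec = excess_decomposition(curves[CE], curves[IE], curves[UE])
        assert np.array_equal(dec.eps_pairwise_all, dec.eps_combined_all - dec.ell_local_all)
        assert np.array_equal(dec.eps_pairwise_adj, dec.eps_combined_adj - dec.ell_local_adj)

    def test_strong_coupling_ordering(self, strong_coupling_model):
        """CE must hold more I-sites than IE than UE at intermediate times."""
        model = strong_coupling_model
        config = SimulationConfig(total_generations=1500, burn_in=300,
                                  n_replicates=30, master_seed=8)
        matched = run_matched_replicates(model, model.native_sequence, config)
        curves = {m: isite_curve([rep[m] for rep in matched]) for m in (CE, IE, UE)}
        mid = slice(model.n_sites, 4 * model.n_sites)  # 1-4 generations/site
        assert curves[CE].mean_all[mid].mean() > curves[IE].mean_all[mid].mean()
        assert curves[IE].mean_all[mid].mean() > curves[UE].mean_all[mid].mean()
        assert curves[CE].mean_adj[mid].mean() > curves[IE].mean_adj[mid].mean()
        dec = excess_decomposition(curves[CE], curves[IE], curves[UE])
        assert dec.eps_combined_adj[mid].mean() > dec.ell_local_adj[mid].mean() > 0

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            excess_decomposition(_fixed_curve(CE, 5, [3, 2], [1, 1]),
                                 _fixed_curve(IE, 5, [3], [1]),
                                 _fixed_curve(UE, 5, [3, 2], [1, 1]))


@pytest.fixture(scope="module")
def matched(small_synthetic):
    config = SimulationConfig(total_generations=1200, burn_in=200,
                              n_replicates=10, master_seed=12)
    return run_matched_replicates(small_synthetic, small_synthetic.native_sequence, config)


class TestMatchedGrids:

    def test_time_grid_is_indexing_into_generation_curve(self, matched, small_synthetic):
        n = small_synthetic.n_sites
        grid = np.array([1.0, 2.0, 3.0])
        tm = time_matched_excess(matched, grid)
        curves = {m: isite_curve([rep[m] for rep in matched]) for m in (CE, IE, UE)}
        full = excess_decomposition(curves[CE], curves[IE], curves[UE])
        for k, t in enumerate(grid):
            g = round(t * n)
            assert tm.eps_combined_all[k] == full.eps_combined_all[g - 1]
            assert tm.ell_local_adj[k] == full.ell_local_adj[g - 1]

    def test_time_zero_gives_zero_excess(self, matched):
        tm = time_matched_excess(matched, np.array([0.0]))
        assert tm.eps_combined_all[0] == 0.0 and tm.ell_local_all[0] == 0.0

    def test_time_grid_beyond_tracked_window_rejected(self, matched):
        with pytest.raises(ValueError):
            time_matched_excess(matched, np.array([1e6]))

    def test_divergence_definition_on_ue(self, matched, small_synthetic):
        """d=1.0 maps to the first generation with >= N accepted events."""
        n = small_synthetic.n_sites
        tr = matched[0][UE]
        cum = np.cumsum(tr.accepted)
        expected_gen = int(np.searchsorted(cum, n) + 1)
        assert cum[expected_gen - 1] >= n and cum[expected_gen - 2] < n

    def test_zero_parameter_model_zero_divergence_matched_excess(self):
        q = 21
        n = 12
        model = PottsModel.from_arrays(np.zeros((n, n, q, q)), np.zeros((n, q)),
                                       Alphabet.generic(q), np.zeros(n, dtype=np.int8))
        config = SimulationConfig(total_generations=800, burn_in=100,
                                  n_replicates=4, master_seed=3)
        matched = run_matched_replicates(model, model.native_sequence, config)
        dec = divergence_matched_excess(matched, np.array([1.0, 2.0]))
        assert not dec.eps_combined_all.any()
        assert not dec.ell_local_adj.any()

    def test_unreachable_divergence_raises_naming_value(self, matched):
        with pytest.raises(ValueError, match="999"):
            divergence_matched_excess(matched, np.array([999.0]))

    def test_divergence_matched_epistatic_share_positive(self, strong_coupling_model):
        model = strong_coupling_model
        config = SimulationConfig(total_generations=2500, burn_in=300,
                                  n_replicates=30, master_seed=4)
        matched = run_matched_replicates(model, model.native_sequence, config)
        dec = divergence_matched_excess(matched, np.array([1.0, 2.0, 3.0]))
        assert (dec.ratio_adj > 0).all()
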