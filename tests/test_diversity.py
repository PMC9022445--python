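from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from pamkit.diversity import (IncidenceMatrix, accumulation_curves, chao2,
                              design_surface, extend_occasions,
                              incidence_from_counts, rarefaction_curve,
                              rarefaction_expected)
from pamkit.ingest import CountMatrix, Recording


def _inc(rows, locations=None, species=None):
    rows = np.asarray(rows)
    n, s = rows.shape
    locations = locations or ["L1"] * n
    idx = pd.MultiIndex.from_tuples(
        [(loc, f"o{i}") for i, loc in enumerate(locations)],
        names=["location", "occasion"],
    )
    cols = species or [f"sp{j}" for j in range(s)]
    return IncidenceMatrix(pd.DataFrame(rows, index=idx, columns=cols))


def brute_force_rarefaction(inc: IncidenceMatrix, t: int) -> float:
    """Oracle: average richness over all C(T, t) sample subsets."""
    data = inc.data.to_numpy(bool)
    total, count = 0.0, 0
    for subset in combinations(range(data.shape[0]), t):
        total += data[list(subset)].any(axis=0).sum()
        count += 1
    return total / count


class TestIncidenceFromCounts:
    def test_binarization_and_q(self, toy_count_matrix, toy_recordings):
        inc = incidence_from_counts(toy_count_matrix, toy_recordings,
                                    exclude_taxa=())
        assert inc.T == 4
        assert set(np.unique(inc.data)) <= {0, 1}
        # Q_i equals the number of recordings with positive count
        assert inc.Q["AAA"] == 3
        assert inc.Q["CCC"] == 3

    def test_mammals_excluded_by_default(self, toy_count_matrix, toy_recordings):
        inc = incidence_from_counts(toy_count_matrix, toy_recordings)
        assert "CCC" not in inc.data.columns

    def test_matches_generator_occupancy(self, default_sim):
        inc = incidence_from_counts(default_sim.count_matrix, default_sim.recordings)
        cm = default_sim.count_matrix
        for sp in inc.data.columns:
            assert inc.Q[sp] == int((cm.counts[sp] > 0).sum())


class TestRarefaction:
    def test_t_equal_T_gives_observed(self):
        inc = _inc([[1, 0], [1, 1], [0, 1]])
        assert rarefaction_expected(inc, 3) == pytest.approx(2.0)

    def test_small_worked_example(self):
        # T=3, species A in all 3 samples, B in 1: E[S_1] = 2 - C(2,1)/C(3,1) = 4/3
        inc = _inc([[1, 1], [1, 0], [1, 0]])
        assert rarefaction_expected(inc, 1) == pytest.approx(4 / 3)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_subsets(self, seed):
        rng = np.random.default_rng(seed)
        T, S = rng.integers(3, 8), rng.integers(2, 10)
        inc = _inc(rng.random((T, S)) < 0.4)
        for t in range(1, T + 1):
            assert rarefaction_expected(inc, t) == pytest.approx(
                brute_force_rarefaction(inc, t), abs=1e-10
            )

    def test_out_of_range_rejected(self):
        inc = _inc([[1, 0], [0, 1]])
        with pytest.raises(ValueError):
            rarefaction_expected(inc, 0)
        with pytest.raises(ValueError):
            rarefaction_expected(inc, 3)

    def test_curve_nondecreasing(self):
        rng = np.random.default_rng(3)
        inc = _inc(rng.random((12, 8)) < 0.3)
        curve = rarefaction_curve(inc)
        assert (np.diff(curve.to_numpy()) >= -1e-12).all()


class TestChao2:
    def test_no_uniques_returns_observed(self):
        inc = _inc([[1, 1], [1, 1], [0, 1]])  # Q = (2, 3): no singletons
        assert chao2(inc).estimate == pytest.approx(2.0)

    def test_formula_arithmetic(self):
        # S_obs = 10, T = 19, Q1 = 3, Q2 = 2 -> 10 + (18/19) * 9/4
        rows = np.zeros((19, 10), dtype=int)
        rows[:, 0:3] = np.eye(19, 3, dtype=int)          # three uniques
        rows[0:2, 3] = 1
        rows[2:4, 4] = 1                                  # two duplicates
        rows[:, 5:] = 1                                   # five everywhere
        est = chao2(_inc(rows))
        assert (est.q1, est.q2, est.s_obs) == (3, 2, 10)
        assert est.estimate == pytest.approx(10 + (18 / 19) * 9 / 4, abs=1e-9)
        assert est.se > 0

    def test_never_below_observed(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            inc = _inc(rng.random((8, 12)) < 0.3)
            assert chao2(inc).estimate >= inc.s_obs - 1e-12


class TestAccumulationCurves:
    def test_single_location_curves_coincide(self):
        rng = np.random.default_rng(5)
        inc = _inc(rng.random((6, 5)) < 0.5)
        curves = accumulation_curves(inc)
        np.testing.assert_allclose(curves["pooled"], curves["single_location_mean"])

    def test_pooling_beats_single_location_with_beta_diversity(self):
        # two locations with disjoint species pools
        rows = [[1, 1, 0, 0], [1, 0, 0, 0], [0, 0, 1, 1], [0, 0, 1, 0]]
        inc = _inc(rows, locations=["L1", "L1", "L2", "L2"])
        curves = accumulation_curves(inc).dropna()
        assert (curves["pooled"] >= curves["single_location_mean"] - 1e-12).all()
        assert curves["pooled"].iloc[-1] > curves["single_location_mean"].iloc[-1]

    def test_both_curves_nondecreasing(self):
        rng = np.random.default_rng(6)
        inc = _inc(rng.random((10, 6)) < 0.4,
                   locations=["L1"] * 5 + ["L2"] * 5)
        curves = accumulation_curves(inc)
        for col in curves:
            vals = curves[col].dropna().to_numpy()
            assert (np.diff(vals) >= -1e-12).all()


class TestExtendOccasions:
    def test_single_occasion_repeats(self):
        inc = _inc([[1, 0, 1]])
        ext = extend_occasions(inc, 190, seed=0)
        assert ext.T == 190
        assert (ext.data.to_numpy() == [1, 0, 1]).all()

    def test_closure_no_new_species_per_location(self):
        rows = [[1, 1, 0], [1, 0, 0], [0, 0, 1]]
        inc = _inc(rows, locations=["L1", "L1", "L2"])
        ext = extend_occasions(inc, 50, seed=1)
        l2 = ext.data.xs("L2", level="location")
        assert (l2[["sp0", "sp1"]].to_numpy() == 0).all()

    def test_frequency_preserved_within_binomial_error(self):
        rng = np.random.default_rng(7)
        rows = rng.random((20, 5)) < 0.5
        inc = _inc(rows)
        target = 1000
        ext = extend_occasions(inc, target, seed=2)
        obs_freq = inc.Q / inc.T
        ext_freq = ext.Q / ext.T
        bound = 3 * np.sqrt(obs_freq * (1 - obs_freq) / target) + 0.02
        assert (np.abs(ext_freq - obs_freq) <= bound).all()

    def test_truncation_unsupported(self):
        inc = _inc([[1], [1], [0]])
        with pytest.raises(ValueError, match="truncation"):
            extend_occasions(inc, 2, seed=0)


class TestDesignSurface:
    def _two_pool_inc(self):
        rows = [[1, 1, 0, 0], [1, 0, 0, 0], [0, 0, 1, 1], [0, 0, 0, 1]]
        return _inc(rows, locations=["L1", "L1", "L2", "L2"])

    def test_full_design_hits_total_richness(self):
        inc = self._two_pool_inc()
        surf = design_surface(inc, n_rep=20, seed=0).surface
        full = surf[(surf["n_locations"] == 2) & (surf["n_occasions"] == 2)]
        assert full["mean_richness"].iloc[0] == pytest.approx(4.0)
        assert full["se"].iloc[0] == 0.0

    def test_single_sample_cell_matches_exhaustive_mean(self):
        inc = self._two_pool_inc()
        exhaustive = inc.data.sum(axis=1).mean()  # mean richness of one row
        surf = design_surface(inc, n_rep=4000, seed=1).surface
        cell = surf[(surf["n_locations"] == 1) & (surf["n_occasions"] == 1)]
        assert cell["mean_richness"].iloc[0] == pytest.approx(exhaustive, abs=0.1)

    def test_monotone_in_both_arguments(self):
        rng = np.random.default_rng(8)
        rows = rng.random((30, 12)) < 0.25
        inc = _inc(rows, locations=[f"L{i % 5}" for i in range(30)])
        surf = design_surface(inc, n_rep=300, seed=2).surface
        wide = surf.pivot(index="n_locations", columns="n_occasions",
                          values="mean_richness")
        se = surf.pivot(index="n_locations", columns="n_occasions", values="se")
        tol = 2 * se.to_numpy()
        assert (np.diff(wide.to_numpy(), axis=0) >= -(tol[1:] + tol[:-1])).all()
        assert (np.diff(wide.to_numpy(), axis=1) >= -(tol[:, 1:] + tol[:, :-1])).all()

    def test_reproducible_bit_for_bit(self):
        inc = self._two_pool_inc()
        s1 = design_surface(inc, n_rep=50, seed=3).surface
        s2 = design_surface(inc, n_rep=50, seed=3).surface
        pd.testing.assert_frame_equal(s1, s2)

    def test_oversized_grid_rejected(self):
        inc = self._two_pool_inc()
        with pytest.raises(ValueError):
            design_surface(inc, n_rep=5, seed=0, locations_grid=[3])

    def test_disjoint_pools_reward_locations_at_fixed_budget(self):
        # 4 locations with disjoint pools: at budget 4, spreading across
        # locations detects strictly more species than deep sampling of one
        rng = np.random.default_rng(9)
        rows = np.zeros((16, 12), dtype=int)
        for loc in range(4):
            rows[4 * loc:4 * loc + 4, 3 * loc:3 * loc + 3] = (
                rng.random((4, 3)) < 0.7
            )
        inc = _inc(rows, locations=[f"L{i // 4}" for i in range(16)])
        surf = design_surface(inc, n_rep=400, seed=4,
                              locations_grid=[1, 2, 4],
                              occasions_grid=[1, 2, 4]).surface
        frontier = surf[surf["n_locations"] * surf["n_occasions"] == 4]
        frontier = frontier.sort_values("n_locations")
        vals = frontier["mean_richness"].to_numpy()
        assert (np.diff(vals) > 0).all()
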