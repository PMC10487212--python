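"""Wavelength selection: availability filter, RReliefF, pruning, CFS."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from chemmap import selection as sel
from chemmap import synthetic as syn


def naive_rrelieff(X, y, k=10, sigma=20.0):
    """Straightforward loop reimplementation used as an independent oracle."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, d = X.shape
    fr = X.max(0) - X.min(0)
    Xn = np.where(fr > 0, (X - X.min(0)) / np.where(fr > 0, fr, 1), 0.0)
    yn = (y - y.min()) / (y.max() - y.min())
    rank_w = np.exp(-((np.arange(1, k + 1) / sigma) ** 2))
    rank_w /= rank_w.sum()
    n_dc, n_da, n_dcda = 0.0, np.zeros(d), np.zeros(d)
    for i in range(n):
        dist = np.array([np.abs(Xn[i] - Xn[j]).sum() if j != i else np.inf
                         for j in range(n)])
        nbr = np.argsort(dist, kind="stable")[:k]
        for rank, j in enumerate(nbr):
            w = rank_w[rank]
            dy = abs(yn[i] - yn[j])
            df = np.abs(Xn[i] - Xn[j])
            n_dc += dy * w
            n_da += df * w
            n_dcda += dy * df * w
    return n_dcda / n_dc - (n_da - n_dcda) / (n - n_dc)


class TestFilterAvailable:
    grid = syn.WAVELENGTH_GRID

    def test_all_true_table_is_identity(self):
        avail = syn.generate_availability_table("dense")
        cand = sel.filter_available(self.grid, avail, "filter")
        assert len(cand.wavelengths) == 237
        np.testing.assert_array_equal(cand.wavelengths, self.grid)

    def test_led_only_wavelength_excluded_for_filter_modality(self):
        avail = syn.generate_availability_table("dense")
        avail.loc[avail.wavelength == 495, "available_filter"] = False
        cand = sel.filter_available(self.grid, avail, "filter")
        assert 495.0 not in cand.wavelengths
        cand_ls = sel.filter_available(self.grid, avail, "light_source")
        assert 495.0 in cand_ls.wavelengths

    def test_light_source_is_union_of_led_and_laser(self):
        avail = syn.generate_availability_table("sparse", seed=3)
        cand = sel.filter_available(self.grid, avail, "light_source")
        union = avail.available_led | avail.available_laser
        np.testing.assert_array_equal(
            cand.wavelengths, avail.wavelength.to_numpy(float)[union])

    def test_empty_candidate_set_raises(self):
        avail = syn.generate_availability_table("dense")
        avail["available_filter"] = False
        with pytest.raises(ValueError, match="available"):
            sel.filter_available(self.grid, avail, "filter")


class TestRReliefF:
    def test_matches_naive_reimplementation(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, (60, 5))
        y = X[:, 2] + 0.3 * rng.normal(0, 1, 60)
        np.testing.assert_allclose(sel.rrelieff_weights(X, y),
                                   naive_rrelieff(X, y), atol=1e-9)

    def test_copy_of_target_ranked_first_among_noise(self):
        rng = np.random.default_rng(1)
        y = rng.normal(0, 1, 200)
        X = np.column_stack([y] + [rng.normal(0, 1, 200) for _ in range(9)])
        w = sel.rrelieff_weights(X, y)
        assert int(np.argmax(w)) == 0

    def test_constant_feature_has_zero_weight(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (80, 4))
        X[:, 1] = 7.0
        w = sel.rrelieff_weights(X, X[:, 0])
        assert abs(w[1]) < 1e-12

    def test_sample_order_invariance_with_all_instances(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (100, 6))
        y = X @ rng.normal(0, 1, 6)
        perm = rng.permutation(100)
        np.testing.assert_allclose(sel.rrelieff_weights(X, y),
                                   sel.rrelieff_weights(X[perm], y[perm]), atol=1e-12)

    def test_constant_target_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            sel.rrelieff_weights(np.random.default_rng(0).normal(0, 1, (30, 3)),
                                 np.ones(30))


class TestPruneCorrelated:
    def _correlated_triplet(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, 500)
        b = 0.9 * a + np.sqrt(1 - 0.81) * rng.normal(0, 1, 500)
        c = 0.3 * a + np.sqrt(1 - 0.09) * rng.normal(0, 1, 500)
        return np.column_stack([a, b, c])

    def test_hand_trace_drops_second_keeps_third(self):
        X = self._correlated_triplet()
        assert sel.prune_correlated([0, 1, 2], X) == [0, 2]

    def test_all_uncorrelated_kept(self):
        X = np.random.default_rng(6).normal(0, 1, (300, 4))
        assert sel.prune_correlated([2, 0, 3, 1], X) == [2, 0, 3, 1]

    def test_identical_wavelengths_fully_pruned(self):
        a = np.random.default_rng(7).normal(0, 1, 100)
        X = np.tile(a[:, None], (1, 20))
        assert sel.prune_correlated(list(range(20)), X) == [0]

    def test_output_independent_of_candidates_below_top_n(self):
        rng = np.random.default_rng(8)
        X = rng.normal(0, 1, (200, 30))
        ranked = list(range(30))
        full = sel.prune_correlated(ranked, X, top_n=20)
        shuffled_tail = ranked[:20] + ranked[29:19:-1]
        assert sel.prune_correlated(shuffled_tail, X, top_n=20) == full

    def test_max_keep_truncates_to_six(self):
        X = np.random.default_rng(9).normal(0, 1, (300, 10))
        assert len(sel.prune_correlated(list(range(10)), X, max_keep=6)) == 6


class TestCfsMerit:
    def test_singleton_merit_is_abs_target_correlation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 200)
        y = -0.6 * x + 0.8 * rng.normal(0, 1, 200)
        r = abs(np.corrcoef(x, y)[0, 1])
        assert sel.cfs_merit([0], x[:, None], y) == pytest.approx(r, abs=1e-12)

    def test_identical_features_merit_equals_r(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 150)
        y = 0.7 * a + 0.5 * rng.normal(0, 1, 150)
        X = np.tile(a[:, None], (1, 4))
        r = abs(np.corrcoef(a, y)[0, 1])
        assert sel.cfs_merit([0, 1, 2, 3], X, y) == pytest.approx(r, abs=1e-10)

    def test_three_feature_case_matches_direct_formula(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (120, 3))
        y = X @ [0.5, -0.2, 0.1] + rng.normal(0, 1, 120)
        r_cf = np.mean([abs(np.corrcoef(X[:, i], y)[0, 1]) for i in range(3)])
        r_ff = np.mean([abs(np.corrcoef(X[:, i], X[:, j])[0, 1])
                        for i, j in combinations(range(3), 2)])
        expected = 3 * r_cf / np.sqrt(3 + 3 * 2 * r_ff)
        assert sel.cfs_merit([0, 1, 2], X, y) == pytest.approx(expected, abs=1e-10)

    def test_zero_variance_feature_warns(self):
        X = np.ones((50, 2))
        X[:, 0] = np.random.default_rng(3).normal(0, 1, 50)
        with pytest.warns(UserWarning, match="zero-variance"):
            sel.cfs_merit([0, 1], X, X[:, 0])


class TestBestFirst:
    def test_matches_exhaustive_on_small_candidate_sets(self):
        for seed in range(30):
            rng = np.random.default_rng(seed)
            d = int(rng.integers(5, 11))
            X = rng.normal(0, 1, (50, d))
            k = int(rng.integers(1, 4))
            idx = rng.choice(d, k, replace=False)
            y = X[:, idx] @ rng.normal(1, 0.5, k) + rng.normal(0, 1, 50)
            corr = sel._CfsCorrelations(X, y)
            found = corr.merit(sel.bestfirst_search(range(d), X, y, corr=corr))
            best = max(corr.merit(s) for r in range(1, d + 1)
                       for s in combinations(range(d), r))
            assert found == pytest.approx(best, abs=1e-10)

    def test_informative_singleton_beats_noise(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 300)
        X = np.column_stack([x] + [rng.normal(0, 1, 300) for _ in range(9)])
        y = x + 0.2 * rng.normal(0, 1, 300)
        assert sel.bestfirst_search(range(10), X, y) == [0]

    def test_duplicate_informative_feature_does_not_improve_merit(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 300)
        X = np.column_stack([x] + [rng.normal(0, 1, 300) for _ in range(5)])
        y = x + 0.2 * rng.normal(0, 1, 300)
        Xdup = np.column_stack([X, x])
        base = sel.cfs_merit(sel.bestfirst_search(range(6), X, y), X, y)
        withdup = sel.cfs_merit(sel.bestfirst_search(range(7), Xdup, y), Xdup, y)
        assert withdup == pytest.approx(base, abs=1e-10)


class TestEnumerateSixMember:
    def test_small_subset_passthrough(self):
        X = np.random.default_rng(0).normal(0, 1, (50, 8))
        y = X[:, 0]
        assert sel.enumerate_six_member([1, 3, 5, 7], X, y) == [1, 3, 5, 7]

    def test_seven_member_subset_reduced_to_best_six(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (100, 7))
        y = X @ rng.normal(0, 1, 7) + rng.normal(0, 1, 100)
        corr = sel._CfsCorrelations(X, y)
        result = sel.enumerate_six_member(list(range(7)), X, y)
        assert len(result) == 6
        merits = {s: corr.merit(s) for s in combinations(range(7), 6)}
        assert len(merits) == 7
        assert corr.merit(result) == pytest.approx(max(merits.values()), abs=1e-12)


class TestSelectWavelengths:
    def test_results_report_wavelengths_and_correlations(self):
        rng = np.random.default_rng(0)
        grid = syn.WAVELENGTH_GRID
        X = rng.normal(0.5, 0.01, (150, len(grid)))
        y = 10 * X[:, 15] + rng.normal(0, 0.02, 150)
        avail = syn.generate_availability_table("dense")
        res = sel.select_wavelengths(X, y, grid, avail, "filter",
                                     method="subset_selection")
        assert res.wavelengths_nm and len(res.wavelengths_nm) <= 6
        assert grid[15] in res.wavelengths_nm
        i = res.wavelengths_nm.index(grid[15])
        assert abs(res.per_wavelength_r[i]) > 0.9
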