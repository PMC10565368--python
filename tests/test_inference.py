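"""OLS/AICc selection, Moran's I, and the paired Wilcoxon against oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import antseasons as ans


def wilcoxon_enumeration_p(d: np.ndarray) -> float:
    """Exact two-sided signed-rank p by enumerating all 2^n sign patterns."""
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    sums = np.array(
        [ranks[np.array(signs, dtype=bool)].sum()
         for signs in itertools.product((0, 1), repeat=len(d))]
    )
    p_le = np.mean(sums <= w_obs)
    p_ge = np.mean(sums >= w_obs)
    return min(1.0, 2 * min(p_le, p_ge))


def _scores_frame(n, rng):
    return pd.DataFrame({"PC1": rng.normal(0, 1, n), "PC2": rng.normal(0, 1, n)})


class TestAicc:
    def test_correction_arithmetic(self):
        # k=3, n=24: correction = 2*3*4/20 = 1.2
        assert ans.aicc(0.0, 24, 3) == pytest.approx(6.0 + 1.2)

    def test_reduces_to_aic_with_n(self):
        vals = [ans.aicc(0.0, n, 3) for n in (10, 30, 100, 1000, 100000)]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert vals[-1] == pytest.approx(6.0, abs=1e-3)

    def test_undefined_when_saturated(self):
        with pytest.raises(ValueError):
            ans.aicc(0.0, 4, 3)


class TestModelSelection:
    def test_perfect_pc1_signal(self, rng):
        scores = _scores_frame(24, rng)
        y = 2.0 + 3.0 * scores["PC1"]
        res = ans.fit_ols_aicc(y, scores, response="demo")
        assert res.selected == ("PC1",)
        assert res.r_squared == pytest.approx(1.0)

    def test_pure_noise_prefers_intercept(self):
        wins = 0
        n_sim = 300
        for seed in range(n_sim):
            r = np.random.default_rng(seed)
            scores = _scores_frame(24, r)
            res = ans.fit_ols_aicc(r.normal(0, 1, 24), scores)
            wins += res.selected == ()
        assert wins > n_sim / 2

    def test_all_candidates_reported(self, rng):
        scores = _scores_frame(24, rng)
        res = ans.fit_ols_aicc(rng.normal(0, 1, 24), scores)
        assert set(res.aicc_table.index) == {"intercept", "PC1", "PC2", "PC1+PC2"}
        assert np.isfinite(res.aicc_table).all()

    def test_small_n_rejected(self, rng):
        scores = _scores_frame(5, rng)
        with pytest.raises(ans.ConfigurationError):
            ans.fit_ols_aicc(rng.normal(0, 1, 5), scores)

    def test_constant_response_rejected(self, rng):
        scores = _scores_frame(24, rng)
        with pytest.raises(ValueError):
            ans.fit_ols_aicc(np.full(24, 3.0), scores)


class TestMoransI:
    def test_null_expectation_at_n24(self, rng):
        coords = rng.uniform(0, 1000, (24, 2))
        W = ans.spatial_weights(coords)
        z = rng.normal(0, 1, 24)
        perms = np.array(
            [ans.morans_i(rng.permutation(z), coords, weights=W) for _ in range(2000)]
        )
        e_i = -1 / 23
        se = perms.std(ddof=1) / np.sqrt(len(perms))
        assert abs(perms.mean() - e_i) < 3 * se

    def test_brute_force_on_toy_layout(self):
        coords = np.array([[0, 0], [0, 1], [0, 2], [0, 3], [0, 4]], dtype=float)
        z = coords[:, 1].copy()  # residual = y-coordinate: strong gradient
        W = ans.spatial_weights(coords)
        zc = z - z.mean()
        num = sum(
            W[i, j] * zc[i] * zc[j] for i in range(5) for j in range(5)
        )
        expected = (5 / W.sum()) * num / (zc**2).sum()
        assert ans.morans_i(z, coords) == pytest.approx(expected, abs=1e-12)
        assert expected > 0

    def test_constant_shift_invariance(self, rng):
        coords = rng.uniform(0, 100, (10, 2))
        z = rng.normal(0, 1, 10)
        assert ans.morans_i(z, coords) == pytest.approx(
            ans.morans_i(z + 42.0, coords), abs=1e-12
        )

    def test_duplicate_coordinates_floored(self, rng):
        coords = np.array([[0, 0], [0, 0], [1, 0], [2, 0], [3, 0]], dtype=float)
        z = rng.normal(0, 1, 5)
        assert np.isfinite(ans.morans_i(z, coords))

    def test_zero_variance_error(self, rng):
        coords = rng.uniform(0, 1, (6, 2))
        with pytest.raises(ValueError):
            ans.morans_i(np.ones(6), coords)

    def test_knn_weights_row_standardized(self, rng):
        W = ans.spatial_weights(rng.uniform(0, 1, (8, 2)), scheme="knn", k=3)
        assert np.allclose(W.sum(axis=1), 1.0)
        assert np.allclose(np.diag(W), 0.0)
        assert ((W > 0).sum(axis=1) == 3).all()


class TestMoranPermutation:
    def test_deterministic_under_seed(self, rng):
        coords = rng.uniform(0, 100, (24, 2))
        z = rng.normal(0, 1, 24)
        r1 = ans.morans_i_permutation(z, coords, seed=5)
        r2 = ans.morans_i_permutation(z, coords, seed=5)
        assert r1.p_value == r2.p_value

    def test_detects_strong_gradient(self):
        rng = np.random.default_rng(0)
        coords = np.column_stack([np.zeros(24), np.arange(24.0)])
        z = coords[:, 1] + rng.normal(0, 0.5, 24)
        res = ans.morans_i_permutation(z, coords, seed=1)
        assert res.p_value <= 0.05
        assert res.statistic > res.expected

    def test_min_permutations_enforced(self, rng):
        coords = rng.uniform(0, 1, (10, 2))
        with pytest.raises(ans.ConfigurationError):
            ans.morans_i_permutation(rng.normal(0, 1, 10), coords, n_perm=50)

    def test_p_in_unit_interval(self, rng):
        coords = rng.uniform(0, 1, (12, 2))
        res = ans.morans_i_permutation(rng.normal(0, 1, 12), coords, n_perm=199, seed=2)
        assert 0 < res.p_value <= 1


class TestPairedTests:
    def test_all_positive_differences_exact_p(self):
        x_a = np.array([2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
        x_b = x_a - np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        rep = ans.paired_tests(x_a, x_b)
        assert rep.method == "exact"
        assert rep.wilcoxon_p == pytest.approx(2 / 2**6)

    def test_matches_enumeration(self):
        rng = np.random.default_rng(8)
        for n in range(5, 11):
            d = rng.normal(0.3, 1.0, n)
            rep = ans.paired_tests(d, np.zeros(n))
            assert rep.method == "exact"
            assert rep.wilcoxon_p == pytest.approx(wilcoxon_enumeration_p(d), abs=1e-12)

    def test_mirrored_differences_near_one(self):
        d = np.array([-2.0, -1.0, -0.5, 0.5, 1.0, 2.0])
        rep = ans.paired_tests(d, np.zeros(6))
        assert rep.wilcoxon_p > 0.8

    def test_rank_invariance_to_scaling(self):
        rng = np.random.default_rng(9)
        d = rng.normal(0.2, 1.0, 12)
        r1 = ans.paired_tests(d, np.zeros(12))
        r2 = ans.paired_tests(2 * d, np.zeros(12))
        assert r1.wilcoxon_statistic == r2.wilcoxon_statistic
        assert r1.wilcoxon_p == r2.wilcoxon_p

    def test_normality_flag_from_shapiro(self):
        rng = np.random.default_rng(10)
        rep = ans.paired_tests(rng.normal(0, 1, 30), np.zeros(30))
        assert rep.differences_normal == (rep.shapiro_p > 0.05)

    def test_degenerate_all_zero(self):
        with pytest.raises(ValueError):
            ans.paired_tests(np.ones(6), np.ones(6))
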