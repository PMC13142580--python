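import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from iscn.inference import (
    fdr_bh,
    fit_region_models,
    spatial_correlation_report,
    spin_permute,
    spin_test,
    _random_rotation,
)

from conftest import make_frame


def bh_oracle(p):
    """Literal step-up definition: adj_(i) = min_{j>=i} (m p_(j) / j)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        adj[i] = running
    return adj


class TestFitRegionModels:
    def test_two_group_toy_matches_hand_values(self):
        """(0, 1) vs (2, 3), intercept+dx design: t and d from closed form."""
        Y = np.zeros((4, 68))
        Y[:, 0] = [2, 3, 0, 1]
        df = make_frame(Y, dx=[1, 1, 0, 0])
        # covariate-free comparison via direct two-sample computation
        x, y = Y[:2, 0], Y[2:, 0]
        sp = np.sqrt((x.var(ddof=1) + y.var(ddof=1)) / 2)
        t_hand = (x.mean() - y.mean()) / (sp * np.sqrt(1 / 2 + 1 / 2))
        d_hand = t_hand * 4 / (np.sqrt(4) * np.sqrt(2))
        t_scipy = stats.ttest_ind(x, y).statistic
        assert t_hand == pytest.approx(t_scipy)
        # full model on a big sample agrees with statsmodels OLS per region
        rng = np.random.default_rng(0)
        n = 300
        Y = rng.normal(0, 1, (n, 68))
        df = make_frame(Y, dx=rng.integers(0, 2, n), seed=1)
        res = fit_region_models(Y, df, formula="base")
        X = sm.add_constant(
            np.column_stack(
                [df.age, (df.sex == "M").astype(float), df.dx.astype(float)]
            )
        )
        fit = sm.OLS(Y[:, 5], X).fit()
        assert res.t[5] == pytest.approx(fit.tvalues[3], abs=1e-8)
        assert res.p[5] == pytest.approx(fit.pvalues[3], abs=1e-10)
        n1, n2 = int(df.dx.sum()), int((1 - df.dx).sum())
        d_expect = fit.tvalues[3] * (n1 + n2) / (np.sqrt(n1 * n2) * np.sqrt(n - 4))
        assert res.cohens_d[5] == pytest.approx(d_expect, abs=1e-10)

    def test_null_data_small_d_uniform_p(self):
        rng = np.random.default_rng(2)
        n = 2000
        Y = rng.normal(0, 1, (n, 68))
        df = make_frame(Y, dx=np.r_[np.ones(n // 2, int), np.zeros(n // 2, int)], seed=2)
        res = fit_region_models(Y, df)
        assert np.all(np.abs(res.cohens_d) < 0.2)
        assert stats.kstest(res.p, "uniform").pvalue > 0.01

    def test_planted_shift_recovered(self):
        """0.3 pooled-SD shift in 10 regions estimated within 0.05 at n = 2000/arm."""
        rng = np.random.default_rng(3)
        n = 4000
        Y = rng.normal(0, 1, (n, 68))
        dx = np.r_[np.ones(2000, int), np.zeros(2000, int)]
        Y[:2000, :10] += 0.3
        df = make_frame(Y, dx=dx, seed=3)
        res = fit_region_models(Y, df)
        assert np.mean(res.cohens_d[:10]) == pytest.approx(0.3, abs=0.05)

    def test_duration_model_uses_cases_only(self, small_cohort):
        df, _ = small_cohort
        thk = df[[c for c in df.columns if c.startswith("thk_")]].to_numpy()
        res = fit_region_models(thk, df, formula="duration")
        assert res.n_cases == int((df.dx == 1).sum())
        assert res.n_controls == 0

    def test_rank_deficient_design_errors(self):
        Y = np.random.default_rng(4).normal(0, 1, (50, 68))
        df = make_frame(Y, dx=np.ones(50, int))  # dx constant -> collinear
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_region_models(Y, df)

    def test_sign_consistency_d_and_t(self, small_cohort):
        df, _ = small_cohort
        thk = df[[c for c in df.columns if c.startswith("thk_")]].to_numpy()
        res = fit_region_models(thk, df)
        assert np.all(np.sign(res.cohens_d) == np.sign(res.t))
        assert np.all(res.p_fdr >= res.p - 1e-15)


class TestFdrBH:
    def test_hand_example_m4(self):
        adj = fdr_bh(np.array([0.01, 0.02, 0.03, 0.5]))
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.5])

    def test_all_ones(self):
        assert np.allclose(fdr_bh(np.ones(5)), 1.0)

    def test_single_p_unchanged(self):
        assert fdr_bh(np.array([0.123]))[0] == pytest.approx(0.123)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_stepup_oracle_exactly(self, seed):
        p = np.random.default_rng(seed).uniform(size=np.random.default_rng(seed).integers(2, 21))
        assert np.array_equal(fdr_bh(p), bh_oracle(p))


class TestSpinTest:
    def test_map_against_itself(self, atlas):
        v = np.random.default_rng(5).normal(0, 1, 68)
        res = spin_test(v, v, atlas, n_rot=99, seed=0)
        assert res.observed_r == pytest.approx(1.0)
        assert res.p_spin == pytest.approx(1 / 100)

    def test_null_r_centered_for_unstructured_maps(self, atlas):
        rng = np.random.default_rng(6)
        res = spin_test(rng.normal(0, 1, 68), rng.normal(0, 1, 68), atlas,
                        n_rot=300, seed=1)
        assert abs(res.null_r.mean()) < 0.05

    def test_p_bounds_are_permutation_valid(self, atlas):
        rng = np.random.default_rng(7)
        for seed in range(3):
            res = spin_test(rng.normal(0, 1, 68), rng.normal(0, 1, 68), atlas,
                            n_rot=50, seed=seed)
            assert 1 / 51 <= res.p_spin <= 1.0

    def test_rotation_matrices_are_proper(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            R = _random_rotation(rng)
            assert np.allclose(R @ R.T, np.eye(3), atol=1e-12)
            assert np.linalg.det(R) == pytest.approx(1.0)

    def test_spin_permutation_preserves_hemisphere_values(self, atlas):
        v = np.arange(68, dtype=float)
        rng = np.random.default_rng(9)
        out = spin_permute(v, atlas, _random_rotation(rng))
        # left parcels only receive left values, right only right
        assert set(out[:34]) <= set(v[:34])
        assert set(out[34:]) <= set(v[34:])

    def test_length_mismatch_errors(self, atlas):
        with pytest.raises(ValueError, match="atlas"):
            spin_test(np.zeros(10), np.zeros(10), atlas, n_rot=10)


class TestSpatialCorrelationReport:
    def test_self_and_anticorrelated_pairs(self, atlas):
        v = np.random.default_rng(10).normal(0, 1, 68)
        rep = spatial_correlation_report(
            v, {"self": v, "anti": -v}, atlas, n_rot=50, seed=0
        )
        assert rep.loc["self", "r"] == pytest.approx(1.0)
        assert rep.loc["anti", "r"] == pytest.approx(-1.0)

    def test_r_matches_direct_formula(self, atlas):
        rng = np.random.default_rng(11)
        a, b = rng.normal(0, 1, 68), rng.normal(0, 1, 68)
        rep = spatial_correlation_report(a, {"b": b}, atlas, n_rot=10, seed=0)
        assert rep.loc["b", "r"] == pytest.approx(stats.pearsonr(a, b)[0], abs=1e-12)
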