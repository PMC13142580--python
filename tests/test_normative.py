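import numpy as np
import pandas as pd
import pytest
from scipy import stats

from iscn.atlas import thickness_columns
from iscn.normative import (
    MEAN_COL,
    assign_bin,
    deviation_scores,
    fit_normative,
    heterogeneity,
    predict_interval,
    stratified_compare,
    subtype_profile_compare,
)
from iscn.simulate import SimulationConfig, generate_cohort

THK = thickness_columns()


@pytest.fixture(scope="module")
def fitted():
    cfg = SimulationConfig(
        n_cases=1, n_controls=3000, n_sites=1, seed=5,
        site_shift_sd=0.0, site_scale_sd=0.0,
    )
    df, _ = generate_cohort(cfg)
    ctr = df[df.dx == 0].reset_index(drop=True)
    model = fit_normative(ctr, targets="mean")
    return model, ctr


class TestDeviationAlgebra:
    def test_observation_at_upper_bound_gives_z_plus_two(self, fitted):
        model, ctr = fitted
        sub = ctr.head(20).copy()
        pi = predict_interval(model, sub)
        sub[THK] = 0.0
        sub[THK[0]] = pi["upper"].to_numpy() * 68  # mean thickness == upper bound
        z = deviation_scores(model, sub)[MEAN_COL]
        assert np.allclose(z, 2.0, atol=1e-10)

    def test_observation_at_mean_gives_zero(self, fitted):
        model, ctr = fitted
        sub = ctr.head(20).copy()
        pi = predict_interval(model, sub)
        sub[THK] = 0.0
        sub[THK[0]] = pi["predicted"].to_numpy() * 68
        z = deviation_scores(model, sub)[MEAN_COL]
        assert np.allclose(z, 0.0, atol=1e-10)

    def test_prediction_lies_inside_own_interval(self, fitted):
        model, ctr = fitted
        pi = predict_interval(model, ctr)
        assert (pi["lower"] < pi["predicted"]).all()
        assert (pi["predicted"] < pi["upper"]).all()

    def test_scale_equivariance(self, fitted):
        """Multiplying thickness by c leaves deviation z unchanged."""
        _, ctr = fitted
        scaled = ctr.copy()
        scaled[THK] = scaled[THK] * 3.0
        m1 = fit_normative(ctr, targets="mean")
        m2 = fit_normative(scaled, targets="mean")
        z1 = deviation_scores(m1, ctr)[MEAN_COL]
        z2 = deviation_scores(m2, scaled)[MEAN_COL]
        assert np.allclose(z1, z2, atol=1e-6)


class TestFitRecovery:
    def test_linear_age_truth_recovered(self):
        rng = np.random.default_rng(0)
        n = 2000
        age = rng.uniform(20, 70, n)
        noise = rng.normal(0, 0.1, n)
        df = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "dx": 0, "age": age,
                "sex": rng.choice(["F", "M"], n),
                "icv": rng.normal(1.5e6, 1e5, n),
            }
        )
        for c in THK:
            df[c] = 3.0 - 0.005 * age + noise
        model = fit_normative(df, targets="mean")
        grid = df.head(200).copy()
        pred = predict_interval(model, grid)["predicted"].to_numpy()
        truth = 3.0 - 0.005 * grid["age"].to_numpy()
        # fitted mean tracks the linear truth well inside the noise SD
        assert np.max(np.abs(pred - truth)) < 0.02

    def test_sex_offset_recovered(self):
        rng = np.random.default_rng(1)
        n = 3000
        sex = rng.choice(["F", "M"], n)
        df = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "dx": 0,
                "age": rng.uniform(20, 70, n),
                "sex": sex,
                "icv": rng.normal(1.5e6, 1e5, n),
            }
        )
        base = 2.5 + 0.05 * (sex == "M") + rng.normal(0, 0.1, n)
        for c in THK:
            df[c] = base
        model = fit_normative(df, targets="mean")
        sex_coef = model.fits[MEAN_COL].params[1]
        assert sex_coef == pytest.approx(0.05, abs=0.01)

    def test_control_z_calibration(self, fitted):
        """In-sample control deviations: mean 0, SD ~ 4/(2 x 1.96) = 1.02."""
        model, ctr = fitted
        z = deviation_scores(model, ctr)[MEAN_COL]
        assert abs(z.mean()) < 0.05
        assert z.std() == pytest.approx(4 / (2 * stats.norm.ppf(0.975)), abs=0.04)


class TestHeterogeneity:
    def test_all_zero_gives_zero(self):
        dev = pd.DataFrame({MEAN_COL: np.zeros(50)})
        assert heterogeneity(dev) == 0.0

    def test_standard_normal_tail_fraction(self):
        z = np.random.default_rng(2).standard_normal(100_000)
        dev = pd.DataFrame({MEAN_COL: z})
        assert heterogeneity(dev) == pytest.approx(2 * stats.norm.cdf(-2), abs=0.005)

    def test_empty_group_errors(self):
        dev = pd.DataFrame({MEAN_COL: np.zeros(10)})
        with pytest.raises(ValueError, match="empty"):
            heterogeneity(dev, mask=np.zeros(10, bool))


class TestSubtypeProfiles:
    def _dev(self, n_per=1000, seed=3):
        rng = np.random.default_rng(seed)
        z = rng.normal(0, 1, (2 * n_per, 68))
        labels = np.r_[np.ones(n_per, int), np.full(n_per, 2, int)]
        return pd.DataFrame(z, columns=THK), labels

    def test_identical_distributions_no_hits(self):
        dev, labels = self._dev()
        table, _ = subtype_profile_compare(dev, labels)
        assert np.all(np.abs(table["d"]) < 0.2)
        assert (table["p_fdr"] < 0.05).sum() == 0

    def test_planted_acc_contrast_detected_with_sign(self):
        dev, labels = self._dev(seed=4)
        dev.iloc[:1000, :4] -= 0.5  # S1 lower in the first four regions
        table, _ = subtype_profile_compare(dev, labels)
        assert (table["p_fdr"].iloc[:4] < 0.05).all()
        assert (table["d"].iloc[:4] < 0).all()

    def test_d_map_self_correlation(self, atlas):
        dev, labels = self._dev(n_per=200, seed=5)
        dev.iloc[:200, :10] -= 0.8
        table, report = subtype_profile_compare(
            dev, labels, templates={"self": np.zeros(68)}, n_rot=10
        )
        rho = stats.spearmanr(table["d"], table["d"]).statistic
        assert rho == pytest.approx(1.0)

    def test_small_subtype_errors(self):
        dev, _ = self._dev(n_per=2)
        with pytest.raises(ValueError, match="at least 2"):
            subtype_profile_compare(dev, np.array([1, 1, 1, 1]))


class TestStratification:
    def test_bin_boundary_rules(self):
        assert assign_bin(1.0) == (1, 5)
        assert assign_bin(55.0) == (20, 55)
        assert assign_bin(0.0) == (0, 1)
        assert assign_bin(56.0) is None

    def test_bins_partition_patients(self):
        rng = np.random.default_rng(6)
        dur = rng.uniform(0, 55, 500)
        assigned = [assign_bin(v) for v in dur]
        assert all(b is not None for b in assigned)

    def test_stratified_tables_and_skipped_bins(self):
        rng = np.random.default_rng(7)
        n = 400
        dev = pd.DataFrame(rng.normal(0, 1, (n, 68)), columns=THK)
        labels = rng.integers(1, 3, n)
        cohort = pd.DataFrame({"duration": rng.uniform(0, 8, n)})
        out = stratified_compare(dev, labels, cohort, strata="duration")
        assert set(out) <= {(0, 1), (1, 5), (5, 10)}
        for (lo, hi), (n1, n2, table) in out.items():
            assert n1 >= 2 and n2 >= 2 and len(table) == 68
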