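"""Agreement statistics: ICC(2,1), Bland–Altman, CoV, Levene, mixed model."""

import numpy as np
import pandas as pd
import pytest

from vasquant import (CohortSpec, LmmSpec, PairedRatings, bland_altman,
                      coefficient_of_variation, fit_uptake_lmm, icc_2_1,
                      levene_test, make_cohort_table,
                      proportional_bias_transform)


def icc21_oracle(x: np.ndarray) -> float:
    """Brute-force ICC(2,1): explicit loop-based two-way ANOVA sums."""
    n, k = x.shape
    grand = sum(x[i, j] for i in range(n) for j in range(k)) / (n * k)
    row = [sum(x[i, j] for j in range(k)) / k for i in range(n)]
    col = [sum(x[i, j] for i in range(n)) / n for j in range(k)]
    ss_r = k * sum((r - grand) ** 2 for r in row)
    ss_c = n * sum((c - grand) ** 2 for c in col)
    ss_e = sum((x[i, j] - row[i] - col[j] + grand) ** 2
               for i in range(n) for j in range(k))
    msr, msc, mse = ss_r / (n - 1), ss_c / (k - 1), ss_e / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestIcc:
    def test_identical_columns_give_one(self):
        x = np.array([[1.0, 1.0], [2.0, 2.0], [5.0, 5.0]])
        res = icc_2_1(PairedRatings(x))
        assert res.estimate == pytest.approx(1.0)

    def test_constant_offset_matrix_vs_oracle(self):
        x = np.array([[1.0, 2.0], [2.0, 3.0], [3.0, 4.0]])
        res = icc_2_1(PairedRatings(x))
        assert res.estimate < 1.0
        assert res.estimate == pytest.approx(icc21_oracle(x), abs=1e-12)

    def test_noisy_duplicate_column_vs_oracle(self):
        rng = np.random.default_rng(7)
        a = rng.normal(3, 1, 50)
        x = np.column_stack([a, a + rng.normal(0, 0.3, 50)])
        res = icc_2_1(PairedRatings(x))
        assert res.estimate == pytest.approx(icc21_oracle(x), abs=1e-10)
        assert res.ci_low < res.estimate < res.ci_high

    def test_estimate_and_ci_match_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(11)
        x = rng.normal(2, 0.5, (12, 3)) + rng.normal(0, 0.8, (12, 1))
        res = icc_2_1(PairedRatings(x))
        long = pd.DataFrame({
            "target": np.repeat(np.arange(12), 3),
            "rater": np.tile(np.arange(3), 12),
            "score": x.ravel(),
        })
        ref = pg.intraclass_corr(long, targets="target", raters="rater",
                                 ratings="score").set_index("Type")
        assert res.estimate == pytest.approx(ref.loc["ICC(A,1)", "ICC"], abs=1e-9)
        lo, hi = ref.loc["ICC(A,1)", "CI95"]  # pingouin rounds the CI to 2 dp
        assert res.ci_low == pytest.approx(lo, abs=6e-3)
        assert res.ci_high == pytest.approx(hi, abs=6e-3)

    def test_absolute_agreement_behaviour(self):
        rng = np.random.default_rng(3)
        x = np.column_stack([rng.normal(2, 1, 30)] * 2) + rng.normal(0, 0.1, (30, 2))
        base = icc_2_1(PairedRatings(x)).estimate
        shifted_all = icc_2_1(PairedRatings(x + 5.0)).estimate
        assert shifted_all == pytest.approx(base, abs=1e-10)
        one_col = x.copy()
        one_col[:, 1] += 2.0  # systematic offset hurts absolute agreement
        assert icc_2_1(PairedRatings(one_col)).estimate < base

    def test_degenerate_all_equal(self):
        res = icc_2_1(PairedRatings(np.full((5, 2), 3.0)))
        assert res.estimate == 1.0 and res.degenerate

    def test_too_few_targets(self):
        with pytest.raises(ValueError, match="3 targets"):
            icc_2_1(PairedRatings(np.array([[1.0, 2.0], [2.0, 1.0]])))

    def test_missing_rows_dropped_and_counted(self):
        x = np.array([[1.0, 2.0], [np.nan, 3.0], [3.0, 4.0], [4.0, 5.0]])
        r = PairedRatings.from_matrix(x)
        assert r.n == 3 and r.n_dropped == 1


class TestBlandAltman:
    def test_identical_series(self):
        x = np.array([1.0, 2.0, 3.0])
        res = bland_altman(x, x)
        assert res.bias == 0 and res.loa_low == 0 and res.loa_high == 0

    def test_hand_computed_loa(self):
        y = np.zeros(4)
        x = np.array([1.0, 1.0, 1.0, 3.0])  # diffs SD = 1.0 exactly
        res = bland_altman(x, y)
        assert res.bias == pytest.approx(1.5)
        assert res.sd_diff == pytest.approx(1.0)
        assert res.loa_low == pytest.approx(-0.46)
        assert res.loa_high == pytest.approx(3.46)

    def test_antisymmetry(self, rng):
        x, y = rng.normal(2, 1, 30), rng.normal(2, 1, 30)
        a, b = bland_altman(x, y), bland_altman(y, x)
        assert a.bias == pytest.approx(-b.bias)
        assert a.loa_low == pytest.approx(-b.loa_high)

    def test_loa_cover_95_percent_of_gaussian_diffs(self, rng):
        x = rng.normal(10, 1, 20000)
        y = x + rng.normal(0.3, 0.5, 20000)
        res = bland_altman(x, y)
        inside = np.mean((res.pair_diffs >= res.loa_low)
                         & (res.pair_diffs <= res.loa_high))
        assert inside == pytest.approx(0.95, abs=0.01)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            bland_altman([1, 2], [1, 2, 3])


class TestProportionalBiasTransform:
    def test_no_association_for_identical_series(self, rng):
        x = rng.uniform(1, 5, 50)
        flag, xt, yt = proportional_bias_transform(x, x)
        assert not flag
        np.testing.assert_array_equal(xt, x)

    def test_multiplicative_bias_triggers_ln(self, rng):
        x = rng.uniform(1, 5, 50)
        y = 1.5 * x
        flag, xt, yt = proportional_bias_transform(x, y)
        assert flag
        np.testing.assert_allclose(xt, np.log(x))
        np.testing.assert_allclose(yt, np.log(y))

    def test_constant_offset_does_not_trigger(self, rng):
        x = rng.uniform(1, 5, 50)
        flag, _, _ = proportional_bias_transform(x, x + 1.0)
        assert not flag


class TestCovAndLevene:
    def test_cov_examples(self):
        assert coefficient_of_variation([4.0, 4.0, 4.0]) == 0.0
        assert coefficient_of_variation([1.0, 3.0]) == pytest.approx(
            np.sqrt(2.0) / 2.0)

    def test_cov_scale_invariance(self, rng):
        v = rng.gamma(3, 1, 40)
        assert coefficient_of_variation(v * 7.3) == pytest.approx(
            coefficient_of_variation(v))

    def test_cov_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            coefficient_of_variation([-1.0, 1.0])

    def test_levene_identical_groups(self):
        g = [1.0, 2.0, 3.0, 4.0]
        stat, p = levene_test([g, list(g)])
        assert stat == pytest.approx(0.0)

    def test_levene_detects_variance_ratio_nine(self):
        rejections = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            _, p = levene_test([r.normal(0, 1, 200), r.normal(0, 3, 200)])
            rejections += p < 0.05
        assert rejections >= 95

    def test_levene_type_one_error_calibrated(self):
        rejections = 0
        for seed in range(200):
            r = np.random.default_rng(1000 + seed)
            pooled = r.normal(0, 1, 120)
            _, p = levene_test([pooled[:60], pooled[60:]])
            rejections += p < 0.05
        assert 0.005 <= rejections / 200 <= 0.12


class TestUptakeLmm:
    @staticmethod
    def _table(slope, intercept=1.0, seed=0, **kw):
        spec = CohortSpec(slope_per_min=slope, intercept=intercept, seed=seed, **kw)
        df, truth = make_cohort_table(spec)
        return df, truth

    def test_noiseless_data_recovers_exact_slope(self):
        df, _ = self._table(0.005, patient_intercept_sd=0, patient_slope_sd=0,
                            segment_sd=0, residual_sd=0, observer_error_sd=0,
                            n_observers=1)
        res = fit_uptake_lmm(df, LmmSpec())
        assert res.fixed_slope == pytest.approx(0.005, abs=1e-8)
        assert res.group_means[38.0] == pytest.approx(1.0 + 0.005 * 38, abs=1e-6)

    def test_reduces_to_ols_when_variances_zero(self):
        import statsmodels.formula.api as smf
        df, _ = self._table(0.004, residual_sd=0.1, patient_intercept_sd=0,
                            patient_slope_sd=0, segment_sd=0,
                            observer_error_sd=0, n_observers=1)
        res = fit_uptake_lmm(df, LmmSpec(random_slope=False,
                                         segment_intercept=False))
        ols = smf.ols("suvmax ~ timepoint_min", df).fit()
        assert res.fixed_slope == pytest.approx(
            ols.params["timepoint_min"], abs=1e-5)

    def test_null_slope_centered_at_zero(self):
        slopes = []
        for seed in range(30):
            df, _ = self._table(0.0, seed=seed)
            rng = np.random.default_rng(seed)
            df = df.copy()
            # permuting timepoint labels breaks any time association
            df["timepoint_min"] = rng.permutation(df["timepoint_min"].to_numpy())
            slopes.append(fit_uptake_lmm(df).fixed_slope)
        assert abs(np.mean(slopes)) < 3 * np.std(slopes) / np.sqrt(len(slopes)) + 1e-4

    def test_single_timepoint_rejected(self):
        df, _ = self._table(0.005)
        with pytest.raises(ValueError, match="timepoint"):
            fit_uptake_lmm(df[df.timepoint_min == 38.0])

    def test_time_as_factor_group_means(self):
        df, _ = self._table(0.005, patient_intercept_sd=0, patient_slope_sd=0,
                            segment_sd=0, residual_sd=0, observer_error_sd=0,
                            n_observers=1)
        res = fit_uptake_lmm(df, LmmSpec(time_as_factor=True, random_slope=False))
        for t in (38.0, 60.0, 90.0):
            assert res.group_means[t] == pytest.approx(1.0 + 0.005 * t, abs=1e-6)
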