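"""Validation statistics: SNR/CNR, ICC, paired tests, regression."""
import math
import warnings

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from vtemri import (add_rician_noise, bonferroni_threshold, cnr,
                    compare_paired, icc, multivariable_regression, paired_t,
                    snr, wilcoxon_signed_rank)
from vtemri.stats import RAYLEIGH_SD_FACTOR, _mean_squares, shapiro_normal

from conftest import uniform_study


# --------------------------------------------------------------------------
# independent loop-based ANOVA oracle for the ICC forms

def icc_anova_oracle(table, form):
    """Shrout-Fleiss single-measure ICCs from explicitly summed ANOVA."""
    n, k = len(table), len(table[0])
    grand = sum(sum(row) for row in table) / (n * k)
    row_means = [sum(row) / k for row in table]
    col_means = [sum(table[i][j] for i in range(n)) / n for j in range(k)]
    ssr = k * sum((m - grand) ** 2 for m in row_means)
    ssc = n * sum((m - grand) ** 2 for m in col_means)
    sst = sum((table[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = (sst - ssr - ssc) / ((n - 1) * (k - 1))
    msw = (sst - ssr) / (n * (k - 1))
    if form == "oneway":
        return (msr - msw) / (msr + (k - 1) * msw)
    if form == "twoway_consistency":
        return (msr - mse) / (msr + (k - 1) * mse)
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestSNRCNR:
    def test_snr_ratio(self):
        assert snr(100.0, 2.0) == 50.0
        assert snr(0.0, 2.0) == 0.0

    def test_snr_requires_positive_sd(self):
        with pytest.raises(ValueError):
            snr(100.0, 0.0)

    def test_snr_rayleigh_correction_recovers_channel_sigma(self):
        assert snr(100.0, 5.0, rayleigh_correct=True) == \
            pytest.approx(100.0 / (5.0 / RAYLEIGH_SD_FACTOR))

    def test_snr_on_noisy_phantom_matches_rayleigh_prediction(self):
        """Background SD of magnitude noise is sigma*sqrt(2-pi/2), so a
        noiseless mean m gives SNR ~= m/(sigma*sqrt(2-pi/2))."""
        sigma, mean = 10.0, 600.0
        ratios = []
        for rep in range(20):
            bg = add_rician_noise(uniform_study(0.0, 0.0, (40, 40, 4)),
                                  sigma, seed=rep)
            ratios.append(snr(mean, float(bg.echo1.std(ddof=1))))
        expected = mean / (sigma * math.sqrt(2 - math.pi / 2))
        assert np.mean(ratios) == pytest.approx(expected, rel=0.02)

    def test_cnr_printed_formula(self):
        assert cnr(100.0, 63.0).value == pytest.approx(0.37)
        assert cnr(80.0, 80.0).value == 0.0

    def test_cnr_negative_flagged(self):
        res = cnr(50.0, 60.0)
        assert res.value == pytest.approx(-0.2)
        assert res.nerve_brighter_than_muscle

    def test_cnr_requires_positive_muscle_snr(self):
        with pytest.raises(ValueError):
            cnr(0.0, 10.0)


class TestICC:
    @pytest.mark.parametrize("form", ["oneway", "twoway_agreement",
                                      "twoway_consistency"])
    def test_identical_columns_give_one(self, form):
        col = np.array([10.0, 12.0, 15.0, 9.0, 14.0])
        res = icc(np.column_stack([col, col]), form=form)
        assert res.value == pytest.approx(1.0)
        assert res.p < 1e-6

    def test_constant_offset_consistency_one_agreement_below(self):
        col = np.array([10.0, 12.0, 15.0, 9.0, 14.0])
        table = np.column_stack([col, col + 3.0])
        res_c = icc(table, form="twoway_consistency")
        res_a = icc(table, form="twoway_agreement")
        assert res_c.value == pytest.approx(1.0)
        assert res_a.value < 1.0
        assert res_a.value == pytest.approx(
            icc_anova_oracle(table.tolist(), "twoway_agreement"), abs=1e-12)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(4)
        table = rng.normal(0, 1, (200, 2))
        res = icc(table, form="twoway_agreement")
        assert abs(res.value) < 0.15

    @pytest.mark.parametrize("form", ["oneway", "twoway_agreement",
                                      "twoway_consistency"])
    def test_matches_hand_anova_oracle(self, form):
        rng = np.random.default_rng(7)
        for _ in range(20):
            table = rng.normal(15, 4, (5, 2))
            mine = icc(table, form=form).value
            assert mine == pytest.approx(
                icc_anova_oracle(table.tolist(), form), abs=1e-10)

    def test_matches_pingouin_reference(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        x = rng.normal(17, 4, (10, 2))
        x[:, 1] += rng.normal(0.5, 1.0, 10)
        df = pd.DataFrame({"t": np.repeat(range(10), 2),
                           "r": np.tile([0, 1], 10),
                           "y": x.reshape(-1)})
        ref = pg.intraclass_corr(df, "t", "r", "y").set_index("Type")
        for form, typ in [("oneway", "ICC1"), ("twoway_agreement", "ICC2"),
                          ("twoway_consistency", "ICC3")]:
            mine = icc(x, form=form)
            row = ref.loc[typ] if typ in ref.index else \
                ref.loc[{"ICC1": "ICC(1,1)", "ICC2": "ICC(A,1)",
                         "ICC3": "ICC(C,1)"}[typ]]
            assert mine.value == pytest.approx(float(row.ICC), abs=1e-10)
            assert mine.p == pytest.approx(float(row.pval), abs=1e-9)
            # pingouin rounds its CI to 2 decimals
            assert mine.ci95[0] == pytest.approx(row.CI95[0], abs=0.006)
            assert mine.ci95[1] == pytest.approx(row.CI95[1], abs=0.006)

    def test_bounds_and_conditional_ordering(self):
        """Single-measure ICC never exceeds 1; the one-way and consistency
        estimators are bounded below by -1/(k-1); and absolute agreement
        cannot exceed consistency when both the rater and the target mean
        squares dominate the residual (the regime where the forms are
        meaningfully compared)."""
        rng = np.random.default_rng(11)
        for _ in range(300):
            n = int(rng.integers(3, 12))
            k = int(rng.integers(2, 5))
            table = rng.normal(0, 1, (n, k))
            msr, msc, mse, _ = _mean_squares(table)
            a = icc(table, form="twoway_agreement").value
            c = icc(table, form="twoway_consistency").value
            o = icc(table, form="oneway").value
            for v in (a, c, o):
                assert v <= 1.0 + 1e-12
            assert o >= -1.0 / (k - 1) - 1e-12
            assert c >= -1.0 / (k - 1) - 1e-12
            if msc >= mse and msr >= mse:
                assert a <= c + 1e-12

    def test_degenerate_tables_rejected(self):
        with pytest.raises(ValueError):
            icc(np.ones((5, 2)))                      # zero variance
        with pytest.raises(ValueError):
            icc(np.random.default_rng(0).random((2, 2)))   # too few rows
        with pytest.raises(ValueError):
            icc(np.random.default_rng(0).random((5, 1)))   # one rater
        bad = np.random.default_rng(0).random((5, 2))
        bad[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            icc(bad)


class TestPairedTests:
    def test_identical_samples_t_zero_p_one(self):
        x = np.array([1.0, 2.0, 3.0])
        res = paired_t(x, x)
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_textbook_five_pairs(self):
        # hand computation: d = [5,2,-1,4,1], mean 2.2, var 22.8/4 = 5.7,
        # t = 2.2/(sqrt(5.7)/sqrt(5)) = 2.060489, df = 4
        x = [120.0, 122.0, 118.0, 130.0, 125.0]
        y = [115.0, 120.0, 119.0, 126.0, 124.0]
        res = paired_t(x, y)
        expected_t = 2.2 / math.sqrt(5.7 / 5)
        assert res.statistic == pytest.approx(expected_t, abs=1e-12)
        assert round(res.statistic, 5) == 2.06049
        assert res.p == pytest.approx(2 * sps.t.sf(expected_t, df=4), abs=1e-12)

    def test_swap_flips_sign_keeps_p(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(0, 1, 15), rng.normal(0.3, 1, 15)
        a, b = paired_t(x, y), paired_t(y, x)
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.p == pytest.approx(b.p)

    def test_wilcoxon_six_positive_differences_exact(self):
        # all 6 differences positive: one-tailed exact p = 1/2^6
        x = np.arange(1.0, 7.0)
        y = np.zeros(6)
        res = wilcoxon_signed_rank(x, y, alternative="greater")
        assert res.p == pytest.approx(1 / 64)

    def test_wilcoxon_identical_samples_degenerate(self):
        x = np.array([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="degenerate"):
            wilcoxon_signed_rank(x, x)

    def test_wilcoxon_swap_symmetry(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(0, 1, 12), rng.normal(0.4, 1, 12)
        assert wilcoxon_signed_rank(x, y).p == \
            pytest.approx(wilcoxon_signed_rank(y, x).p)

    def test_normality_gate_routes_tests(self):
        rng = np.random.default_rng(5)
        x = rng.normal(10, 1, 20)
        assert compare_paired(x, x + rng.normal(0, 0.5, 20)).test == "paired_t"
        heavy = x + rng.standard_cauchy(20) * 3
        assert shapiro_normal(heavy - x) is False
        assert compare_paired(x, heavy).test == "wilcoxon"


class TestRegression:
    def test_exact_linear_recovery(self):
        rng = np.random.default_rng(0)
        cov = pd.DataFrame({"weight": rng.uniform(50, 90, 15),
                            "height": rng.uniform(1.5, 1.9, 15)})
        res = multivariable_regression(2.0 * cov.weight, cov)
        assert res.table.loc["weight", "coef"] == pytest.approx(2.0, abs=1e-10)
        assert res.table.loc["weight", "se"] == pytest.approx(0.0, abs=1e-9)

    def test_duplicated_covariate_warns_singular(self):
        rng = np.random.default_rng(1)
        w = rng.uniform(50, 90, 15)
        cov = pd.DataFrame({"a": w, "b": w})
        with pytest.warns(UserWarning, match="condition number"):
            res = multivariable_regression(rng.normal(0, 1, 15), cov)
        assert res.condition_number > 1e8

    def test_null_covariates_rarely_significant(self):
        """aT2* independent of weight/height/BMI: all three covariate
        p-values clear 0.05 in the large majority of n=15 replicates."""
        rng = np.random.default_rng(9)
        all_ns = 0
        reps = 500
        for _ in range(reps):
            height = rng.normal(1.75, 0.08, 15)
            bmi = rng.normal(21.9, 1.2, 15)
            cov = pd.DataFrame({"weight": bmi * height**2, "height": height,
                                "bmi": bmi})
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = multivariable_regression(rng.normal(17.9, 4, 15), cov)
            ps = res.table.loc[["weight", "height", "bmi"], "p"]
            all_ns += int((ps > 0.05).all())
        assert all_ns / reps >= 0.90

    def test_bonferroni_values(self):
        res = bonferroni_threshold(0.05, 6)
        assert res.rounded == 0.008
        assert res.value == pytest.approx(0.05 / 6)
        assert bonferroni_threshold(0.05, 1).value == 0.05
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)
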