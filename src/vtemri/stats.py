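"""Validation statistics: SNR/CNR, ICC, paired tests, regression, Bonferroni.

The agreement measure is the single-measure intraclass correlation in three
classical forms (one-way random; two-way random, absolute agreement; two-way
mixed, consistency), computed from the ANOVA mean squares of a targets x
raters table with F-based confidence intervals and a test of ICC = 0.
SNR and CNR follow the ROI conventions of quantitative MR validation work:
SNR = mean tissue signal / SD of a background-air ROI, and
CNR = (SNR_muscle - SNR_nerve) / SNR_muscle (a normalized contrast).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm

ICC_FORMS = ("oneway", "twoway_agreement", "twoway_consistency")

#: Rayleigh SD factor: the SD of background magnitude noise is
#: sigma * sqrt(2 - pi/2) for channel noise sigma.
RAYLEIGH_SD_FACTOR = math.sqrt(2.0 - math.pi / 2.0)


# --------------------------------------------------------------------------
# SNR / CNR

def snr(signal_roi_mean: float, noise_sd: float,
        rayleigh_correct: bool = False) -> float:
    """Signal-to-noise ratio: tissue ROI mean over background-noise SD.

    ``noise_sd`` is the raw SD of the background-air ROI. With
    ``rayleigh_correct=True`` the SD is first divided by sqrt(2 - pi/2) to
    recover the underlying channel sigma (off by default; the raw printed
    convention is the reference behaviour).
    """
    if noise_sd <= 0:
        raise ValueError(f"noise_sd must be > 0, got {noise_sd}")
    if rayleigh_correct:
        noise_sd = noise_sd / RAYLEIGH_SD_FACTOR
    return signal_roi_mean / noise_sd


class CNRResult(NamedTuple):
    value: float
    nerve_brighter_than_muscle: bool


def cnr(snr_muscle: float, snr_nerve: float) -> CNRResult:
    """Normalized nerve/muscle contrast: (SNR_muscle - SNR_nerve) / SNR_muscle.

    Negative values (nerve brighter than muscle) are returned as-is with
    the flag set.
    """
    if snr_muscle <= 0:
        raise ValueError(f"snr_muscle must be > 0, got {snr_muscle}")
    value = (snr_muscle - snr_nerve) / snr_muscle
    return CNRResult(value=float(value), nerve_brighter_than_muscle=value < 0)


# --------------------------------------------------------------------------
# ICC

@dataclass
class ICCResult:
    value: float
    ci95: tuple[float, float]
    p: float
    form: str
    n_targets: int
    n_raters: int
    f_stat: float
    df1: float
    df2: float


def _mean_squares(x: np.ndarray) -> tuple[float, float, float, float]:
    """ANOVA mean squares of a targets x raters table.

    Returns (MSR, MSC, MSE, MSW): rows (targets), columns (raters),
    residual, and within-target (one-way) mean squares.
    """
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * float(((row_means - grand) ** 2).sum())
    ssc = n * float(((col_means - grand) ** 2).sum())
    sst = float(((x - grand) ** 2).sum())
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    msw = (sst - ssr) / (n * (k - 1))
    return msr, msc, mse, msw


def icc(table, form: str = "twoway_agreement", alpha: float = 0.05) -> ICCResult:
    """Single-measure intraclass correlation of a targets x raters table.

    Forms: ``oneway`` (one-way random, ICC(1,1)), ``twoway_agreement``
    (two-way random, absolute agreement, ICC(A,1)) and
    ``twoway_consistency`` (two-way mixed, consistency, ICC(C,1)).
    Confidence intervals use the exact F bounds for the one-way and
    consistency forms and the Satterthwaite approximation for absolute
    agreement; the p-value tests ICC = 0 with F = MSR/MSE (MSR/MSW for the
    one-way form).
    """
    if form not in ICC_FORMS:
        raise ValueError(f"form must be one of {ICC_FORMS}, got {form!r}")
    x = np.asarray(table, dtype=float)
    if isinstance(table, pd.DataFrame):
        x = table.to_numpy(dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings table must be 2D (targets x raters)")
    n, k = x.shape
    if n < 3 or k < 2:
        raise ValueError(f"need >= 3 targets and >= 2 raters, got {n} x {k}")
    if np.isnan(x).any():
        raise ValueError("ratings table has missing cells")
    if np.ptp(x) == 0:
        raise ValueError("zero total variance: ICC undefined")

    msr, msc, mse, msw = _mean_squares(x)
    q = sps.f.ppf  # upper quantile helper via 1 - alpha/2

    if form == "oneway":
        value = (msr - msw) / (msr + (k - 1) * msw) if msw > 0 else 1.0
        df1, df2 = n - 1.0, n * (k - 1.0)
        f_stat = msr / msw if msw > 0 else math.inf
        if math.isinf(f_stat):
            lo = hi = 1.0
        else:
            fl = f_stat / q(1 - alpha / 2, df1, df2)
            fu = f_stat * q(1 - alpha / 2, df2, df1)
            lo = (fl - 1) / (fl + k - 1)
            hi = (fu - 1) / (fu + k - 1)
    elif form == "twoway_consistency":
        value = (msr - mse) / (msr + (k - 1) * mse) if mse > 0 else 1.0
        df1, df2 = n - 1.0, (n - 1.0) * (k - 1.0)
        f_stat = msr / mse if mse > 0 else math.inf
        if math.isinf(f_stat):
            lo = hi = 1.0
        else:
            fl = f_stat / q(1 - alpha / 2, df1, df2)
            fu = f_stat * q(1 - alpha / 2, df2, df1)
            lo = (fl - 1) / (fl + k - 1)
            hi = (fu - 1) / (fu + k - 1)
    else:  # twoway_agreement
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
        value = (msr - mse) / denom if denom > 0 else 1.0
        df1, df2 = n - 1.0, (n - 1.0) * (k - 1.0)
        f_stat = msr / mse if mse > 0 else math.inf
        if math.isinf(f_stat) or mse == 0:
            lo = hi = 1.0 if msc == 0 else value
        else:
            r = value
            fj = msc / mse
            with np.errstate(divide="ignore", invalid="ignore"):
                vn = (k - 1) * (n - 1) * \
                    (k * r * fj + n * (1 + (k - 1) * r) - k * r) ** 2
                vd = (n - 1) * k**2 * r**2 * fj**2 + \
                    (n * (1 + (k - 1) * r) - k * r) ** 2
                v = vn / vd
                f3u = q(1 - alpha / 2, n - 1, v)
                f3l = q(1 - alpha / 2, v, n - 1)
                lo = n * (msr - f3u * mse) / (
                    f3u * (k * msc + (k * n - k - n) * mse) + n * msr)
                hi = n * (f3l * msr - mse) / (
                    k * msc + (k * n - k - n) * mse + n * f3l * msr)

    p = float(sps.f.sf(f_stat, df1, df2)) if math.isfinite(f_stat) else 0.0
    return ICCResult(value=float(value), ci95=(float(lo), float(hi)), p=p,
                     form=form, n_targets=n, n_raters=k,
                     f_stat=float(f_stat), df1=df1, df2=df2)


# --------------------------------------------------------------------------
# paired tests

@dataclass
class PairedTestResult:
    test: str
    statistic: float
    p: float
    n: int


def paired_t(x: Sequence[float], y: Sequence[float]) -> PairedTestResult:
    """Classical paired Student's t test, two-sided.

    Identical samples (all differences zero) give t = 0, p = 1 rather than
    an undefined statistic.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D paired samples of equal length")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    if np.all(d == 0):
        return PairedTestResult(test="paired_t", statistic=0.0, p=1.0, n=x.size)
    res = sps.ttest_rel(x, y)
    return PairedTestResult(test="paired_t", statistic=float(res.statistic),
                            p=float(res.pvalue), n=x.size)


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float],
                         alternative: str = "two-sided") -> PairedTestResult:
    """Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped (Wilcoxon convention). The exact null
    distribution is used for n <= 25 (when the ranks are untied), otherwise
    the normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D paired samples of equal length")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("degenerate pairs: all differences are zero")
    has_ties = np.unique(np.abs(d)).size < d.size
    method = "exact" if (d.size <= 25 and not has_ties) else "approx"
    res = sps.wilcoxon(d, alternative=alternative, method=method,
                       correction=(method == "approx"))
    return PairedTestResult(test="wilcoxon", statistic=float(res.statistic),
                            p=float(res.pvalue), n=int(d.size))


def shapiro_normal(values: Sequence[float], alpha: float = 0.05) -> bool:
    """Shapiro-Wilk normality gate at the given alpha."""
    values = np.asarray(values, dtype=float)
    if np.ptp(values) == 0:
        return False
    return bool(sps.shapiro(values).pvalue > alpha)


def compare_paired(x: Sequence[float], y: Sequence[float],
                   alpha: float = 0.05) -> PairedTestResult:
    """Paired comparison routed by a Shapiro-Wilk gate on the differences:
    paired t when the differences look normal, Wilcoxon otherwise."""
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    if np.all(d == 0):
        return paired_t(x, y)
    if shapiro_normal(d, alpha):
        return paired_t(x, y)
    return wilcoxon_signed_rank(x, y)


def two_sample_t(x: Sequence[float], y: Sequence[float]) -> PairedTestResult:
    """Two-sample Student's t test (equal variances), two-sided."""
    res = sps.ttest_ind(np.asarray(x, float), np.asarray(y, float))
    return PairedTestResult(test="two_sample_t", statistic=float(res.statistic),
                            p=float(res.pvalue), n=len(x) + len(y))


# --------------------------------------------------------------------------
# regression and multiplicity

@dataclass
class RegressionResult:
    table: pd.DataFrame            # coef, se, t, p per term (incl. intercept)
    condition_number: float
    n: int

    def p_for(self, term: str) -> float:
        return float(self.table.loc[term, "p"])


def multivariable_regression(response: Sequence[float],
                             covariates: pd.DataFrame,
                             cond_warn: float = 1e8) -> RegressionResult:
    """OLS of a response on several covariates, with intercept.

    Anthropometric covariate sets (weight, height, BMI) are close to
    collinear by construction; the design condition number is always
    reported and a warning is emitted above ``cond_warn``.
    """
    y = np.asarray(response, dtype=float)
    X = covariates.astype(float)
    if len(y) != len(X):
        raise ValueError("response and covariates have different lengths")
    exog = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        # near-singular designs are diagnosed via the condition number below
        warnings.simplefilter("ignore")
        fit = sm.OLS(y, exog).fit()
    cond = float(np.linalg.cond(exog.to_numpy()))
    if cond > cond_warn:
        warnings.warn(
            f"near-singular design (condition number {cond:.3g}); "
            "coefficient tests are unstable", UserWarning, stacklevel=2)
    table = pd.DataFrame({
        "coef": fit.params, "se": fit.bse, "t": fit.tvalues, "p": fit.pvalues})
    return RegressionResult(table=table, condition_number=cond, n=len(y))


class BonferroniThreshold(NamedTuple):
    value: float          # alpha / n_tests, full precision
    rounded: float        # rounded to 3 decimals for reporting


def bonferroni_threshold(alpha: float, n_tests: int) -> BonferroniThreshold:
    """Family-wise significance threshold alpha / n_tests."""
    if n_tests <= 0:
        raise ValueError(f"n_tests must be >= 1, got {n_tests}")
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    value = alpha / n_tests
    return BonferroniThreshold(value=value, rounded=round(value, 3))
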