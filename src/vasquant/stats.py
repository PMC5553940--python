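"""Method- and observer-agreement statistics.

The layer mirrors the analyses an SPSS user would run on a long-format
measurement table: single-measure intraclass correlation ICC(2,1) from a
two-way random-effects ANOVA under absolute agreement (with the
McGraw–Wong F-based 95% CI), Bland–Altman limits of agreement with the
natural-log transform rule for proportional bias, coefficient of variation,
Levene's homogeneity test (classic, mean-centered), and a linear mixed
model of uptake time with per-patient random intercept and slope plus a
per-segment random intercept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "PairedRatings",
    "IccResult",
    "AgreementResult",
    "LmmSpec",
    "LmmResult",
    "icc_2_1",
    "bland_altman",
    "proportional_bias_transform",
    "coefficient_of_variation",
    "levene_test",
    "fit_uptake_lmm",
]


@dataclass(frozen=True)
class PairedRatings:
    """n targets × k raters/methods matrix of continuous ratings.

    Rows with missing cells are dropped (complete-case) and counted.
    """

    values: np.ndarray
    row_labels: list[str] | None = None
    col_labels: list[str] | None = None
    n_dropped: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 2 or self.values.shape[1] < 2:
            raise ValueError("ratings must be an n × k matrix with k >= 2")

    @classmethod
    def from_matrix(cls, values: np.ndarray, **kw) -> "PairedRatings":
        values = np.asarray(values, dtype=float)
        complete = ~np.isnan(values).any(axis=1)
        return cls(values[complete], n_dropped=int((~complete).sum()), **kw)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class IccResult:
    estimate: float
    ci_low: float
    ci_high: float
    n: int
    k: int
    degenerate: bool = False  # all cells equal: ICC defined as 1


@dataclass(frozen=True)
class AgreementResult:
    """Bland–Altman summary for one method/observer pair."""

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n_used: int
    log_transformed: bool = False
    pair_means: np.ndarray = field(default=None, repr=False)
    pair_diffs: np.ndarray = field(default=None, repr=False)


def _anova_mean_squares(x: np.ndarray) -> tuple[float, float, float]:
    """(MSR, MSC, MSE) of the two-way (targets × raters) ANOVA without
    replication."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc_2_1(ratings: PairedRatings, alpha: float = 0.05) -> IccResult:
    """Single-measure ICC, two-way random effects, absolute agreement.

    ICC(2,1) = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE)), with the
    McGraw–Wong Satterthwaite F interval for the CI. A matrix with zero
    total variance has perfect agreement by definition: the estimate is 1
    with a degenerate CI, flagged.
    """
    x = ratings.values
    n, k = ratings.n, ratings.k
    if n < 3:
        raise ValueError("ICC CI computation needs at least 3 targets")
    if np.isnan(x).any():
        raise ValueError("ratings contain missing cells; use from_matrix()")
    if np.ptp(x) == 0:
        return IccResult(1.0, 1.0, 1.0, n, k, degenerate=True)
    msr, msc, mse = _anova_mean_squares(x)
    icc = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))

    # McGraw & Wong case-2A single-measure interval
    a = (k * icc) / (n * (1 - icc)) if icc < 1 else np.inf
    b = 1 + (k * icc * (n - 1)) / (n * (1 - icc)) if icc < 1 else np.inf
    if not np.isfinite(a):
        return IccResult(float(icc), 1.0, 1.0, n, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
    f1 = sps.f.ppf(1 - alpha / 2, n - 1, v)
    f2 = sps.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f1 * mse) / (
        f1 * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f2 * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f2 * msr
    )
    return IccResult(float(icc), float(lower), float(upper), n, k)


def bland_altman(x, y, transformed: bool = False) -> AgreementResult:
    """Bland–Altman bias and 95% limits of agreement.

    bias = mean(x − y); LoA = bias ± 1.96 · sample SD of the differences.
    Per-pair means and differences are returned for plotting.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired series must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    diffs = x - y
    means = (x + y) / 2.0
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return AgreementResult(
        bias=bias, sd_diff=sd,
        loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd,
        n_used=int(x.size), log_transformed=transformed,
        pair_means=means, pair_diffs=diffs,
    )


def proportional_bias_transform(
    x, y, alpha: float = 0.05
) -> tuple[bool, np.ndarray, np.ndarray]:
    """ln-transform rule for Bland–Altman proportional bias.

    Tests the Pearson correlation between pair means and pair differences;
    if significant at *alpha* the series are returned natural-log
    transformed with flag True, otherwise unchanged with flag False.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired series must have equal length")
    means, diffs = (x + y) / 2.0, x - y
    if np.ptp(diffs) == 0 or np.ptp(means) == 0:
        return False, x, y
    _, p = sps.pearsonr(means, diffs)
    if p < alpha:
        if np.any(x <= 0) or np.any(y <= 0):
            raise ValueError("ln transform triggered but values are not all positive")
        return True, np.log(x), np.log(y)
    return False, x, y


def coefficient_of_variation(values) -> float:
    """Sample SD / mean (scale-free dispersion)."""
    values = np.asarray(values, dtype=float)
    m = values.mean()
    if m == 0:
        raise ValueError("coefficient of variation undefined for zero mean")
    if values.size < 2:
        return 0.0
    return float(values.std(ddof=1) / m)


def levene_test(groups: list) -> tuple[float, float]:
    """Classic Levene homogeneity test (absolute deviations from group means)."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least 2 observations")
    stat, p = sps.levene(*arrays, center="mean")
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# Linear mixed model of uptake time


@dataclass(frozen=True)
class LmmSpec:
    """Model structure for outcome ~ uptake time.

    ``time_as_factor`` switches the fixed effect from a per-minute slope to
    a 3-level factor coding (changes the meaning of the coefficient).
    ``random_slope``/``segment_intercept`` toggle the random-effect parts.
    """

    outcome: str = "suvmax"
    time_col: str = "timepoint_min"
    patient_col: str = "patient_id"
    segment_col: str = "segment"
    random_slope: bool = True
    segment_intercept: bool = True
    time_as_factor: bool = False


@dataclass(frozen=True)
class LmmResult:
    fixed_slope: float
    slope_se: float
    slope_p: float
    slope_ci: tuple[float, float]
    random_variances: dict[str, float]
    group_means: dict[float, float]
    n_obs: int
    n_dropped: int
    converged: bool
    structure: str


def fit_uptake_lmm(records: pd.DataFrame, spec: LmmSpec = LmmSpec()) -> LmmResult:
    """REML fit of outcome ~ uptake time with repeated-measures structure.

    Random effects: per-patient intercept (+ slope) and a per-segment
    intercept fitted as a variance component within patient. On
    non-convergence the model falls back to random-intercept-only, flagged
    in ``structure``.
    """
    df = records[[spec.outcome, spec.time_col, spec.patient_col, spec.segment_col]].copy()
    n_in = len(df)
    df = df.dropna()
    df.columns = ["y", "t", "patient", "segment"]
    if df["t"].nunique() < 2:
        raise ValueError("need at least 2 distinct timepoints")
    if df.groupby("patient")["t"].nunique().min() < 2:
        raise ValueError("every patient needs at least 2 timepoints")

    fixed = "y ~ C(t)" if spec.time_as_factor else "y ~ t"
    vc = {"segment": "0 + C(segment)"} if spec.segment_intercept else None

    def _fit(re_formula: str):
        model = smf.mixedlm(fixed, df, groups=df["patient"],
                            re_formula=re_formula, vc_formula=vc)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return model.fit(reml=True)

    structure = "patient intercept+slope" if spec.random_slope else "patient intercept"
    if spec.segment_intercept:
        structure += " + segment intercept (vc)"
    res = _fit("~t" if spec.random_slope else "~1")
    converged = bool(res.converged)
    if not converged and spec.random_slope:
        res = _fit("~1")
        structure = "patient intercept (fallback)" + (
            " + segment intercept (vc)" if spec.segment_intercept else ""
        )
        converged = bool(res.converged)

    if spec.time_as_factor:
        # report the last-level contrast as the headline coefficient
        name = [p for p in res.params.index if p.startswith("C(t)")][-1]
    else:
        name = "t"
    # t-based inference with between-patient df: with a random slope the
    # time effect is informed by the patient-level slopes, so the normal
    # Wald interval undercovers badly at 6 patients
    df_t = max(df["patient"].nunique() - 1, 1)
    est, se = float(res.params[name]), float(res.bse[name])
    tcrit = sps.t.ppf(0.975, df_t)
    ci = (est - tcrit * se, est + tcrit * se)
    p_val = 2 * sps.t.sf(abs(est / se), df_t) if se > 0 else 0.0
    random_variances = {}
    cov_re = res.cov_re
    for i, rn in enumerate(cov_re.index):
        random_variances[f"patient_{rn}"] = float(cov_re.iloc[i, i])
    if vc is not None and hasattr(res, "vcomp") and len(res.vcomp):
        random_variances["segment_intercept"] = float(res.vcomp[0])
    random_variances["residual"] = float(res.scale)

    times = sorted(df["t"].unique())
    if spec.time_as_factor:
        base = res.params["Intercept"]
        group_means = {}
        for t in times:
            key = f"C(t)[T.{t}]"
            group_means[float(t)] = float(base + res.params.get(key, 0.0))
    else:
        group_means = {
            float(t): float(res.params["Intercept"] + res.params["t"] * t)
            for t in times
        }

    return LmmResult(
        fixed_slope=est,
        slope_se=se,
        slope_p=float(p_val),
        slope_ci=(float(ci[0]), float(ci[1])),
        random_variances=random_variances,
        group_means=group_means,
        n_obs=len(df),
        n_dropped=n_in - len(df),
        converged=converged,
        structure=structure,
    )
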