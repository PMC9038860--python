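"""Cohort-level statistics for the marrow-infiltration analysis.

The core model regresses the logit-transformed biopsy infiltration fraction
on the non-fatty portion of bone marrow with bone mineral density (BMD) as a
control covariate.  Inference uses White-style heteroskedasticity-consistent
covariance (HC1 by default) with a Student-t reference; a Breusch-Pagan test documents
the heteroskedasticity that motivates it, and variance inflation factors
screen for collinearity.  Threshold-based prediction of osteolytic lesions
and of the myeloma diagnosis is assessed by ROC analysis with a Youden
operating point, DeLong confidence bands, and post-hoc power under
Obuchowski's binormal variance model.  Inter-reader BMD agreement is
summarised by the single-rater two-way random-effects intraclass
correlation, ICC(2,1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_auc_score

__all__ = [
    "RegressionResult",
    "ROCResult",
    "ConfusionMetrics",
    "PowerSpec",
    "DecisionRule",
    "logit_bounded",
    "fit_infiltration_model",
    "breusch_pagan",
    "roc_youden",
    "confusion_metrics",
    "white_hc0",
    "roc_power",
    "regression_sample_size",
    "icc2",
    "majority_vote",
    "binarize_diagnosis",
]

#: decision cutoff on the non-fatty portion (%) for lesion / diagnosis calls
DEFAULT_CUTOFF_PERCENT = 0.93
#: MGUS is defined by biopsy infiltration below 10%
MGUS_INFILTRATION_THRESHOLD = 0.10


@dataclass(frozen=True)
class DecisionRule:
    """Call a patient positive when the non-fatty portion exceeds the cutoff."""

    cutoff_percent: float = DEFAULT_CUTOFF_PERCENT

    def __post_init__(self) -> None:
        if self.cutoff_percent < 0:
            raise ValueError("cutoff must be non-negative")

    def __call__(self, non_fatty_percent: float | np.ndarray) -> np.ndarray:
        return (np.asarray(non_fatty_percent) > self.cutoff_percent).astype(int)


def logit_bounded(y: float | np.ndarray, n: int) -> float | np.ndarray:
    """Boundary-safe log-odds of a fraction.

    Applies the Smithson-Verkuilen compression ``(y (n - 1) + 0.5) / n``
    uniformly before the logit, so 0 and 1 map to finite values that shrink
    toward the boundary as the sample grows.
    """
    if n < 2:
        raise ValueError("compression needs a sample size of at least 2")
    y = np.asarray(y, dtype=float)
    if np.any((y < 0) | (y > 1)):
        raise ValueError("fractions must lie in [0, 1]")
    z = (y * (n - 1) + 0.5) / n
    out = np.log(z / (1.0 - z))
    return float(out) if out.ndim == 0 else out


def breusch_pagan(design: np.ndarray, residuals: np.ndarray) -> tuple[float, float]:
    """Breusch-Pagan LM test: n R^2 of squared residuals on the design.

    ``design`` must include the constant column.  The statistic is referred
    to a chi-square with as many degrees of freedom as non-constant
    regressors.  Constant residuals give (0, 1).
    """
    design = np.asarray(design, dtype=float)
    residuals = np.asarray(residuals, dtype=float)
    e2 = residuals**2
    if np.allclose(e2, e2[0]):
        return 0.0, 1.0
    n = design.shape[0]
    aux = sm.OLS(e2, design).fit()
    k = int(np.linalg.matrix_rank(design)) - 1
    stat = n * aux.rsquared
    return float(stat), float(stats.chi2.sf(stat, k))


@dataclass
class RegressionResult:
    """Bounded-response regression with White-robust inference."""

    params: dict[str, float]
    robust_se: dict[str, float]
    p_values: dict[str, float]
    partial_r: float
    semipartial_r: float
    model_r: float
    vif: dict[str, float]
    bp_stat: float
    bp_p: float
    n: int
    main_predictor: str = "non_fatty_percent"


def _partial_correlations(
    y: np.ndarray, x: np.ndarray, z: np.ndarray
) -> tuple[float, float]:
    """(partial, semipartial) correlation of x with y controlling z."""
    zc = sm.add_constant(z)
    ry = y - zc @ np.linalg.lstsq(zc, y, rcond=None)[0]
    rx = x - zc @ np.linalg.lstsq(zc, x, rcond=None)[0]
    partial = float(np.corrcoef(ry, rx)[0, 1])
    semipartial = float(np.corrcoef(y, rx)[0, 1])
    return partial, semipartial


def white_hc0(X: np.ndarray, residuals: np.ndarray) -> np.ndarray:
    """White's original heteroskedasticity-consistent covariance (HC0).

    The textbook sandwich ``(X'X)^-1 X' diag(e^2) X (X'X)^-1``; no
    small-sample correction.
    """
    X = np.asarray(X, dtype=float)
    e = np.asarray(residuals, dtype=float)
    bread = np.linalg.inv(X.T @ X)
    meat = X.T @ (X * (e**2)[:, None])
    return bread @ meat @ bread


def fit_infiltration_model(
    t: pd.DataFrame,
    response: str = "infiltration",
    main: str = "non_fatty_percent",
    covariates: Sequence[str] = ("bmd_mg_ml",),
    cov_type: str = "HC1",
) -> RegressionResult:
    """OLS of the logit-compressed infiltration on the non-fatty portion + BMD.

    White-robust covariance (Student-t reference, n - k df) for the reported
    standard errors and p-values; the default HC1 variant carries the
    ``n / (n - k)`` degrees-of-freedom correction, which keeps the test of
    the main predictor close to its nominal size at study-scale n while
    remaining consistent under heteroskedasticity (HC0/HC2/HC3 selectable).
    Breusch-Pagan on the squared residuals of the unweighted fit; variance
    inflation factors per predictor; partial, semipartial and whole-model
    correlations for the main predictor.
    """
    cols = [response, main, *covariates]
    data = t[cols].dropna()
    n = len(data)
    if n < 10:
        raise ValueError(f"need at least 10 complete cases, found {n}")
    y = logit_bounded(data[response].to_numpy(), n)
    predictors = [main, *covariates]
    X = sm.add_constant(data[predictors].to_numpy())
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design (duplicated or constant predictor)")

    ols = sm.OLS(y, X)
    plain = ols.fit()
    robust = ols.fit(cov_type=cov_type, use_t=True)

    names = ["const", *predictors]
    bp_stat, bp_p = breusch_pagan(X, plain.resid)
    vif = {}
    for j, name in enumerate(predictors, start=1):
        others = np.delete(X, j, axis=1)
        r2 = sm.OLS(X[:, j], others).fit().rsquared
        vif[name] = float(1.0 / (1.0 - r2)) if r2 < 1 else math.inf
    partial, semipartial = _partial_correlations(
        y, data[main].to_numpy().astype(float), data[list(covariates)].to_numpy().astype(float)
    )
    return RegressionResult(
        params=dict(zip(names, map(float, robust.params))),
        robust_se=dict(zip(names, map(float, robust.bse))),
        p_values=dict(zip(names, map(float, robust.pvalues))),
        partial_r=partial,
        semipartial_r=semipartial,
        model_r=float(np.sqrt(max(plain.rsquared, 0.0))),
        vif=vif,
        bp_stat=bp_stat,
        bp_p=bp_p,
        n=n,
        main_predictor=main,
    )


# --------------------------------------------------------------------------
# ROC / decision analysis


@dataclass
class ROCResult:
    auc: float
    ci95: tuple[float, float]
    youden_threshold: float
    sensitivity: float
    specificity: float
    power_at_alpha: float | None = None
    alpha: float = 0.05


def _delong_ci(scores: np.ndarray, labels: np.ndarray, auc: float) -> tuple[float, float]:
    """DeLong 95% interval from case/control placement values."""
    x = scores[labels == 1]
    y = scores[labels == 0]
    psi = (x[:, None] > y[None, :]).astype(float) + 0.5 * (x[:, None] == y[None, :])
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    var = 0.0
    if len(x) > 1:
        var += np.var(v10, ddof=1) / len(x)
    if len(y) > 1:
        var += np.var(v01, ddof=1) / len(y)
    half = stats.norm.ppf(0.975) * math.sqrt(max(var, 0.0))
    return float(max(auc - half, 0.0)), float(min(auc + half, 1.0))


def roc_youden(
    scores: np.ndarray, labels: np.ndarray, alpha: float = 0.05, compute_power: bool = True
) -> ROCResult:
    """Empirical ROC with the Youden operating point.

    Candidate thresholds sit midway between adjacent observed scores (plus
    sentinels outside the range); a case is called positive when its score
    strictly exceeds the threshold.  Ties in Youden's J are broken toward the
    higher threshold, i.e. toward specificity.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    auc = float(roc_auc_score(labels, scores))

    u = np.unique(scores)
    candidates = np.concatenate([[u[0] - 1.0], (u[:-1] + u[1:]) / 2.0, [u[-1] + 1.0]])
    pos = labels == 1
    best = None
    for thr in candidates:
        called = scores > thr
        sens = called[pos].mean()
        spec = (~called)[~pos].mean()
        j = sens + spec - 1.0
        # equal J: the later (larger) candidate wins, favouring specificity
        if best is None or j >= best[0]:
            best = (j, thr, sens, spec)
    j, thr, sens, spec = best
    power = None
    if compute_power and pos.sum() >= 2 and (~pos).sum() >= 2:
        effective = min(max(auc, 0.5), 1.0 - 1e-9)
        power = roc_power(effective, int(pos.sum()), int((~pos).sum()), alpha)
    return ROCResult(
        auc=auc,
        ci95=_delong_ci(scores, labels, auc),
        youden_threshold=float(thr),
        sensitivity=float(sens),
        specificity=float(spec),
        power_at_alpha=power,
        alpha=alpha,
    )


def _round_half_up(x: float, ndigits: int) -> float:
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMetrics:
    sensitivity: float
    specificity: float
    accuracy: float
    sensitivity_fraction: tuple[int, int]
    specificity_fraction: tuple[int, int]

    def rounded(self, ndigits: int = 2) -> tuple[float, float]:
        # half-up, the convention used when such rates are printed (5/8 -> 0.63)
        return _round_half_up(self.sensitivity, ndigits), _round_half_up(
            self.specificity, ndigits
        )


def confusion_metrics(tp: int, fn: int, tn: int, fp: int) -> ConfusionMetrics:
    """Sensitivity/specificity with their exact count fractions."""
    if min(tp, fn, tn, fp) < 0:
        raise ValueError("counts must be non-negative")
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("both outcome margins must be non-empty")
    total = tp + fn + tn + fp
    return ConfusionMetrics(
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        accuracy=(tp + tn) / total,
        sensitivity_fraction=(tp, tp + fn),
        specificity_fraction=(tn, tn + fp),
    )


def _obuchowski_variance(theta: float, kappa: float) -> float:
    """Obuchowski's binormal variance function for continuous ratings.

    ``kappa`` is the control-to-case ratio; the returned value is the
    per-case variance coefficient of the empirical AUC.
    """
    a = stats.norm.ppf(theta) * math.sqrt(2.0)
    return (0.0099 * math.exp(-(a**2) / 2.0)) * ((5 * a**2 + 8) + (a**2 + 8) / kappa)


def roc_power(auc: float, n_cases: int, n_controls: int, alpha: float = 0.05) -> float:
    """Post-hoc power of the two-sided test that the AUC differs from 0.5.

    Null variance is evaluated at AUC 0.5 and the alternative variance at the
    stated AUC, both with Obuchowski's function; both rejection tails are
    counted, so power equals alpha exactly on the null boundary.
    """
    if not 0.5 <= auc < 1.0:
        raise ValueError("auc must lie in [0.5, 1)")
    if min(n_cases, n_controls) < 2:
        raise ValueError("need at least 2 cases and 2 controls")
    kappa = n_controls / n_cases
    v0 = _obuchowski_variance(0.5, kappa)
    va = _obuchowski_variance(auc, kappa)
    za = stats.norm.ppf(1.0 - alpha / 2.0)
    shift = math.sqrt(n_cases) * (auc - 0.5)
    upper = stats.norm.cdf((shift - za * math.sqrt(v0)) / math.sqrt(va))
    lower = stats.norm.cdf((-shift - za * math.sqrt(v0)) / math.sqrt(va))
    return float(upper + lower)


@dataclass(frozen=True)
class PowerSpec:
    """Regression sample-size planning inputs (Cohen's f^2 effect size)."""

    f2: float = 0.32
    alpha: float = 0.05
    power: float = 0.8
    n_predictors: int = 2

    def __post_init__(self) -> None:
        if self.f2 <= 0:
            raise ValueError("effect size must be positive")
        if not 0 < self.alpha < 1 or not 0 < self.power < 1:
            raise ValueError("alpha and power must lie in (0, 1)")
        if self.n_predictors < 1:
            raise ValueError("need at least one predictor")


def regression_sample_size(ps: PowerSpec, max_n: int = 1_000_000) -> int:
    """Smallest n whose noncentral-F power for the 1-df main-predictor test
    reaches the target (noncentrality f^2 * n, denominator df n - p - 1)."""
    n = ps.n_predictors + 2
    while n <= max_n:
        df2 = n - ps.n_predictors - 1
        crit = stats.f.ppf(1.0 - ps.alpha, 1, df2)
        if 1.0 - stats.ncf.cdf(crit, 1, df2, ps.f2 * n) >= ps.power:
            return n
        n += 1
    raise ValueError("target power unreachable within the search limit")


def icc2(ratings: np.ndarray) -> float:
    """ICC(2,1): single-rater agreement, two-way random-effects ANOVA."""
    ratings = np.asarray(ratings, dtype=float)
    if ratings.ndim != 2:
        raise ValueError("ratings must be subjects x raters")
    n, k = ratings.shape
    if k < 2 or n < 3:
        raise ValueError("need at least 2 raters and 3 subjects")
    if np.isnan(ratings).any():
        raise ValueError("missing cells are not supported")
    grand = ratings.mean()
    if np.allclose(ratings, grand):
        raise ValueError("zero total variance")
    row_means = ratings.mean(axis=1)
    col_means = ratings.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((ratings - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return float((msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n))


def majority_vote(calls: Sequence[int]) -> int:
    """Binary consensus of exactly three reader calls."""
    if len(calls) != 3:
        raise ValueError("majority vote needs exactly 3 calls")
    if any(c not in (0, 1) for c in calls):
        raise ValueError("calls must be binary")
    return int(sum(calls) >= 2)


def binarize_diagnosis(group: str, infiltration: float) -> int:
    """Myeloma-vs-MGUS outcome; smoldering myeloma joins the myeloma group
    when its biopsy infiltration reaches the 10% MGUS threshold."""
    if group == "MM":
        return 1
    if group == "SMM":
        return int(infiltration >= MGUS_INFILTRATION_THRESHOLD)
    if group == "MGUS":
        return 0
    raise ValueError(f"unknown diagnosis group {group!r}")
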