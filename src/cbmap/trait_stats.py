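"""Inference statistics, normality assessment and outlier detection for traits.

Regression-based prediction of crop traits leans on normally distributed
errors, so before any model is enounced each trait vector is summarized and
its distribution checked against the normal via quantile-quantile analysis.
Outliers — extreme field measurements from sensor noise or handling errors —
are detected with studentized deleted (leave-one-out externally studentized)
residuals; the policy is identification and reporting, never silent removal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import OLSInfluence

from .exceptions import FitError, InputError

__all__ = [
    "InferenceStats",
    "NormalityReport",
    "OutlierReport",
    "summarize",
    "assess_normality",
    "studentized_deleted_residuals",
    "RATING_THRESHOLDS",
]

#: r_qq thresholds for the qualitative normality rating.  Tunable: a stricter
#: laboratory could demand 0.999 for "very strong".
RATING_THRESHOLDS = {"very strong": 0.995, "strong": 0.98}


@dataclass(frozen=True)
class InferenceStats:
    """Order statistics, moments and a qualitative normality rating."""

    n: int
    max: float
    min: float
    mean: float
    median: float
    sd: float
    normality_rating: str


@dataclass(frozen=True)
class NormalityReport:
    """Paired sample/theoretical quantiles and their correlation.

    ``r_qq`` is the Pearson correlation between the sorted standardized data
    and standard-normal quantiles at plotting positions (k - 0.5)/n; near-unit
    values indicate the approximate linearity of the quantile-quantile plot
    expected under normal errors.
    """

    sample_quantiles: np.ndarray
    theoretical_quantiles: np.ndarray
    r_qq: float
    rating: str


@dataclass(frozen=True)
class OutlierReport:
    residuals: np.ndarray
    flagged: np.ndarray
    threshold: float


def _rate(r_qq: float, thresholds: dict[str, float]) -> str:
    if r_qq >= thresholds["very strong"]:
        return "very strong"
    if r_qq >= thresholds["strong"]:
        return "strong"
    return "weak"


def summarize(values, thresholds: dict[str, float] | None = None) -> InferenceStats:
    """Inference statistics for one trait vector (sample sd, n - 1 denominator)."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise InputError("summarize requires a 1-d vector with n >= 2")
    if not np.all(np.isfinite(x)):
        raise InputError("trait values must be finite")
    if x.size >= 8 and np.std(x) > 0:
        rating = assess_normality(x, thresholds=thresholds).rating
    else:
        rating = "weak"
    return InferenceStats(
        n=int(x.size),
        max=float(x.max()),
        min=float(x.min()),
        mean=float(x.mean()),
        median=float(np.median(x)),
        sd=float(x.std(ddof=1)),
        normality_rating=rating,
    )


def assess_normality(values, thresholds: dict[str, float] | None = None) -> NormalityReport:
    """Quantile-quantile normality check of a trait vector.

    The data are standardized by their mean and sample sd, sorted, and paired
    with standard-normal quantiles at plotting positions (k - 0.5)/n.  The
    Pearson correlation of the pairs quantifies the linearity of the normal
    Q-Q plot; the qualitative rating discretizes it.
    """
    thresholds = thresholds or RATING_THRESHOLDS
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 8:
        raise InputError("assess_normality requires a 1-d vector with n >= 8")
    n = x.size
    theo = sps.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    sd = x.std(ddof=1)
    if sd == 0:
        return NormalityReport(
            sample_quantiles=np.zeros(n),
            theoretical_quantiles=theo,
            r_qq=0.0,
            rating="weak",
        )
    z = np.sort((x - x.mean()) / sd)
    r_qq = float(np.corrcoef(z, theo)[0, 1])
    return NormalityReport(
        sample_quantiles=z, theoretical_quantiles=theo,
        r_qq=r_qq, rating=_rate(r_qq, thresholds),
    )


def studentized_deleted_residuals(
    design,
    response,
    add_intercept: bool = True,
    alpha: float = 0.05,
) -> OutlierReport:
    """Leave-one-out externally studentized residuals with a Bonferroni flag.

    Each residual is scaled by an error variance estimated with that
    observation deleted, so a gross outlier cannot inflate its own yardstick.
    Observation ``i`` is flagged when |t_i| exceeds the two-sided t quantile at
    level ``alpha / n`` (Bonferroni over the n look-ups) with n - p - 2
    degrees of freedom, p being the number of predictors.
    """
    X = np.atleast_2d(np.asarray(design, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and np.asarray(response).size == X.shape[1]:
        X = X.T
    y = np.asarray(response, dtype=float)
    if add_intercept:
        X = sm.add_constant(X, has_constant="add")
    n, k = X.shape
    if n <= k + 1:
        raise FitError(f"need n > p + 1 observations (n={n}, parameters={k})")
    if np.linalg.matrix_rank(X) < k:
        raise FitError("singular design matrix")
    fit = sm.OLS(y, X).fit()
    # a numerically exact fit has nothing to studentize: every deleted-fit
    # error variance is 0/0 noise, and no observation is extreme
    scale = float(np.sum(y**2)) or 1.0
    if fit.ssr <= 1e-24 * scale:
        resid = np.zeros(n)
    else:
        resid = np.nan_to_num(
            np.asarray(OLSInfluence(fit).resid_studentized_external), nan=0.0)
    df = n - k - 1
    threshold = float(sps.t.ppf(1.0 - alpha / (2.0 * n), df))
    return OutlierReport(
        residuals=resid, flagged=np.abs(resid) > threshold, threshold=threshold
    )
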