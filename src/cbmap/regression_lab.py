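"""Model fitting, goodness-of-fit metrics and model selection for CB traits.

Crop prediction models are statistical, not mechanistic: candidate families
(linear, polynomial, logarithmic, reciprocal, power) are fitted by least
squares and scored with two coefficients of determination —

* ``R^2 = 1 - SSE/SST`` about the arithmetic mean of the observed response,
  valid for linear and nonlinear fits alike when evaluated on the original
  response scale, and
* a *resistant* ``R^2_res = 1 - (median|y - yhat| / median|y - center|)^2``
  that swaps the means for medians, so a handful of gross field outliers
  cannot dominate the score —

together with the ANOVA F statistic and per-term t statistics at the 95%
level.  Model selection is rule-based: candidates with non-significant terms
are discarded first, then candidates failing physical boundary checks (e.g.
zero yield at zero vegetation), and survivors are ranked by resistant R^2.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Callable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import curve_fit
import statsmodels.api as sm

from .exceptions import DomainError, FitError, InputError, InsufficientDataError

__all__ = [
    "AnovaTable",
    "ModelSpec",
    "FittedModel",
    "Standardizer",
    "CoherenceResult",
    "SelectionResult",
    "r_squared",
    "r_squared_resistant",
    "fit",
    "standardize",
    "coherence_analysis",
    "select_model",
]

SIGNIFICANCE_LEVEL = 0.05  # all inference at the 95% confidence level


# ---------------------------------------------------------------------------
# goodness-of-fit metrics
# ---------------------------------------------------------------------------

def r_squared(y, yhat) -> float:
    """Coefficient of determination 1 - SSE/SST about the mean of ``y``.

    Computed on the original response scale for every model family, which
    keeps scores comparable across linear and nonlinear candidates; it may be
    negative for a fit worse than the constant mean.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.size < 2:
        raise InputError("r_squared needs two equal-length vectors with n >= 2")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise DomainError("R^2 undefined for a constant response")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / sst


def r_squared_resistant(
    y, yhat, center: Literal["median", "mean"] = "median"
) -> float:
    """Resistant coefficient of determination.

    ``1 - (median|y - yhat| / median|y - c|)^2`` with ``c`` the sample median
    of ``y`` (a mean-centred variant is kept for sensitivity checks).  Because
    both numerator and denominator are medians of absolute deviations, moving
    any single observation arbitrarily far leaves the score unchanged as long
    as its residual rank stays above the median.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.size < 2:
        raise InputError("r_squared_resistant needs equal-length vectors, n >= 2")
    c = float(np.median(y)) if center == "median" else float(y.mean())
    denom = float(np.median(np.abs(y - c)))
    if denom == 0:
        raise DomainError("resistant R^2 undefined: median absolute deviation is 0")
    num = float(np.median(np.abs(y - yhat)))
    return 1.0 - (num / denom) ** 2


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------

_TERM_RE = re.compile(
    r"""^(?:
        ln\((?P<log>\w+)\)            |   # ln(X1)
        1/(?P<recip>\w+)              |   # 1/X1
        (?P<cube>\w+)\^3              |   # X1^3
        (?P<square>\w+)\^2            |   # X1^2
        (?P<prod_a>\w+)\*(?P<prod_b>\w+) |  # X1*X3
        (?P<ident>\w+)                    # X1
    )$""",
    re.VERBOSE,
)


def _term_traits(term: str) -> tuple[str, ...]:
    m = _TERM_RE.match(term.replace(" ", ""))
    if m is None:
        raise InputError(f"cannot parse model term {term!r}")
    d = m.groupdict()
    if d["prod_a"]:
        return (d["prod_a"], d["prod_b"])
    for key in ("log", "recip", "cube", "square", "ident"):
        if d[key]:
            return (d[key],)
    raise InputError(f"cannot parse model term {term!r}")  # pragma: no cover


def _eval_term(term: str, data: Mapping[str, np.ndarray]) -> np.ndarray:
    m = _TERM_RE.match(term.replace(" ", ""))
    assert m is not None
    d = m.groupdict()
    if d["log"]:
        x = np.asarray(data[d["log"]], dtype=float)
        if np.any(x <= 0):
            raise DomainError(f"ln({d['log']}) requires positive values")
        return np.log(x)
    if d["recip"]:
        x = np.asarray(data[d["recip"]], dtype=float)
        if np.any(x == 0):
            raise DomainError(f"1/{d['recip']} requires nonzero values")
        return 1.0 / x
    if d["cube"]:
        return np.asarray(data[d["cube"]], dtype=float) ** 3
    if d["square"]:
        return np.asarray(data[d["square"]], dtype=float) ** 2
    if d["prod_a"]:
        return np.asarray(data[d["prod_a"]], dtype=float) * np.asarray(
            data[d["prod_b"]], dtype=float
        )
    return np.asarray(data[d["ident"]], dtype=float)


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one candidate model.

    ``family="ols"`` models are linear in the parameters over transformed
    terms (identity, square, cube, product, reciprocal, natural log of a
    predictor); ``family="power"`` is the intrinsically nonlinear
    ``y = a * x^b`` on a single predictor.  ``domain`` bounds the predictor
    interval within which predictions are considered valid.
    """

    response_id: str
    terms: tuple[str, ...] = ()
    family: Literal["ols", "power"] = "ols"
    predictor: str | None = None
    intercept: bool = True
    domain: tuple[float, float] | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.family == "power":
            if self.predictor is None:
                raise InputError("power family requires a predictor symbol")
        elif not self.terms and not self.intercept:
            raise InputError("a model needs at least one term or an intercept")
        if self.domain is not None and self.domain[0] >= self.domain[1]:
            raise InputError("model domain must be a non-empty interval")

    @property
    def required_traits(self) -> tuple[str, ...]:
        if self.family == "power":
            traits: tuple[str, ...] = (self.predictor,)  # type: ignore[assignment]
        else:
            traits = tuple(t for term in self.terms for t in _term_traits(term))
        seen: list[str] = []
        for t in (self.response_id, *traits):
            if t not in seen:
                seen.append(t)
        return tuple(seen)


@dataclass(frozen=True)
class AnovaTable:
    """Regression ANOVA decomposition.

    For linear-in-parameters fits with an intercept the sums of squares add
    exactly (SS_total = SS_reg + SS_err); for the nonlinear power family the
    rows are the analogous original-scale quantities and the identity is only
    approximate.
    """

    df_reg: int
    ss_reg: float
    ms_reg: float
    df_err: int
    ss_err: float
    ms_err: float
    df_total: int
    ss_total: float
    f_stat: float
    p_value: float


@dataclass(frozen=True)
class FittedModel:
    """A fitted candidate with coefficients, inference and both R^2 scores."""

    spec: ModelSpec
    params: dict[str, float]
    bse: dict[str, float] | None = None
    tvalues: dict[str, float] | None = None
    pvalues: dict[str, float] | None = None
    r2: float | None = None
    r2_res: float | None = None
    anova: AnovaTable | None = None
    n: int | None = None
    predictor_range: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def n_params(self) -> int:
        return len(self.params)

    @property
    def all_terms_significant(self) -> bool | None:
        if self.pvalues is None:
            return None
        return all(p <= SIGNIFICANCE_LEVEL for p in self.pvalues.values())

    def predict(self, data: Mapping[str, np.ndarray] | pd.DataFrame) -> np.ndarray:
        if self.spec.family == "power":
            x = np.asarray(data[self.spec.predictor], dtype=float)
            if np.any(x < 0):
                raise DomainError("power model requires nonnegative predictor")
            return self.params["a"] * np.power(x, self.params["b"])
        cols = [_eval_term(t, data) for t in self.spec.terms]
        n = len(next(iter(cols))) if cols else len(
            np.asarray(data[self.spec.required_traits[-1]], dtype=float)
        )
        yhat = np.zeros(n)
        if self.spec.intercept:
            yhat += self.params["const"]
        for term, col in zip(self.spec.terms, cols):
            yhat = yhat + self.params[term] * col
        return yhat

    def predict_at(self, x) -> np.ndarray | float:
        """Evaluate a single-predictor model at predictor value(s) ``x``."""
        predictors = [t for t in self.spec.required_traits if t != self.spec.response_id]
        if len(predictors) != 1:
            raise InputError("predict_at requires a single-predictor model")
        arr = np.atleast_1d(np.asarray(x, dtype=float))
        out = self.predict({predictors[0]: arr})
        return float(out[0]) if np.isscalar(x) or np.ndim(x) == 0 else out


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _listwise(data, traits: Sequence[str]) -> pd.DataFrame:
    frame = pd.DataFrame({t: np.asarray(data[t], dtype=float) for t in traits})
    return frame.dropna()


def _fit_ols(spec: ModelSpec, frame: pd.DataFrame, r2_res_center) -> FittedModel:
    y = frame[spec.response_id].to_numpy()
    names: list[str] = []
    cols: list[np.ndarray] = []
    if spec.intercept:
        names.append("const")
        cols.append(np.ones(len(frame)))
    for term in spec.terms:
        names.append(term)
        cols.append(_eval_term(term, frame))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise FitError("singular design matrix")
    if len(frame) <= X.shape[1]:
        raise FitError("not enough rows for the number of parameters")
    res = sm.OLS(y, X).fit()
    yhat = np.asarray(res.fittedvalues)
    df_reg = len(spec.terms) if spec.intercept else X.shape[1]
    df_err = int(res.df_resid)
    ss_err = float(res.ssr)
    ss_total = float(np.sum((y - y.mean()) ** 2))
    ss_reg = ss_total - ss_err if spec.intercept else float(np.sum(yhat**2))
    ms_reg = ss_reg / df_reg if df_reg else np.nan
    ms_err = ss_err / df_err
    f_stat = (ms_reg / ms_err if ms_err > 0 else math.inf) if df_reg else np.nan
    p_value = float(sps.f.sf(f_stat, df_reg, df_err)) if df_reg else np.nan
    anova = AnovaTable(
        df_reg=df_reg, ss_reg=ss_reg, ms_reg=ms_reg,
        df_err=df_err, ss_err=ss_err, ms_err=ms_err,
        df_total=df_reg + df_err, ss_total=ss_total,
        f_stat=float(f_stat), p_value=p_value,
    )
    return FittedModel(
        spec=spec,
        params=dict(zip(names, map(float, res.params))),
        bse=dict(zip(names, map(float, res.bse))),
        tvalues=dict(zip(names, map(float, res.tvalues))),
        pvalues=dict(zip(names, map(float, res.pvalues))),
        r2=r_squared(y, yhat),
        r2_res=r_squared_resistant(y, yhat, center=r2_res_center),
        anova=anova,
        n=len(frame),
        predictor_range={
            t: (float(frame[t].min()), float(frame[t].max()))
            for t in spec.required_traits if t != spec.response_id
        },
    )


def _fit_power(spec: ModelSpec, frame: pd.DataFrame, r2_res_center) -> FittedModel:
    y = frame[spec.response_id].to_numpy()
    x = frame[spec.predictor].to_numpy()
    if np.any(x <= 0) or np.any(y <= 0):
        raise DomainError("power family requires positive predictor and response")
    if len(frame) < 3:
        raise FitError("power fit needs at least 3 rows")
    # log-log OLS initializer; the definitive estimate is nonlinear least
    # squares on the original response scale
    slope, intercept = np.polyfit(np.log(x), np.log(y), 1)
    p0 = (math.exp(intercept), slope)
    popt, pcov = curve_fit(
        lambda xx, a, b: a * np.power(xx, b), x, y, p0=p0,
        maxfev=200 * 10, xtol=1e-10, ftol=1e-10,
    )
    a, b = map(float, popt)
    yhat = a * np.power(x, b)
    n = len(frame)
    df_reg, df_err = 1, n - 2
    ss_err = float(np.sum((y - yhat) ** 2))
    ss_reg = float(np.sum((yhat - y.mean()) ** 2))
    ss_total = float(np.sum((y - y.mean()) ** 2))
    ms_reg, ms_err = ss_reg / df_reg, ss_err / df_err
    f_stat = ms_reg / ms_err if ms_err > 0 else math.inf  # exact fit
    anova = AnovaTable(
        df_reg=df_reg, ss_reg=ss_reg, ms_reg=ms_reg,
        df_err=df_err, ss_err=ss_err, ms_err=ms_err,
        df_total=n - 1, ss_total=ss_total,
        f_stat=f_stat, p_value=float(sps.f.sf(f_stat, df_reg, df_err)),
    )
    se = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    tvals = {k: (v / s if s > 0 else np.inf) for (k, v), s in zip({"a": a, "b": b}.items(), se)}
    pvals = {k: float(2 * sps.t.sf(abs(t), df_err)) for k, t in tvals.items()}
    return FittedModel(
        spec=spec,
        params={"a": a, "b": b},
        bse={"a": float(se[0]), "b": float(se[1])},
        tvalues={k: float(v) for k, v in tvals.items()},
        pvalues=pvals,
        r2=r_squared(y, yhat),
        r2_res=r_squared_resistant(y, yhat, center=r2_res_center),
        anova=anova,
        n=n,
        predictor_range={spec.predictor: (float(x.min()), float(x.max()))},
    )


def fit(
    spec: ModelSpec,
    data,
    r2_res_center: Literal["median", "mean"] = "median",
) -> FittedModel:
    """Fit a candidate model on a trait table.

    ``data`` is any mapping of trait symbol to vector (a DataFrame of cell
    values, typically).  Rows with a missing value in any required trait are
    dropped listwise — correlation happens only among cells that actually
    store data.  Linear-in-parameters families go through ordinary least
    squares on the transformed design; the power family through nonlinear
    least squares initialized from a log-log OLS fit.  Both R^2 scores are
    always evaluated on the original response scale.
    """
    frame = _listwise(data, spec.required_traits)
    if spec.family == "power":
        return _fit_power(spec, frame, r2_res_center)
    return _fit_ols(spec, frame, r2_res_center)


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Standardizer:
    """Location/scale transform ``z = (x - center) / scale``."""

    center: float
    scale: float

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise InputError("standardizer scale must be positive")

    @classmethod
    def from_data(cls, values) -> "Standardizer":
        x = np.asarray(values, dtype=float)
        x = x[np.isfinite(x)]
        return cls(center=float(x.mean()), scale=float(x.std(ddof=1)))


def standardize(values, s: Standardizer) -> np.ndarray:
    return (np.asarray(values, dtype=float) - s.center) / s.scale


# ---------------------------------------------------------------------------
# coherence between equivalent traits
# ---------------------------------------------------------------------------

_POLY_TERMS = {"linear": 1, "quadratic": 2, "cubic": 3}

#: variance-ratio threshold above which the regression fallacy warning is
#: raised: when the smaller variance exceeds half the larger one the two
#: measurements vary on similar scales and a sub-unity slope must not be read
#: as attenuation.
FALLACY_VARIANCE_RATIO = 0.5


@dataclass(frozen=True)
class CoherenceResult:
    fits: tuple[FittedModel, ...]        # ranked, best resistant R^2 first
    variance_ratio: float                # smaller variance over larger
    fallacy_flag: bool


def coherence_analysis(
    trait_a,
    trait_b,
    families: Sequence[str] = ("linear", "quadratic", "cubic"),
    symbols: tuple[str, str] = ("A", "B"),
) -> CoherenceResult:
    """Correlate two equivalent quantifications of one trait.

    Fits polynomial families of ``trait_a`` on ``trait_b`` over paired
    non-missing cells, scoring each with R^2 and resistant R^2, and checks the
    variance ratio: similar variances raise the regression-fallacy flag
    because a slope below one is then the expected consequence of |r| <= 1,
    not evidence of attenuation.
    """
    a = np.asarray(trait_a, dtype=float)
    b = np.asarray(trait_b, dtype=float)
    if a.shape != b.shape:
        raise InputError("paired trait vectors must have equal length")
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.size < 10:
        raise InsufficientDataError(
            f"coherence analysis needs >= 10 paired cells, found {a.size}"
        )
    sa, sb = symbols
    data = {sa: a, sb: b}
    fits = []
    for fam in families:
        degree = _POLY_TERMS.get(fam)
        if degree is None:
            raise InputError(f"unknown coherence family {fam!r}")
        terms = tuple([sb, f"{sb}^2", f"{sb}^3"][:degree])
        spec = ModelSpec(response_id=sa, terms=terms, name=f"{fam} {sa}~{sb}")
        fits.append(fit(spec, data))
    fits.sort(key=lambda m: m.r2_res, reverse=True)
    var_a, var_b = a.var(ddof=1), b.var(ddof=1)
    hi = max(var_a, var_b)
    ratio = float(min(var_a, var_b) / hi) if hi > 0 else 1.0
    return CoherenceResult(
        fits=tuple(fits),
        variance_ratio=ratio,
        fallacy_flag=ratio >= FALLACY_VARIANCE_RATIO,
    )


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SelectionResult:
    winner: FittedModel
    ranking: tuple[FittedModel, ...]
    reasons: dict[str, list[str]]  # spec name -> audit trail


def select_model(
    candidates: Sequence[FittedModel],
    boundary_checks: Sequence[tuple[float, Callable[[float], bool]]] = (),
) -> SelectionResult:
    """Rule-based ranking of fitted candidates.

    1. Discard candidates with any term non-significant at the 95% level.
    2. Discard candidates failing a physical boundary check (each check is a
       predictor value and a predicate on the predicted response there, e.g.
       zero yield for zero vegetation).
    3. Rank survivors by resistant R^2, ties by ANOVA F, ties by fewest
       parameters.

    Every discard is recorded in the returned audit trail.  If the filters
    eliminate every candidate, the ranking falls back to all candidates so a
    winner is always produced, with the failures still on record.
    """
    if not candidates:
        raise InputError("select_model needs at least one candidate")
    reasons: dict[str, list[str]] = {}

    def _name(m: FittedModel) -> str:
        return m.spec.name or f"{m.spec.family}:{','.join(m.spec.terms) or m.spec.predictor}"

    survivors = []
    for m in candidates:
        log = reasons.setdefault(_name(m), [])
        if m.all_terms_significant is False:
            bad = [k for k, p in (m.pvalues or {}).items() if p > SIGNIFICANCE_LEVEL]
            log.append(f"discarded: non-significant term(s) {bad}")
            continue
        ok = True
        for x0, check in boundary_checks:
            try:
                y0 = m.predict_at(x0)
            except (DomainError, InputError) as exc:
                log.append(f"discarded: boundary check at x={x0} not evaluable ({exc})")
                ok = False
                break
            if not check(float(y0)):
                log.append(f"discarded: boundary check failed at x={x0} (y={y0:.4g})")
                ok = False
                break
        if ok:
            survivors.append(m)
    pool = survivors or list(candidates)
    ranked = sorted(
        pool,
        key=lambda m: (
            -(m.r2_res if m.r2_res is not None else -np.inf),
            -(m.anova.f_stat if m.anova is not None else -np.inf),
            m.n_params,
        ),
    )
    for rank, m in enumerate(ranked, start=1):
        reasons.setdefault(_name(m), []).append(
            f"ranked #{rank} (R2_res={m.r2_res:.4f}, F={m.anova.f_stat:.2f})"
            if m.r2_res is not None and m.anova is not None
            else f"ranked #{rank}"
        )
    return SelectionResult(winner=ranked[0], ranking=tuple(ranked), reasons=reasons)
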