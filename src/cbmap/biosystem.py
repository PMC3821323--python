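"""The control biosystem: vigor map in, yield and quality prediction maps out.

A vineyard season can be steered from a single automatically acquired input —
the relative vegetative vigor V-8 (%), the fraction of near-infrared image
pixels classified as vegetation — because, of all soil, plant and produce
traits examined, vigor is the only one that survives model selection for both
yield and must quality.  The biosystem packages the two selected models:

* a power law ``Y = a * X1^b`` for yield in kg per 16 m^2 cell, and
* a linear law ``QPI = c0 + c1 * X1`` for the Quality Potential Index,

and applies them cell-wise to a vigor map at either resolution.  The
reference coefficient sets estimated on the Requena (Valencia) Cabernet-
Sauvignon field study are shipped as frozen presets (``requena-2013`` for the
4 m grid, ``requena-2013-low`` for the 8 m grid), so the canonical worked
examples are pinned independently of any refit.

Predictions outside the fitted vigor interval [0, 100] raise an error rather
than a warning: a statistical model's validity cannot be guaranteed outside
its working interval, so extrapolation is refused outright.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .exceptions import ExtrapolationError, InputError, InsufficientDataError
from .geogrid import CBMap
from .regression_lab import FittedModel, ModelSpec, r_squared, r_squared_resistant

__all__ = [
    "Biosystem",
    "PRESETS",
    "load_preset",
    "predict_yield",
    "predict_qpi",
    "optimal_vigor",
    "run_biosystem",
    "compare_predictions",
    "ComparisonResult",
    "model_to_json",
    "model_from_json",
]

VIGOR_DOMAIN = (0.0, 100.0)


def _power_model(name: str, a: float, b: float) -> FittedModel:
    return FittedModel(
        spec=ModelSpec(
            response_id="Xy", family="power", predictor="X1",
            domain=VIGOR_DOMAIN, name=name,
        ),
        params={"a": a, "b": b},
        predictor_range={"X1": VIGOR_DOMAIN},
    )


def _linear_model(name: str, response: str, intercept: float, slope: float) -> FittedModel:
    return FittedModel(
        spec=ModelSpec(
            response_id=response, terms=("X1",), domain=VIGOR_DOMAIN, name=name,
        ),
        params={"const": intercept, "X1": slope},
        predictor_range={"X1": VIGOR_DOMAIN},
    )


@dataclass(frozen=True)
class Biosystem:
    """A pair of selected prediction models sharing the vigor predictor X1."""

    yield_model: FittedModel
    qpi_model: FittedModel
    resolution_tag: str = "high"

    def __post_init__(self) -> None:
        for m in (self.yield_model, self.qpi_model):
            preds = [t for t in m.spec.required_traits if t != m.spec.response_id]
            if preds != ["X1"]:
                raise InputError("biosystem models must use the single predictor X1")


#: Frozen coefficient sets from the Requena field study: the selected
#: high-resolution (4 m cells) and low-resolution (8 m cells) yield power laws
#: and linear QPI laws.
PRESETS: dict[str, Biosystem] = {
    "requena-2013": Biosystem(
        yield_model=_power_model("yield-power-high", a=0.5724, b=0.5212),
        qpi_model=_linear_model("qpi-linear-high", "QPI", intercept=0.289, slope=-0.007),
        resolution_tag="high",
    ),
    "requena-2013-low": Biosystem(
        yield_model=_power_model("yield-power-low", a=1.0623, b=0.3626),
        qpi_model=_linear_model("qpi-linear-low", "QPI", intercept=0.265, slope=-0.0062),
        resolution_tag="low",
    ),
}


def load_preset(name: str) -> Biosystem:
    try:
        return PRESETS[name]
    except KeyError:
        raise InputError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None


def _check_domain(vigor, model: FittedModel) -> None:
    lo, hi = model.spec.domain or VIGOR_DOMAIN
    v = np.asarray(vigor, dtype=float)
    if np.any(v < lo) or np.any(v > hi):
        raise ExtrapolationError(
            f"vigor outside the model's validity interval [{lo}, {hi}]"
        )


def predict_yield(vigor, model: FittedModel):
    """Predicted yield (kg per 16 m^2) at V-8 vigor percentage(s)."""
    _check_domain(vigor, model)
    return model.predict_at(vigor)


def predict_qpi(vigor, model: FittedModel):
    """Predicted Quality Potential Index at V-8 vigor percentage(s)."""
    _check_domain(vigor, model)
    return model.predict_at(vigor)


def optimal_vigor(qpi_model: FittedModel) -> float | None:
    """The vigor percentage at which predicted QPI crosses 0 (best quality).

    Returns the exact root within [0, 100] (display rounding is left to the
    caller), or ``None`` when the model never reaches QPI = 0 in its domain.
    """
    lo, hi = qpi_model.spec.domain or VIGOR_DOMAIN
    f = lambda x: float(qpi_model.predict_at(x))
    f_lo, f_hi = f(lo), f(hi)
    if f_lo == 0.0:
        return float(lo)
    if f_hi == 0.0:
        return float(hi)
    if f_lo * f_hi > 0:
        return None
    return float(brentq(f, lo, hi, xtol=1e-10))


def run_biosystem(vigor_map: CBMap, b: Biosystem) -> tuple[CBMap, CBMap]:
    """Apply the biosystem to a vigor map, yielding prediction maps.

    Missing vigor cells stay missing in both outputs.  Cells outside the
    models' vigor domain are skipped (left missing) with a warning — they
    indicate an upstream data problem, not a predictable state.
    """
    v = vigor_map.values
    lo, hi = b.yield_model.spec.domain or VIGOR_DOMAIN
    ok = ~np.isnan(v)
    out_of_range = ok & ((v < lo) | (v > hi))
    if out_of_range.any():
        warnings.warn(
            f"{int(out_of_range.sum())} vigor cell(s) outside [{lo}, {hi}] "
            "were skipped",
            stacklevel=2,
        )
    usable = ok & ~out_of_range
    yield_values = np.full(v.shape, np.nan)
    qpi_values = np.full(v.shape, np.nan)
    if usable.any():
        yield_values[usable] = b.yield_model.predict_at(v[usable])
        qpi_values[usable] = b.qpi_model.predict_at(v[usable])
    n_obs = np.where(usable, vigor_map.n_obs, 0)
    yield_map = CBMap(grid=vigor_map.grid, trait_id="Xy", units="kg/16 m^2",
                      values=yield_values, n_obs=n_obs.copy())
    qpi_map = CBMap(grid=vigor_map.grid, trait_id="QPI", units="",
                    values=qpi_values, n_obs=n_obs.copy())
    return yield_map, qpi_map


@dataclass(frozen=True)
class ComparisonResult:
    residual_map: CBMap               # measured - predicted
    r2: float
    r2_res: float
    relative_error_at_max: float      # (measured - predicted)/measured at measured max
    n_paired: int


def compare_predictions(pred_map: CBMap, measured_map: CBMap) -> ComparisonResult:
    """Score a prediction map against ground-truth measurements, cell-wise."""
    if pred_map.grid != measured_map.grid:
        raise InputError("prediction and measurement maps must share one grid")
    ok = ~(np.isnan(pred_map.values) | np.isnan(measured_map.values))
    if not ok.any():
        raise InsufficientDataError("no paired non-missing cells to compare")
    residuals = np.full(pred_map.grid.shape, np.nan)
    residuals[ok] = measured_map.values[ok] - pred_map.values[ok]
    y = measured_map.values[ok]
    yhat = pred_map.values[ok]
    i_max = int(np.argmax(y))
    rel_err = float((y[i_max] - yhat[i_max]) / y[i_max])
    residual_map = CBMap(
        grid=pred_map.grid, trait_id=f"resid({measured_map.trait_id})",
        units=measured_map.units, values=residuals,
        n_obs=np.where(ok, np.maximum(measured_map.n_obs, 1), 0),
    )
    return ComparisonResult(
        residual_map=residual_map,
        r2=r_squared(y, yhat),
        r2_res=r_squared_resistant(y, yhat),
        relative_error_at_max=rel_err,
        n_paired=int(ok.sum()),
    )


# ---------------------------------------------------------------------------
# JSON (de)serialization of model presets
# ---------------------------------------------------------------------------

def model_to_json(model: FittedModel, note: str = "") -> str:
    payload = {
        "family": model.spec.family,
        "response_id": model.spec.response_id,
        "terms": list(model.spec.terms),
        "predictor": model.spec.predictor,
        "intercept": model.spec.intercept,
        "domain": list(model.spec.domain) if model.spec.domain else None,
        "name": model.spec.name,
        "coefficients": model.params,
        "note": note,
    }
    return json.dumps(payload, indent=2)


def model_from_json(text: str) -> FittedModel:
    payload = json.loads(text)
    spec = ModelSpec(
        response_id=payload["response_id"],
        terms=tuple(payload.get("terms", ())),
        family=payload["family"],
        predictor=payload.get("predictor"),
        intercept=payload.get("intercept", True),
        domain=tuple(payload["domain"]) if payload.get("domain") else None,
        name=payload.get("name", ""),
    )
    return FittedModel(spec=spec, params=dict(payload["coefficients"]))
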