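"""The Quality Potential Index (QPI) for grape must, scalar and map-level.

Perfectly ripe red grapes balance sugar against acidity: enological practice
puts the optimum at 22 degrees Brix, 0.75 g/100 mL titratable acidity (i.e. a
Brix:TA ratio near 30) and pH about 3.4, with Brix times pH squared near 260.
Multiplying the two balance ratios and taking the common logarithm gives a
single score symmetric about the optimum,

    QPI = 2*log10(pH * Brix) - log10(780 * TA_gL),

which is 0 exactly when (pH*Brix)^2 = 780*TA_gL, positive for over-ripe /
under-acid musts and negative for the converse, and for physiological must
values stays within [-1, 1].  The constant is 780 when total acidity enters
in g/L and 7800 when it enters as titratable acidity in g/100 mL; the two
forms are algebraically identical since TA_g100mL = 0.1 * TA_gL.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError, InputError
from .geogrid import CBMap

__all__ = [
    "MustChemistry",
    "baume_to_brix",
    "ta_to_g100mL",
    "balance_ratios",
    "qpi",
    "qpi_from_g100mL",
    "qpi_map",
    "MISSING_EXPORT_SENTINEL",
]

#: Sentinel written for missing cells when exporting a QPI map for display;
#: observed QPI magnitudes stay below ~0.8, so 1 reads unambiguously as
#: "no information".  Never used in computation.
MISSING_EXPORT_SENTINEL = 1.0

BRIX_PER_BAUME = 1.8
OPTIMAL_BRIX_TA_RATIO = 30.0
OPTIMAL_BRIX_PH2 = 260.0


@dataclass(frozen=True)
class MustChemistry:
    """Per-cell must measurements; acidity and sugar in both unit systems.

    Construct from the measured Baumé / g/L values with :meth:`from_field`;
    the derived Brix and g/100 mL fields are filled by the fixed conversions.
    """

    baume: float
    brix: float
    ta_gL: float
    ta_g100mL: float
    ph: float

    def __post_init__(self) -> None:
        for name in ("baume", "brix", "ta_gL", "ta_g100mL", "ph"):
            if getattr(self, name) <= 0:
                raise DomainError(f"must chemistry field {name} must be positive")
        if not math.isclose(self.brix, BRIX_PER_BAUME * self.baume, rel_tol=1e-9):
            raise InputError("inconsistent sugar fields: Brix must equal 1.8 * Baumé")
        if not math.isclose(self.ta_g100mL, 0.1 * self.ta_gL, rel_tol=1e-9):
            raise InputError("inconsistent acidity fields: g/100 mL must equal 0.1 * g/L")

    @classmethod
    def from_field(cls, baume: float, ta_gL: float, ph: float) -> "MustChemistry":
        return cls(
            baume=baume,
            brix=baume_to_brix(baume),
            ta_gL=ta_gL,
            ta_g100mL=ta_to_g100mL(ta_gL),
            ph=ph,
        )


def baume_to_brix(x6):
    """Sugar conversion: degrees Brix = 1.8 * degrees Baumé."""
    x6 = np.asarray(x6, dtype=float)
    if np.any(x6 < 0):
        raise DomainError("Baumé must be nonnegative")
    out = BRIX_PER_BAUME * x6
    return float(out) if out.ndim == 0 else out


def ta_to_g100mL(x7):
    """Acidity conversion: titratable acidity g/100 mL = 0.1 * total acidity g/L."""
    x7 = np.asarray(x7, dtype=float)
    if np.any(x7 < 0):
        raise DomainError("total acidity must be nonnegative")
    out = 0.1 * x7
    return float(out) if out.ndim == 0 else out


def balance_ratios(m: MustChemistry) -> tuple[float, float]:
    """The two normalized ripeness ratios, each approaching 1 at the optimum:
    Brix/(30 * TA_g100mL) and Brix * pH^2 / 260."""
    if m.ta_g100mL <= 0:
        raise DomainError("acidity must be positive")
    return (
        m.brix / (OPTIMAL_BRIX_TA_RATIO * m.ta_g100mL),
        m.brix * m.ph**2 / OPTIMAL_BRIX_PH2,
    )


def qpi(ph, ta_gL, brix):
    """Quality Potential Index from pH, total acidity (g/L) and degrees Brix.

    ``2*log10(ph * brix) - log10(780 * ta_gL)``; accepts scalars or arrays.
    """
    ph = np.asarray(ph, dtype=float)
    ta = np.asarray(ta_gL, dtype=float)
    brix = np.asarray(brix, dtype=float)
    if np.any(ph <= 0) or np.any(ta <= 0) or np.any(brix <= 0):
        raise DomainError("QPI inputs must be positive")
    out = 2.0 * np.log10(ph * brix) - np.log10(780.0 * ta)
    return float(out) if out.ndim == 0 else out


def qpi_from_g100mL(ph, ta_g100mL, brix):
    """QPI with titratable acidity in g/100 mL: 2*log10(ph*brix) - log10(7800*TA).

    Algebraically identical to :func:`qpi` via TA_g100mL = 0.1 * TA_gL.
    """
    ph = np.asarray(ph, dtype=float)
    ta = np.asarray(ta_g100mL, dtype=float)
    brix = np.asarray(brix, dtype=float)
    if np.any(ph <= 0) or np.any(ta <= 0) or np.any(brix <= 0):
        raise DomainError("QPI inputs must be positive")
    out = 2.0 * np.log10(ph * brix) - np.log10(7800.0 * ta)
    return float(out) if out.ndim == 0 else out


def qpi_map(
    ph_map: CBMap,
    ta_map: CBMap,
    sugar_map: CBMap,
    sugar_units: str = "brix",
    missing_sentinel: bool = False,
) -> CBMap:
    """Cell-wise QPI from pH, total acidity (g/L) and sugar maps.

    Chemistry is averaged per cell first and scored second, so the map QPI of
    a cell is the QPI of its mean must.  Sugar maps in degrees Baumé
    (``sugar_units="baume"``) are converted to Brix.  A cell is missing in the
    output whenever any input cell is missing; ``missing_sentinel=True``
    writes the display sentinel 1 into missing cells instead (export only —
    downstream computation should always use the NaN-marked form).
    """
    if not (ph_map.grid == ta_map.grid == sugar_map.grid):
        raise InputError("QPI input maps must share one grid")
    if sugar_units not in ("brix", "baume"):
        raise InputError(f"unknown sugar units {sugar_units!r}")
    sugar = sugar_map.values
    if sugar_units == "baume":
        sugar = np.where(np.isnan(sugar), np.nan, BRIX_PER_BAUME * sugar)
    ok = ~(np.isnan(ph_map.values) | np.isnan(ta_map.values) | np.isnan(sugar))
    values = np.full(ph_map.grid.shape, np.nan)
    if ok.any():
        values[ok] = qpi(ph_map.values[ok], ta_map.values[ok], sugar[ok])
    n_obs = np.where(ok, np.minimum.reduce(
        [ph_map.n_obs, ta_map.n_obs, sugar_map.n_obs]), 0)
    if missing_sentinel:
        exported = np.where(ok, values, MISSING_EXPORT_SENTINEL)
        return CBMap(grid=ph_map.grid, trait_id="QPI", units="",
                     values=exported, n_obs=np.maximum(n_obs, 1))
    return CBMap(grid=ph_map.grid, trait_id="QPI", units="", values=values, n_obs=n_obs)
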