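"""Globally referenced regular grids for crop biometric maps.

Field measurements arrive as geodetic (WGS84) or local Cartesian points.  This
module converts between the two frames, lays a regular square grid over a
user-chosen local origin, aggregates point samples into per-cell trait values
(the *crop biometric map*, or CB map), and changes map resolution by block
aggregation.  Cells never sampled stay explicitly missing — a missing cell is
a first-class state, never a zero.

Frame conventions
-----------------
The local frame is the Local Tangent Plane (LTP): a Cartesian east/north/up
frame tangent to the WGS84 ellipsoid at the field origin.  Grid column index
``j`` increases eastward and row index ``i`` increases northward from the
origin corner; indices are 0-based with half-open cell intervals
``[k*s, (k+1)*s)`` so every point on a shared edge belongs to exactly one cell.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .exceptions import InputError, MapFormatError

__all__ = [
    "GeodeticPoint",
    "LtpPoint",
    "GridSpec",
    "CellIndex",
    "TraitSample",
    "CBMap",
    "geodetic_to_ltp",
    "ltp_to_geodetic",
    "assign_to_cell",
    "rasterize",
    "downsample",
    "read_map",
    "write_map",
]

# WGS84 ellipsoid
_WGS84_A = 6378137.0
_WGS84_F = 1.0 / 298.257223563
_WGS84_E2 = _WGS84_F * (2.0 - _WGS84_F)


@dataclass(frozen=True)
class GeodeticPoint:
    """A WGS84 geodetic position: latitude/longitude in degrees, ellipsoidal
    altitude in metres."""

    lat: float
    lon: float
    alt: float = 0.0

    def __post_init__(self) -> None:
        if not (-90.0 <= self.lat <= 90.0):
            raise InputError(f"latitude {self.lat} outside [-90, 90]")
        if not (-180.0 <= self.lon <= 180.0):
            raise InputError(f"longitude {self.lon} outside [-180, 180]")
        if not math.isfinite(self.alt):
            raise InputError("altitude must be finite")


@dataclass(frozen=True)
class LtpPoint:
    """A point in the local east/north/up frame, metres from the field origin."""

    east: float
    north: float
    up: float = 0.0

    def __post_init__(self) -> None:
        if not all(map(math.isfinite, (self.east, self.north, self.up))):
            raise InputError("LTP coordinates must be finite")


@dataclass(frozen=True)
class CellIndex:
    """0-based (row, column) cell address; row grows northward, column eastward."""

    i: int
    j: int


@dataclass(frozen=True)
class GridSpec:
    """Square-cell grid anchored at a geodetic origin.

    ``n_cols`` is the horizontal resolution (cells along east), ``n_rows`` the
    vertical resolution (cells along north).
    """

    origin: GeodeticPoint
    cell_size: float
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise InputError("cell_size must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise InputError("grid must have at least one row and one column")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)


@dataclass(frozen=True)
class TraitSample:
    """One georeferenced measurement of one trait."""

    position: LtpPoint | GeodeticPoint
    trait_id: str
    value: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise InputError("sample value must be finite")


@dataclass
class CBMap:
    """A crop biometric map: one trait on a regular grid, missing-aware.

    ``values`` holds the per-cell magnitude with NaN marking missing cells;
    ``n_obs`` counts the samples that contributed to each cell (0 for missing).
    """

    grid: GridSpec
    trait_id: str
    units: str
    values: np.ndarray
    n_obs: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise InputError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if self.n_obs is None:
            self.n_obs = np.where(np.isnan(self.values), 0, 1)
        self.n_obs = np.asarray(self.n_obs, dtype=int)
        if self.n_obs.shape != self.grid.shape:
            raise InputError("n_obs shape does not match grid shape")
        if np.any(np.isnan(self.values) & (self.n_obs > 0)):
            raise InputError("missing cells must have n_obs = 0")

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def cell_values(self) -> np.ndarray:
        """Non-missing cell values as a flat vector."""
        return self.values[~self.missing_mask]


# ---------------------------------------------------------------------------
# geodetic <-> LTP
# ---------------------------------------------------------------------------

def _geodetic_to_ecef(p: GeodeticPoint) -> np.ndarray:
    lat = math.radians(p.lat)
    lon = math.radians(p.lon)
    sin_lat, cos_lat = math.sin(lat), math.cos(lat)
    n = _WGS84_A / math.sqrt(1.0 - _WGS84_E2 * sin_lat * sin_lat)
    x = (n + p.alt) * cos_lat * math.cos(lon)
    y = (n + p.alt) * cos_lat * math.sin(lon)
    z = (n * (1.0 - _WGS84_E2) + p.alt) * sin_lat
    return np.array([x, y, z])


def _ecef_to_geodetic(xyz: np.ndarray) -> GeodeticPoint:
    x, y, z = xyz
    lon = math.atan2(y, x)
    rho = math.hypot(x, y)
    # Bowring-style fixed-point iteration on latitude; converges far below
    # 1 mm in a handful of steps for terrestrial points.
    lat = math.atan2(z, rho * (1.0 - _WGS84_E2))
    for _ in range(20):
        sin_lat = math.sin(lat)
        n = _WGS84_A / math.sqrt(1.0 - _WGS84_E2 * sin_lat * sin_lat)
        alt = rho / math.cos(lat) - n if abs(lat) < math.pi / 2.01 else z / sin_lat - n * (1 - _WGS84_E2)
        new_lat = math.atan2(z, rho * (1.0 - _WGS84_E2 * n / (n + alt)))
        if abs(new_lat - lat) < 1e-14:
            lat = new_lat
            break
        lat = new_lat
    sin_lat = math.sin(lat)
    n = _WGS84_A / math.sqrt(1.0 - _WGS84_E2 * sin_lat * sin_lat)
    if abs(math.degrees(lat)) < 89.9:
        alt = rho / math.cos(lat) - n
    else:
        alt = z / sin_lat - n * (1.0 - _WGS84_E2)
    return GeodeticPoint(math.degrees(lat), math.degrees(lon), alt)


def _enu_rotation(origin: GeodeticPoint) -> np.ndarray:
    lat = math.radians(origin.lat)
    lon = math.radians(origin.lon)
    sl, cl = math.sin(lat), math.cos(lat)
    so, co = math.sin(lon), math.cos(lon)
    return np.array(
        [
            [-so, co, 0.0],
            [-sl * co, -sl * so, cl],
            [cl * co, cl * so, sl],
        ]
    )


def geodetic_to_ltp(p: GeodeticPoint, origin: GeodeticPoint) -> LtpPoint:
    """Express geodetic point ``p`` in the east/north/up frame at ``origin``.

    The transform goes through Earth-centered Earth-fixed (ECEF) Cartesian
    coordinates on the WGS84 ellipsoid and rotates the offset into the tangent
    plane.  ``ltp_to_geodetic`` is its inverse to sub-millimetre accuracy for
    offsets up to tens of kilometres.
    """
    d = _geodetic_to_ecef(p) - _geodetic_to_ecef(origin)
    e, n, u = _enu_rotation(origin) @ d
    return LtpPoint(e, n, u)


def ltp_to_geodetic(p: LtpPoint, origin: GeodeticPoint) -> GeodeticPoint:
    """Inverse of :func:`geodetic_to_ltp`."""
    enu = np.array([p.east, p.north, p.up])
    xyz = _geodetic_to_ecef(origin) + _enu_rotation(origin).T @ enu
    return _ecef_to_geodetic(xyz)


# ---------------------------------------------------------------------------
# gridding
# ---------------------------------------------------------------------------

def assign_to_cell(p: LtpPoint, grid: GridSpec) -> CellIndex | None:
    """Map an LTP point to its grid cell, or ``None`` if it falls outside.

    Cells are half-open squares ``[j*s, (j+1)*s) x [i*s, (i+1)*s)``: a point on
    the lower/western edge belongs to that cell, a point on the upper/eastern
    edge to the next one.
    """
    s = grid.cell_size
    j = math.floor(p.east / s)
    i = math.floor(p.north / s)
    if 0 <= i < grid.n_rows and 0 <= j < grid.n_cols:
        return CellIndex(i, j)
    return None


def _to_ltp(position: LtpPoint | GeodeticPoint, origin: GeodeticPoint) -> LtpPoint:
    if isinstance(position, GeodeticPoint):
        return geodetic_to_ltp(position, origin)
    return position


def rasterize(
    samples: Sequence[TraitSample] | Iterable[TraitSample],
    grid: GridSpec,
    reducer: Literal["mean", "max"] = "mean",
) -> CBMap:
    """Aggregate point samples of one trait into a CB map.

    Each cell takes the ``reducer`` (mean by default, max for applications that
    label cells with top values) of the samples falling inside it.  Cells with
    no samples are missing; out-of-grid samples are counted and reported on the
    returned map as ``n_out_of_grid``.  Geodetic sample positions are converted
    to the grid's LTP frame first.
    """
    samples = list(samples)
    if reducer not in ("mean", "max"):
        raise InputError(f"unknown reducer {reducer!r}")
    trait_ids = {s.trait_id for s in samples}
    if len(trait_ids) > 1:
        raise InputError(f"mixed trait_ids in sample list: {sorted(trait_ids)}")
    trait_id = trait_ids.pop() if trait_ids else ""

    sums = np.zeros(grid.shape)
    maxima = np.full(grid.shape, -np.inf)
    counts = np.zeros(grid.shape, dtype=int)
    n_out = 0
    for s in samples:
        cell = assign_to_cell(_to_ltp(s.position, grid.origin), grid)
        if cell is None:
            n_out += 1
            continue
        sums[cell.i, cell.j] += s.value
        maxima[cell.i, cell.j] = max(maxima[cell.i, cell.j], s.value)
        counts[cell.i, cell.j] += 1

    values = np.full(grid.shape, np.nan)
    occupied = counts > 0
    if reducer == "mean":
        values[occupied] = sums[occupied] / counts[occupied]
    else:
        values[occupied] = maxima[occupied]

    cbmap = CBMap(grid=grid, trait_id=trait_id, units="", values=values, n_obs=counts)
    cbmap.n_out_of_grid = n_out  # type: ignore[attr-defined]
    return cbmap


def downsample(
    cbmap: CBMap, factor: int, weights: Literal["n_obs", "equal"] = "n_obs"
) -> CBMap:
    """Coarsen a map by merging ``factor`` x ``factor`` blocks of cells.

    Each output cell is the mean of its non-missing children, weighted by
    their sample counts (equivalent to re-rasterizing the original samples on
    the coarse grid); ``weights="equal"`` gives an unweighted block mean for
    maps whose counts are not meaningful.  An output cell is missing only when
    every child is missing.  A ragged edge (dimensions not divisible by
    ``factor``) is allowed; edge blocks simply contain fewer children.  Trait
    units are unchanged: a yield map in kg per original-cell area keeps those
    units on the coarse grid.
    """
    if not isinstance(factor, (int, np.integer)) or factor < 2:
        raise InputError("downsampling factor must be an integer >= 2")
    grid = cbmap.grid
    n_rows = -(-grid.n_rows // factor)
    n_cols = -(-grid.n_cols // factor)
    out_grid = GridSpec(
        origin=grid.origin,
        cell_size=grid.cell_size * factor,
        n_rows=n_rows,
        n_cols=n_cols,
    )
    values = np.full((n_rows, n_cols), np.nan)
    n_obs = np.zeros((n_rows, n_cols), dtype=int)
    for i in range(n_rows):
        for j in range(n_cols):
            block = cbmap.values[
                i * factor : (i + 1) * factor, j * factor : (j + 1) * factor
            ]
            block_n = cbmap.n_obs[
                i * factor : (i + 1) * factor, j * factor : (j + 1) * factor
            ]
            ok = ~np.isnan(block)
            n_obs[i, j] = int(block_n[ok].sum())
            if not ok.any():
                continue
            if weights == "n_obs":
                w = block_n[ok].astype(float)
                if w.sum() == 0:
                    w = np.ones(ok.sum())
            else:
                w = np.ones(int(ok.sum()))
            values[i, j] = float(np.average(block[ok], weights=w))
    if weights == "equal":
        # counts are not meaningful under an unweighted merge; keep child tally
        pass
    return CBMap(
        grid=out_grid, trait_id=cbmap.trait_id, units=cbmap.units,
        values=values, n_obs=n_obs,
    )


# ---------------------------------------------------------------------------
# plain-text serialization
# ---------------------------------------------------------------------------

_HEADER_KEYS = (
    "origin_lat", "origin_lon", "origin_alt",
    "cell_size", "n_rows", "n_cols", "trait_id", "units",
)


def write_map(cbmap: CBMap, path) -> None:
    """Serialize a CB map to a plain-text file (header + value and count
    matrices).  Missing cells are written as empty fields, never as 0."""
    buf = io.StringIO()
    g = cbmap.grid
    header = {
        "origin_lat": repr(g.origin.lat),
        "origin_lon": repr(g.origin.lon),
        "origin_alt": repr(g.origin.alt),
        "cell_size": repr(g.cell_size),
        "n_rows": str(g.n_rows),
        "n_cols": str(g.n_cols),
        "trait_id": cbmap.trait_id,
        "units": cbmap.units,
    }
    for key in _HEADER_KEYS:
        buf.write(f"{key},{header[key]}\n")
    buf.write("[values]\n")
    for row in cbmap.values:
        buf.write(",".join("" if np.isnan(v) else repr(float(v)) for v in row) + "\n")
    buf.write("[n_obs]\n")
    for row in cbmap.n_obs:
        buf.write(",".join(str(int(v)) for v in row) + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def _parse_matrix(lines: list[str], n_rows: int, n_cols: int, kind: str) -> np.ndarray:
    if len(lines) != n_rows:
        raise MapFormatError(f"expected {n_rows} {kind} rows, found {len(lines)}")
    out = np.full((n_rows, n_cols), np.nan)
    for i, line in enumerate(lines):
        fields = line.split(",")
        if len(fields) != n_cols:
            raise MapFormatError(
                f"{kind} row {i}: expected {n_cols} columns, found {len(fields)}"
            )
        for j, tok in enumerate(fields):
            tok = tok.strip()
            if tok:
                try:
                    out[i, j] = float(tok)
                except ValueError as exc:
                    raise MapFormatError(f"{kind} row {i}, col {j}: {tok!r}") from exc
    return out


def read_map(path) -> CBMap:
    """Read a CB map written by :func:`write_map`.

    Raises :class:`MapFormatError` on a malformed header or a matrix whose
    shape disagrees with the header.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() != ""]
    header: dict[str, str] = {}
    idx = 0
    while idx < len(lines) and not lines[idx].startswith("["):
        key, _, value = lines[idx].partition(",")
        header[key.strip()] = value
        idx += 1
    missing = [k for k in _HEADER_KEYS if k not in header]
    if missing:
        raise MapFormatError(f"missing header keys: {missing}")
    try:
        grid = GridSpec(
            origin=GeodeticPoint(
                float(header["origin_lat"]),
                float(header["origin_lon"]),
                float(header["origin_alt"]),
            ),
            cell_size=float(header["cell_size"]),
            n_rows=int(header["n_rows"]),
            n_cols=int(header["n_cols"]),
        )
    except (ValueError, InputError) as exc:
        raise MapFormatError(f"bad header: {exc}") from exc
    if idx >= len(lines) or lines[idx] != "[values]":
        raise MapFormatError("expected [values] section")
    idx += 1
    value_lines = []
    while idx < len(lines) and not lines[idx].startswith("["):
        value_lines.append(lines[idx])
        idx += 1
    values = _parse_matrix(value_lines, grid.n_rows, grid.n_cols, "values")
    if idx >= len(lines) or lines[idx] != "[n_obs]":
        raise MapFormatError("expected [n_obs] section")
    n_obs_lines = lines[idx + 1 :]
    n_obs = _parse_matrix(n_obs_lines, grid.n_rows, grid.n_cols, "n_obs")
    if np.any(np.isnan(n_obs)):
        raise MapFormatError("n_obs matrix contains empty fields")
    return CBMap(
        grid=grid,
        trait_id=header["trait_id"],
        units=header["units"],
        values=values,
        n_obs=n_obs.astype(int),
    )
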