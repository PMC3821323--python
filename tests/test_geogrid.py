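"""Coordinate conversion, rasterization and resolution-change behaviour."""

import math

import numpy as np
import pytest

from cbmap.exceptions import InputError, MapFormatError
from cbmap.geogrid import (
    CBMap,
    GeodeticPoint,
    GridSpec,
    LtpPoint,
    TraitSample,
    assign_to_cell,
    downsample,
    geodetic_to_ltp,
    ltp_to_geodetic,
    rasterize,
    read_map,
    write_map,
)

ORIGIN = GeodeticPoint(lat=39.5, lon=-1.1, alt=700.0)


def _grid(cell=4.0, rows=3, cols=4):
    return GridSpec(origin=ORIGIN, cell_size=cell, n_rows=rows, n_cols=cols)


class TestGeodeticLtp:
    def test_origin_maps_to_zero(self):
        p = geodetic_to_ltp(ORIGIN, ORIGIN)
        assert (p.east, p.north, p.up) == pytest.approx((0.0, 0.0, 0.0), abs=1e-9)

    def test_one_arcsecond_of_latitude(self):
        """1" of latitude northward moves ~30.8 m north at 39.5 deg.

        Oracle: the meridian arc for a small latitude increment is
        M(phi) * dphi with M the meridian radius of curvature of WGS84.
        """
        arcsec = 1.0 / 3600.0
        p = geodetic_to_ltp(
            GeodeticPoint(ORIGIN.lat + arcsec, ORIGIN.lon, ORIGIN.alt), ORIGIN
        )
        a, f = 6378137.0, 1.0 / 298.257223563
        e2 = f * (2 - f)
        phi = math.radians(ORIGIN.lat)
        m_radius = a * (1 - e2) / (1 - e2 * math.sin(phi) ** 2) ** 1.5
        expected_north = (m_radius + ORIGIN.alt) * math.radians(arcsec)
        assert p.north == pytest.approx(expected_north, abs=0.001)
        assert 30.7 < p.north < 30.9
        assert abs(p.east) < 1e-3

    def test_round_trip_under_one_millimetre(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            de, dn, du = rng.uniform([-5000, -5000, -50], [5000, 5000, 50])
            p = LtpPoint(de, dn, du)
            back = geodetic_to_ltp(ltp_to_geodetic(p, ORIGIN), ORIGIN)
            err = math.dist((back.east, back.north, back.up), (de, dn, du))
            assert err < 1e-3

    def test_invalid_coordinates_rejected(self):
        with pytest.raises(InputError):
            GeodeticPoint(lat=91.0, lon=0.0)
        with pytest.raises(InputError):
            GeodeticPoint(lat=0.0, lon=200.0)


class TestAssignToCell:
    @pytest.mark.parametrize(
        "east,north,expected",
        [
            (0.0, 0.0, (0, 0)),        # lower boundary owned by the lower cell
            (3.99, 3.99, (0, 0)),
            (4.0, 0.0, (0, 1)),        # half-open: shared edge goes east
            (0.0, 4.0, (1, 0)),
            (-0.01, 0.0, None),        # just outside
            (16.0, 0.0, None),         # past the last column
        ],
    )
    def test_half_open_convention(self, east, north, expected):
        cell = assign_to_cell(LtpPoint(east, north), _grid())
        if expected is None:
            assert cell is None
        else:
            assert (cell.i, cell.j) == expected

    def test_agrees_with_rectangle_scan(self):
        """Floor-division assignment matches a brute-force scan of all cells."""
        grid = _grid(cell=2.5, rows=7, cols=9)
        rng = np.random.default_rng(11)
        pts = rng.uniform([-5, -5], [30, 30], size=(1000, 2))
        for east, north in pts:
            brute = None
            for i in range(grid.n_rows):
                for j in range(grid.n_cols):
                    s = grid.cell_size
                    if j * s <= east < (j + 1) * s and i * s <= north < (i + 1) * s:
                        brute = (i, j)
            cell = assign_to_cell(LtpPoint(east, north), grid)
            assert (None if cell is None else (cell.i, cell.j)) == brute


class TestRasterize:
    def _samples(self, pts, trait="X1"):
        return [TraitSample(LtpPoint(e, n), trait, v) for e, n, v in pts]

    def test_mean_and_max_reducers(self):
        pts = [(1.0, 1.0, 4.0), (2.0, 3.0, 6.0)]
        mean_map = rasterize(self._samples(pts), _grid())
        assert mean_map.values[0, 0] == pytest.approx(5.0)
        assert mean_map.n_obs[0, 0] == 2
        max_map = rasterize(self._samples(pts), _grid(), reducer="max")
        assert max_map.values[0, 0] == pytest.approx(6.0)

    def test_empty_and_mixed_inputs(self):
        empty = rasterize([], _grid())
        assert empty.missing_mask.all()
        mixed = self._samples([(1, 1, 2.0)]) + self._samples([(1, 1, 3.0)], "X2")
        with pytest.raises(InputError):
            rasterize(mixed, _grid())

    def test_out_of_grid_counted_not_raised(self):
        cbm = rasterize(self._samples([(1, 1, 2.0), (-3, 0, 9.0)]), _grid())
        assert cbm.n_out_of_grid == 1
        assert cbm.n_obs.sum() == 1

    def test_conserves_sample_mass(self):
        rng = np.random.default_rng(3)
        pts = [(e, n, v) for e, n, v in
               zip(rng.uniform(0, 16, 200), rng.uniform(0, 12, 200),
                   rng.normal(5, 2, 200))]
        cbm = rasterize(self._samples(pts), _grid())
        in_grid = sum(v for e, n, v in pts
                      if assign_to_cell(LtpPoint(e, n), _grid()) is not None)
        ok = ~cbm.missing_mask
        assert float((cbm.values[ok] * cbm.n_obs[ok]).sum()) == pytest.approx(in_grid)


class TestDownsample:
    def test_block_mean_skips_missing(self):
        values = np.array([[2.0, 4.0], [6.0, np.nan]])
        cbm = CBMap(grid=_grid(rows=2, cols=2), trait_id="X1", units="%",
                    values=values)
        out = downsample(cbm, 2)
        assert out.values[0, 0] == pytest.approx(4.0)
        assert out.n_obs[0, 0] == 3
        assert out.grid.cell_size == 8.0

    def test_all_missing_block_stays_missing(self):
        cbm = CBMap(grid=_grid(rows=2, cols=2), trait_id="X1", units="%",
                    values=np.full((2, 2), np.nan))
        assert np.isnan(downsample(cbm, 2).values).all()

    def test_weighted_by_counts(self):
        values = np.array([[2.0, 10.0], [np.nan, np.nan]])
        n_obs = np.array([[3, 1], [0, 0]])
        cbm = CBMap(grid=_grid(rows=2, cols=2), trait_id="X1", units="%",
                    values=values, n_obs=n_obs)
        out = downsample(cbm, 2)
        assert out.values[0, 0] == pytest.approx((3 * 2.0 + 1 * 10.0) / 4)
        assert downsample(cbm, 2, weights="equal").values[0, 0] == pytest.approx(6.0)

    def test_conserves_weighted_mass_with_ragged_edge(self):
        rng = np.random.default_rng(5)
        grid = _grid(rows=5, cols=7)
        values = rng.normal(3, 1, grid.shape)
        values[rng.random(grid.shape) < 0.3] = np.nan
        n_obs = np.where(np.isnan(values), 0, rng.integers(1, 4, grid.shape))
        cbm = CBMap(grid=grid, trait_id="X1", units="%", values=values, n_obs=n_obs)
        out = downsample(cbm, 2)
        mass_in = np.nansum(values * n_obs)
        mass_out = np.nansum(out.values * out.n_obs)
        assert mass_out == pytest.approx(mass_in)
        assert out.grid.shape == (3, 4)

    def test_factor_below_two_rejected(self):
        cbm = CBMap(grid=_grid(), trait_id="X1", units="%",
                    values=np.zeros((3, 4)))
        with pytest.raises(InputError):
            downsample(cbm, 1)


class TestMapIO:
    def test_round_trip_preserves_everything(self, tmp_path):
        rng = np.random.default_rng(9)
        values = rng.normal(0, 1, (3, 4))
        values[0, 1] = np.nan
        n_obs = np.where(np.isnan(values), 0, 2)
        cbm = CBMap(grid=_grid(), trait_id="X8", units="pH",
                    values=values, n_obs=n_obs)
        path = tmp_path / "map.csv"
        write_map(cbm, path)
        back = read_map(path)
        assert back.grid == cbm.grid
        assert back.trait_id == "X8" and back.units == "pH"
        assert np.array_equal(np.isnan(back.values), np.isnan(values))
        np.testing.assert_allclose(back.values[~np.isnan(values)],
                                   values[~np.isnan(values)], rtol=0, atol=0)
        assert np.array_equal(back.n_obs, n_obs)

    def test_shape_mismatch_is_format_error(self, tmp_path):
        cbm = CBMap(grid=_grid(), trait_id="X1", units="%", values=np.zeros((3, 4)))
        path = tmp_path / "map.csv"
        write_map(cbm, path)
        lines = path.read_text().splitlines()
        del lines[9]  # drop one value row
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(MapFormatError):
            read_map(path)
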