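"""IDW interpolation, Jenks natural breaks, raster classification, ASCII I/O."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pm25risk import spatial as sp


def small_grid(n=4, origin=(0.0, 0.0), cell=1.0):
    return sp.GridSpec(origin[0], origin[1], cell, n, n)


class TestIdw:
    def test_cell_at_station_takes_station_value_exactly(self):
        # station at the center of cell (row 3, col 0) of a 4x4 unit grid
        grid = small_grid()
        fld = sp.idw_interpolate(
            np.array([0.5, 2.5]), np.array([0.5, 3.5]),
            np.array([42.0, 7.0]), grid)
        assert fld.values[3, 0] == 42.0

    def test_midpoint_between_two_equal_weights(self):
        grid = sp.GridSpec(0.0, 0.0, 1.0, 1, 1)  # single cell center (0.5, 0.5)
        fld = sp.idw_interpolate(
            np.array([0.5, 0.5]), np.array([-0.5, 1.5]),
            np.array([10.0, 20.0]), grid, power=2.0)
        assert fld.values[0, 0] == pytest.approx(15.0)

    @pytest.mark.parametrize("power", [1.0, 2.0, 3.5])
    def test_matches_brute_force_oracle(self, rng, power):
        x, y = rng.uniform(0, 4, 5), rng.uniform(0, 4, 5)
        v = rng.uniform(0, 100, 5)
        grid = small_grid()
        fld = sp.idw_interpolate(x, y, v, grid, power=power)
        gx, gy = grid.cell_centers()
        for r in range(4):
            for c in range(4):
                num = den = 0.0
                for i in range(5):
                    d = np.hypot(gx[r, c] - x[i], gy[r, c] - y[i])
                    w = d ** (-power)
                    num += w * v[i]
                    den += w
                assert fld.values[r, c] == pytest.approx(num / den, abs=1e-10)

    def test_bounded_by_sample_range(self, rng):
        x, y = rng.uniform(0, 4, 7), rng.uniform(0, 4, 7)
        v = rng.uniform(10, 90, 7)
        fld = sp.idw_interpolate(x, y, v, small_grid())
        assert fld.values.min() >= v.min() - 1e-12
        assert fld.values.max() <= v.max() + 1e-12

    def test_translation_invariance(self, rng):
        x, y = rng.uniform(0, 4, 6), rng.uniform(0, 4, 6)
        v = rng.uniform(0, 50, 6)
        a = sp.idw_interpolate(x, y, v, small_grid())
        b = sp.idw_interpolate(x + 100, y - 30, v,
                               small_grid(origin=(100.0, -30.0)))
        np.testing.assert_allclose(a.values, b.values, atol=1e-9)

    def test_convex_combination_shifts_with_constant(self, rng):
        x, y = rng.uniform(0, 4, 6), rng.uniform(0, 4, 6)
        v = rng.uniform(0, 50, 6)
        a = sp.idw_interpolate(x, y, v, small_grid())
        b = sp.idw_interpolate(x, y, v + 13.5, small_grid())
        np.testing.assert_allclose(b.values - a.values, 13.5, atol=1e-10)

    def test_k_nearest_restricts_support(self):
        # with k=1 each cell copies its closest station
        grid = sp.GridSpec(0.0, 0.0, 2.0, 2, 1)  # centers (1,1) and (3,1)
        fld = sp.idw_interpolate(
            np.array([0.0, 4.0]), np.array([1.0, 1.0]),
            np.array([5.0, 9.0]), grid, k_nearest=1)
        np.testing.assert_array_equal(fld.values, [[5.0, 9.0]])

    def test_empty_points_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            sp.idw_interpolate(np.array([]), np.array([]), np.array([]),
                               small_grid())

    def test_nonpositive_power_rejected(self):
        with pytest.raises(ValueError, match="power"):
            sp.idw_interpolate(np.array([1.0]), np.array([1.0]),
                               np.array([1.0]), small_grid(), power=0.0)


def exhaustive_jenks(vals, k):
    """Brute-force minimum within-class SSD over all contiguous partitions."""
    vals = np.sort(np.asarray(vals, dtype=float))
    n = len(vals)

    def ssd(seg):
        return float(np.sum((seg - seg.mean()) ** 2))

    best = np.inf
    for cuts in itertools.combinations(range(1, n), k - 1):
        edges = [0, *cuts, n]
        obj = sum(ssd(vals[a:b]) for a, b in zip(edges, edges[1:]))
        best = min(best, obj)
    return best


class TestJenks:
    def test_two_obvious_clusters(self):
        bs = sp.jenks_breaks([1.0, 2.0, 3.0, 10.0, 11.0, 12.0], k=2)
        assert bs.breaks == [3.0]

    def test_each_distinct_value_its_own_class(self):
        vals = [1.0, 4.0, 9.0]
        bs = sp.jenks_breaks(vals, k=3)
        assert bs.breaks == [1.0, 4.0]
        assert bs.objective == pytest.approx(0.0)

    @pytest.mark.parametrize("seed,k", [(s, k) for s in range(6)
                                        for k in (2, 3, 4)])
    def test_dp_matches_exhaustive_optimum(self, seed, k):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(k + 1, 13))
        vals = np.round(rng.uniform(0, 100, size=n), 2)
        if len(np.unique(vals)) < k:
            pytest.skip("degenerate draw")
        bs = sp.jenks_breaks(vals, k)
        assert bs.objective == pytest.approx(exhaustive_jenks(vals, k),
                                             abs=1e-8)

    def test_objective_non_increasing_in_k(self, rng):
        vals = rng.uniform(0, 50, size=30)
        objs = [sp.jenks_breaks(vals, k).objective for k in (2, 3, 4, 5)]
        assert all(a >= b - 1e-12 for a, b in zip(objs, objs[1:]))

    def test_labels(self):
        bs = sp.jenks_breaks([1.0, 2.0, 8.0, 9.0, 20.0, 21.0], k=3)
        assert bs.labels == ["low", "moderate", "high"]

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="k must be"):
            sp.jenks_breaks([1.0, 2.0], k=1)
        with pytest.raises(ValueError, match="distinct"):
            sp.jenks_breaks([1.0, 1.0, 1.0], k=2)


class TestClassify:
    def test_uniform_field_single_class(self):
        grid = small_grid(2)
        fld = sp.RasterField(grid, np.full((2, 2), 5.0))
        bs = sp.BreakSet(k=3, breaks=[10.0, 20.0])
        cls = sp.classify_raster(fld, bs)
        assert np.all(cls.values == 0.0)

    def test_boundary_values_fall_in_lower_class(self):
        grid = sp.GridSpec(0, 0, 1.0, 3, 1)
        fld = sp.RasterField(grid, np.array([[10.0, 10.5, 20.0]]))
        bs = sp.BreakSet(k=3, breaks=[10.0, 20.0])
        cls = sp.classify_raster(fld, bs)
        np.testing.assert_array_equal(cls.values, [[0.0, 1.0, 1.0]])

    def test_nodata_propagates(self):
        grid = sp.GridSpec(0, 0, 1.0, 2, 1)
        fld = sp.RasterField(grid, np.array([[5.0, sp.NODATA]]))
        cls = sp.classify_raster(fld, sp.BreakSet(k=2, breaks=[10.0]))
        assert cls.values[0, 1] == sp.NODATA

    def test_class_round_trip_through_ascii(self, rng, tmp_path):
        grid = small_grid()
        fld = sp.RasterField(grid, rng.uniform(0, 100, size=(4, 4)))
        bs = sp.jenks_breaks(fld.values.ravel(), k=3)
        cls = sp.classify_raster(fld, bs)
        cls.to_ascii(tmp_path / "cls.asc")
        back = sp.RasterField.from_ascii(tmp_path / "cls.asc")
        np.testing.assert_array_equal(back.values, cls.values)
        assert back.grid == cls.grid


class TestAsciiGrid:
    def test_round_trip_preserves_six_significant_digits(self, rng, tmp_path):
        grid = sp.GridSpec(12.5, -3.25, 0.4, 5, 3)
        fld = sp.RasterField(grid, rng.uniform(0, 250, size=(3, 5)))
        fld.to_ascii(tmp_path / "f.asc")
        back = sp.RasterField.from_ascii(tmp_path / "f.asc")
        assert back.grid == grid
        np.testing.assert_allclose(back.values, fld.values, rtol=1e-5)
        # a second write of the read-back grid is byte-stable
        back.to_ascii(tmp_path / "g.asc")
        fld.to_ascii(tmp_path / "h.asc")
        assert (tmp_path / "g.asc").read_bytes() == \
            (tmp_path / "h.asc").read_bytes()

    def test_header_format(self, tmp_path):
        fld = sp.RasterField(small_grid(2), np.zeros((2, 2)))
        fld.to_ascii(tmp_path / "f.asc")
        lines = (tmp_path / "f.asc").read_text().splitlines()
        assert lines[0] == "ncols 2"
        assert lines[5].startswith("NODATA_value")


@settings(max_examples=30, derandomize=True, deadline=None)
@given(st.integers(0, 10_000), st.floats(0.5, 4.0))
def test_idw_invariant_under_common_distance_rescaling(seed, scale):
    rng = np.random.default_rng(seed)
    x, y = rng.uniform(0, 4, 5), rng.uniform(0, 4, 5)
    v = rng.uniform(0, 10, 5)
    a = sp.idw_interpolate(x, y, v, small_grid())
    b = sp.idw_interpolate(
        x * scale, y * scale, v,
        sp.GridSpec(0.0, 0.0, scale, 4, 4))
    np.testing.assert_allclose(a.values, b.values, atol=1e-9)
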