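import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rawms.errors import DegenerateRunError, RangeError, ValidationError
from rawms.rasterize import (
    RasterConfig,
    RasterGrid,
    export_grid,
    mz_to_bin,
    rasterize_run,
    rasterize_series,
    rt_to_bin,
)
from rawms.sources import MS1, Source
from rawms.spectra_io import Scan
from rawms.synthetic_data import SyntheticCohortConfig, generate_run

from conftest import random_series


def brute_force_grid(scans, config):
    """Independent per-point binning: plain loops, dict accumulation."""
    g = config.grid_size
    rts = [s.rt for s in scans]
    rt_min, rt_max = min(rts), max(rts)
    sums, counts = {}, {}
    for scan in scans:
        row = min(math.floor((scan.rt - rt_min) / (rt_max - rt_min) * g), g - 1)
        for mz, inten in zip(scan.mz, scan.intensity):
            col = min(math.floor(mz / 2000.0 * g), g - 1)
            sums[(row, col)] = sums.get((row, col), 0.0) + inten
            counts[(row, col)] = counts.get((row, col), 0) + 1
    grid = np.zeros((g, g))
    for cell, total in sums.items():
        grid[cell] = total / counts[cell]
    return grid


class TestBinning:
    @pytest.mark.parametrize(
        "mz,expected", [(0.0, 0), (2000.0, 511), (400.0, 102), (1999.999, 511)]
    )
    def test_mz_to_bin(self, mz, expected):
        assert mz_to_bin(mz, RasterConfig(grid_size=512)) == expected

    def test_mz_out_of_range(self):
        with pytest.raises(RangeError):
            mz_to_bin(2000.5, RasterConfig())

    def test_rt_to_bin_edges_and_midpoint(self):
        config = RasterConfig(grid_size=512)
        assert rt_to_bin(0.0, 0.0, 100.0, config) == 0
        assert rt_to_bin(100.0, 0.0, 100.0, config) == 511
        assert rt_to_bin(50.0, 0.0, 100.0, config) == 256

    def test_rt_out_of_range(self):
        with pytest.raises(RangeError):
            rt_to_bin(101.0, 0.0, 100.0, RasterConfig())

    def test_degenerate_rt_extent(self):
        with pytest.raises(DegenerateRunError):
            rt_to_bin(1.0, 1.0, 1.0, RasterConfig())


class TestRasterizeSeries:
    def test_empty_series_rejected(self, small_config):
        with pytest.raises(ValidationError):
            rasterize_series([], small_config)

    def test_pointless_scans_give_zero_grid(self, small_config):
        scans = [Scan(1, 0.0, [], []), Scan(1, 10.0, [], [])]
        grid = rasterize_series(scans, small_config)
        assert grid.values.shape == (64, 64)
        assert np.all(grid.values == 0)

    def test_two_points_one_cell_averaged(self):
        """Points 0.1 Th apart share a 3.90625 Th bin; the cell holds their mean."""
        config = RasterConfig(grid_size=512)
        scans = [
            Scan(1, 0.0, [500.0, 500.1], [10.0, 30.0]),
            Scan(1, 10.0, [], []),
        ]
        grid = rasterize_series(scans, config)
        nonzero = np.argwhere(grid.values != 0)
        assert nonzero.tolist() == [[0, 128]]
        assert grid.values[0, 128] == pytest.approx(20.0)

    def test_ms1_padding_columns_are_black(self, rng):
        """MS1 content confined to 400-1249 Th leaves the 0-400 and 1250-2000
        column ranges exactly zero."""
        config = RasterConfig(grid_size=512)
        scans = []
        for rt in np.linspace(0, 100, 8):
            mz = np.unique(rng.uniform(400.0, 1249.0, size=30))
            scans.append(Scan(1, float(rt), mz, rng.exponential(5.0, mz.size)))
        grid = rasterize_series(scans, config)
        lo = mz_to_bin(400.0, config)
        hi = mz_to_bin(1249.999, config)
        assert np.all(grid.values[:, :lo] == 0)
        assert np.all(grid.values[:, hi + 1 :] == 0)
        assert grid.values.sum() > 0

    def test_matches_brute_force_oracle(self, rng):
        config = RasterConfig(grid_size=64)
        for _ in range(10):
            scans = random_series(rng, n_scans=6, max_points=40)
            grid = rasterize_series(scans, config)
            np.testing.assert_array_equal(grid.values, brute_force_grid(scans, config))

    def test_points_poolable_across_same_rt_scans(self):
        """Redistributing points among scans at one RT leaves the grid unchanged."""
        config = RasterConfig(grid_size=32)
        a = [
            Scan(1, 0.0, [100.0, 900.0], [4.0, 8.0]),
            Scan(1, 50.0, [500.0], [2.0]),
        ]
        b = [
            Scan(1, 0.0, [100.0], [4.0]),
            Scan(1, 0.0, [900.0], [8.0]),
            Scan(1, 50.0, [500.0], [2.0]),
        ]
        np.testing.assert_array_equal(
            rasterize_series(a, config).values, rasterize_series(b, config).values
        )

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_nonnegative_and_oracle_exact(self, seed):
        rng = np.random.default_rng(seed)
        config = RasterConfig(grid_size=16)
        scans = random_series(rng, n_scans=4, max_points=25)
        grid = rasterize_series(scans, config)
        assert grid.values.min() >= 0
        np.testing.assert_array_equal(grid.values, brute_force_grid(scans, config))


class TestRasterizeRun:
    def test_canonical_order_and_count(self):
        config = SyntheticCohortConfig(n_per_class=2, n_windows=10, n_scans=6)
        run = generate_run(0, config, seed=3)
        grids = rasterize_run(run, RasterConfig(grid_size=32))
        assert len(grids) == 11
        assert grids[0].source == MS1
        assert [g.source for g in grids[1:]] == [Source.ms2(i) for i in range(10)]

    def test_deterministic(self, tiny_run, small_config):
        a = rasterize_run(tiny_run, small_config)
        b = rasterize_run(tiny_run, small_config)
        for ga, gb in zip(a, b):
            np.testing.assert_array_equal(ga.values, gb.values)

    def test_toy_run_matches_oracle(self, tiny_run, small_config):
        grids = rasterize_run(tiny_run, small_config)
        np.testing.assert_array_equal(
            grids[0].values, brute_force_grid(tiny_run.ms1_scans, small_config)
        )
        np.testing.assert_array_equal(
            grids[1].values, brute_force_grid(tiny_run.ms2_series[0], small_config)
        )


class TestExport:
    def grid(self, values):
        values = np.asarray(values, dtype=float)
        return RasterGrid(values, MS1, RasterConfig(grid_size=values.shape[0]))

    def test_zero_grid_png8_is_black(self, tmp_path):
        import imageio.v3 as iio

        path = tmp_path / "zero.png"
        export_grid(self.grid(np.zeros((4, 4))), path, "png8")
        assert np.all(iio.imread(path) == 0)

    def test_max_value_maps_to_255(self, tmp_path):
        import imageio.v3 as iio

        values = np.zeros((4, 4))
        values[1, 2] = 7.5
        values[0, 0] = 3.75
        path = tmp_path / "g.png"
        export_grid(self.grid(values), path, "png8")
        img = iio.imread(path)
        assert img[1, 2] == 255
        assert img[0, 0] == 128  # half the max, rounded

    def test_array_mode_round_trip_exact(self, tmp_path, rng):
        values = rng.exponential(1.0, size=(8, 8))
        path = tmp_path / "g.npy"
        export_grid(self.grid(values), path, "array64")
        np.testing.assert_array_equal(np.load(path), values)
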