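"""Rasterize scan series into fixed (RT x m/z) intensity grids.

Every scan series — the MS1 series or one isolation window's MS2 series —
becomes one G x G grid: rows are retention-time bins (ascending downward),
columns are m/z bins (ascending rightward) over a fixed 0-2000 Th axis.
Each recorded point lands in exactly one cell; a cell's value is the
arithmetic mean of the intensities of the points assigned to it, and cells
receiving no points stay zero. Because the m/z axis always spans 0-2000 Th
while SWATH MS1 acquisitions only cover 400-1249 Th, the MS1 grid carries
implicit black padding in the 0-400 and 1250-2000 Th column ranges.

Bins are half-open [lo, hi) with the top edge closed, so coverage is total
and non-overlapping. The RT axis is normalized per scan series: by default
each series' own [rt_min, rt_max] is mapped onto the grid (``per_run_minmax``),
which emulates scaling runs of similar duration onto a uniform time axis; a
``fixed_duration`` policy maps [0, duration] instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import DegenerateRunError, RangeError, ValidationError
from .sources import MS1, Source
from .spectra_io import MsRun, Scan

__all__ = [
    "RasterConfig",
    "RasterGrid",
    "mz_to_bin",
    "rt_to_bin",
    "rasterize_series",
    "rasterize_run",
    "export_grid",
]

MZ_RANGE = (0.0, 2000.0)


@dataclass(frozen=True)
class RasterConfig:
    """Grid geometry and RT normalization policy.

    grid_size: number of bins per axis (study-scale choices are 512 and
        2048; any G >= 2 is accepted for testing).
    rt_policy: "per_run_minmax" maps each series' own RT extent onto the
        grid; "fixed_duration" maps [0, rt_duration] seconds.
    """

    grid_size: int = 512
    mz_range: tuple[float, float] = MZ_RANGE
    rt_policy: str = "per_run_minmax"
    rt_duration: float | None = None

    def __post_init__(self) -> None:
        if self.grid_size < 2:
            raise ValidationError(f"grid_size must be >= 2, got {self.grid_size}")
        lo, hi = self.mz_range
        if not lo < hi:
            raise ValidationError(f"mz_range must have lower < upper, got {self.mz_range}")
        if self.rt_policy not in ("per_run_minmax", "fixed_duration"):
            raise ValidationError(f"unknown rt_policy {self.rt_policy!r}")
        if self.rt_policy == "fixed_duration" and not (
            self.rt_duration and self.rt_duration > 0
        ):
            raise ValidationError("fixed_duration policy requires a positive rt_duration")


@dataclass
class RasterGrid:
    """One scan series rasterized onto a G x G nonnegative intensity grid."""

    values: np.ndarray  # rows = RT bins ascending, cols = m/z bins ascending
    source: Source = field(default_factory=lambda: MS1)
    config: RasterConfig = field(default_factory=RasterConfig)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        g = self.config.grid_size
        if self.values.shape != (g, g):
            raise ValidationError(
                f"grid shape {self.values.shape} does not match grid_size {g}"
            )
        if self.values.size and float(self.values.min()) < 0:
            raise ValidationError("grid values must be nonnegative")


def mz_to_bin(mz, config: RasterConfig):
    """Map m/z (Th) to a column index: floor(mz/span * G), top edge clamped."""
    lo, hi = config.mz_range
    mz_arr = np.asarray(mz, dtype=float)
    if np.any(mz_arr < lo) or np.any(mz_arr > hi):
        raise RangeError(f"m/z outside [{lo}, {hi}]")
    g = config.grid_size
    bins = np.floor((mz_arr - lo) / (hi - lo) * g).astype(int)
    bins = np.minimum(bins, g - 1)
    return int(bins) if np.isscalar(mz) or bins.ndim == 0 else bins


def rt_to_bin(rt, rt_min: float, rt_max: float, config: RasterConfig):
    """Map RT (s) to a row index over [rt_min, rt_max], top edge clamped."""
    if not rt_min < rt_max:
        raise DegenerateRunError(f"rt_min ({rt_min}) must be < rt_max ({rt_max})")
    rt_arr = np.asarray(rt, dtype=float)
    if np.any(rt_arr < rt_min) or np.any(rt_arr > rt_max):
        raise RangeError(f"RT outside [{rt_min}, {rt_max}]")
    g = config.grid_size
    bins = np.floor((rt_arr - rt_min) / (rt_max - rt_min) * g).astype(int)
    bins = np.minimum(bins, g - 1)
    return int(bins) if np.isscalar(rt) or bins.ndim == 0 else bins


def _rt_extent(scans: Sequence[Scan], config: RasterConfig) -> tuple[float, float]:
    if config.rt_policy == "fixed_duration":
        return 0.0, float(config.rt_duration)  # type: ignore[arg-type]
    rts = [s.rt for s in scans]
    rt_min, rt_max = min(rts), max(rts)
    if not rt_min < rt_max:
        raise DegenerateRunError(
            "scan series has no RT extent; use the fixed_duration policy"
        )
    return rt_min, rt_max


def rasterize_series(
    scans: Sequence[Scan],
    config: RasterConfig | None = None,
    source: Source = MS1,
) -> RasterGrid:
    """Bin-average one scan series into a grid.

    Each recorded (rt, mz, intensity) point is assigned to one cell; the
    cell value is the mean intensity of its points, empty cells are 0.
    """
    config = config or RasterConfig()
    if not scans:
        raise ValidationError("cannot rasterize an empty scan series")
    g = config.grid_size
    rt_min, rt_max = _rt_extent(scans, config)

    # One bincount over all points, concatenated in scan order, so each
    # cell's sum accumulates in recorded-point order.
    flats, weights = [], []
    for scan in scans:
        if scan.mz.size == 0:
            continue
        row = rt_to_bin(scan.rt, rt_min, rt_max, config)
        flats.append(row * g + mz_to_bin(scan.mz, config))
        weights.append(scan.intensity)
    if flats:
        flat = np.concatenate(flats)
        sums = np.bincount(flat, weights=np.concatenate(weights), minlength=g * g)
        counts = np.bincount(flat, minlength=g * g)
    else:
        sums = counts = np.zeros(g * g)

    values = np.divide(sums, counts, out=np.zeros(g * g), where=counts > 0)
    return RasterGrid(values.reshape(g, g), source=source, config=config)


def rasterize_run(run: MsRun, config: RasterConfig | None = None) -> list[RasterGrid]:
    """Rasterize every scan series of a run: MS1 first, then MS2 windows ascending."""
    config = config or RasterConfig()
    grids = [rasterize_series(run.ms1_scans, config, MS1)]
    for idx in sorted(run.ms2_series):
        grids.append(rasterize_series(run.ms2_series[idx], config, Source.ms2(idx)))
    return grids


_TRANSFORMS = ("linear_max", "log1p_then_linear")


def apply_transform(values: np.ndarray, transform: str) -> np.ndarray:
    """Intensity transform applied before per-image max normalization."""
    if transform == "linear_max":
        return np.asarray(values, dtype=float)
    if transform == "log1p_then_linear":
        return np.log1p(np.asarray(values, dtype=float))
    raise ValidationError(f"unknown transform {transform!r}; choose from {_TRANSFORMS}")


def export_grid(
    grid: RasterGrid, path, mode: str = "array64", transform: str = "linear_max"
) -> None:
    """Write a grid to disk.

    array64/array32/array16 save the raw values as .npy at the stated float
    width (array64 is lossless); png8/png16 scale by the per-image maximum
    after ``transform`` and quantize to 8/16-bit gray, with all-zero grids
    exporting as all-zero images.
    """
    path = Path(path)
    if mode in ("array64", "array32", "array16"):
        dtype = {"array64": "<f8", "array32": "<f4", "array16": "<f2"}[mode]
        np.save(path, grid.values.astype(dtype))
        return
    if mode not in ("png8", "png16"):
        raise ValidationError(f"unknown export mode {mode!r}")
    import imageio.v3 as iio

    values = apply_transform(grid.values, transform)
    peak = float(values.max())
    scaled = values / peak if peak > 0 else values
    depth = 255 if mode == "png8" else 65535
    dtype = np.uint8 if mode == "png8" else np.uint16
    iio.imwrite(path, np.round(scaled * depth).astype(dtype), extension=".png")
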