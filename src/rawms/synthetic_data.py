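"""Synthetic SWATH-like cohorts with controlled class signal.

Each simulated run mimics a data-independent-acquisition sample: one MS1
scan series over the precursor range 400-1249 Th and K MS2 scan series,
one per precursor isolation window, over the fragment range 0-2000 Th.
Peptide-like peaks elute as Gaussian profiles in retention time; each
peak's fragments are routed into exactly the MS2 series whose isolation
window contains the precursor m/z. Class signal is injected by multiplying
the intensities of designated discriminative peaks by a fold change in
class 1 — either in both MS1 and MS2 ("ms1_and_ms2") or only in the
fragments ("ms2_only", leaving MS1 distributionally identical between
classes). Noise is multiplicative lognormal on peak intensities plus a
uniform-m/z, exponential-intensity background in every scan.

The generator is fully seeded: the cohort master seed derives one seed per
sample, so runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .spectra_io import MsRun, Scan, WindowScheme
from .util import derive_seed

__all__ = [
    "PeakSpec",
    "SyntheticCohortConfig",
    "tiled_window_scheme",
    "default_peak_inventory",
    "generate_run",
    "generate_cohort",
]

MS1_MZ_RANGE = (400.0, 1249.0)
MS2_MZ_RANGE = (0.0, 2000.0)


@dataclass(frozen=True)
class PeakSpec:
    """One peptide-like analyte: a precursor and its fragment pattern.

    fold_change multiplies intensities in class 1 when ``discriminative``;
    signal_location controls whether the fold change is visible in MS1 and
    MS2 ("ms1_and_ms2") or in the fragments only ("ms2_only").
    """

    precursor_mz: float
    rt_center: float
    rt_sigma: float
    base_intensity: float
    fragments: tuple[tuple[float, float], ...]  # (m/z, relative intensity)
    discriminative: bool = False
    fold_change: float = 1.0
    signal_location: str = "ms1_and_ms2"

    def __post_init__(self) -> None:
        if not MS1_MZ_RANGE[0] <= self.precursor_mz <= MS1_MZ_RANGE[1]:
            raise ValidationError(
                f"precursor m/z {self.precursor_mz} outside {MS1_MZ_RANGE}"
            )
        if self.rt_sigma <= 0:
            raise ValidationError("rt_sigma must be positive")
        if self.base_intensity <= 0:
            raise ValidationError("base_intensity must be positive")
        if self.fold_change < 1:
            raise ValidationError("fold_change must be >= 1")
        if self.signal_location not in ("ms1_and_ms2", "ms2_only"):
            raise ValidationError(f"unknown signal_location {self.signal_location!r}")
        for mz, rel in self.fragments:
            if not MS2_MZ_RANGE[0] <= mz <= MS2_MZ_RANGE[1]:
                raise ValidationError(f"fragment m/z {mz} outside {MS2_MZ_RANGE}")
            if not 0 < rel <= 1:
                raise ValidationError(f"relative intensity {rel} outside (0, 1]")


def tiled_window_scheme(n_windows: int) -> WindowScheme:
    """K contiguous, non-overlapping isolation windows tiling 400-1249 Th."""
    if n_windows < 1:
        raise ConfigError("need at least one isolation window")
    edges = np.linspace(MS1_MZ_RANGE[0], MS1_MZ_RANGE[1], n_windows + 1)
    return WindowScheme([(float(a), float(b)) for a, b in zip(edges[:-1], edges[1:])])


def default_peak_inventory(
    n_peaks: int = 20,
    n_discriminative: int = 5,
    fold_change: float = 4.0,
    signal_location: str = "ms1_and_ms2",
    rt_span: float = 600.0,
    n_fragments: int = 4,
    seed: int = 20210712,
) -> list[PeakSpec]:
    """A reproducible peak inventory spread over the acquisition space.

    Precursors are spread over the MS1 range, elution centers over the
    middle 70% of the gradient, base intensities log-uniform over roughly
    one decade; the first ``n_discriminative`` peaks (by generation order)
    carry the class fold change.
    """
    if n_discriminative > n_peaks:
        raise ConfigError("n_discriminative cannot exceed n_peaks")
    rng = np.random.default_rng(seed)
    peaks = []
    for i in range(n_peaks):
        fragments = tuple(
            (float(mz), float(rel))
            for mz, rel in zip(
                rng.uniform(100.0, 1900.0, size=n_fragments),
                rng.uniform(0.2, 1.0, size=n_fragments),
            )
        )
        peaks.append(
            PeakSpec(
                precursor_mz=float(rng.uniform(420.0, 1240.0)),
                rt_center=float(rng.uniform(0.15, 0.85) * rt_span),
                rt_sigma=float(rng.uniform(rt_span / 60.0, rt_span / 25.0)),
                base_intensity=float(10 ** rng.uniform(1.7, 2.7)),
                fragments=fragments,
                discriminative=i < n_discriminative,
                fold_change=fold_change if i < n_discriminative else 1.0,
                signal_location=signal_location,
            )
        )
    return peaks


@dataclass
class SyntheticCohortConfig:
    """Study-condition knobs of the generator.

    Defaults are desk-scale: K=10 windows (the acquisition geometry the
    pipeline emulates uses 100; set ``n_windows=100`` for a full-geometry
    cohort), 32 scans per series over a 600 s gradient, 20 peaks of which
    5 discriminate the classes at fold change 4, lognormal intensity noise
    sigma 0.3 and 20 exponential background points per scan.
    """

    n_per_class: int = 30
    n_windows: int = 10
    n_scans: int = 32
    rt_span: float = 600.0
    peaks: list[PeakSpec] = field(default_factory=list)
    n_background_points: int = 20
    background_scale: float = 10.0
    noise_sigma: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_windows < 1:
            raise ConfigError("n_windows must be >= 1")
        if self.n_scans < 2:
            raise ConfigError("need at least 2 scans per series")
        if self.rt_span <= 0:
            raise ConfigError("rt_span must be positive")
        if not self.peaks:
            self.peaks = default_peak_inventory(rt_span=self.rt_span)

    @property
    def window_scheme(self) -> WindowScheme:
        return tiled_window_scheme(self.n_windows)

    def with_signal(self, fold_change: float, signal_location: str = "ms1_and_ms2"):
        """Same inventory with every discriminative peak's signal re-dialled."""
        peaks = [
            replace(p, fold_change=fold_change if p.discriminative else 1.0,
                    signal_location=signal_location)
            for p in self.peaks
        ]
        return replace(self, peaks=peaks)


def _window_index(scheme: WindowScheme, mz: float) -> int:
    for i, (lo, hi) in enumerate(scheme.windows):
        # half-open tiles, top window closed, so routing is unambiguous
        if lo <= mz < hi or (i == len(scheme) - 1 and mz == hi):
            return i
    raise ConfigError(f"precursor m/z {mz} falls outside every isolation window")


def _merge_points(mz: np.ndarray, intensity: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sort by m/z and sum intensities at duplicate m/z (strict ordering)."""
    if mz.size == 0:
        return mz, intensity
    order = np.argsort(mz, kind="stable")
    mz, intensity = mz[order], intensity[order]
    uniq, inverse = np.unique(mz, return_inverse=True)
    summed = np.bincount(inverse, weights=intensity)
    return uniq, summed


def generate_run(class_label: int, config: SyntheticCohortConfig, seed: int) -> MsRun:
    """Simulate one sample's acquisition.

    At each of ``n_scans`` evenly spaced RTs, every peak contributes a
    point at its precursor m/z to the MS1 scan and one point per fragment
    to its window's MS2 scan, with intensity
    base * gaussian(rt) * lognormal noise * fold change (fold applied in
    class 1 for discriminative peaks, in MS1 only when the signal location
    covers MS1).
    """
    if class_label not in (0, 1):
        raise ValidationError(f"class_label must be 0 or 1, got {class_label}")
    scheme = config.window_scheme
    routing = [_window_index(scheme, p.precursor_mz) for p in config.peaks]

    rng = np.random.default_rng(seed)
    rts = np.linspace(0.0, config.rt_span, config.n_scans)

    ms1_scans: list[Scan] = []
    ms2_scans: dict[int, list[Scan]] = {i: [] for i in range(len(scheme))}
    for rt in rts:
        ms1_mz, ms1_int = [], []
        frag_mz: dict[int, list[float]] = {i: [] for i in range(len(scheme))}
        frag_int: dict[int, list[float]] = {i: [] for i in range(len(scheme))}
        for peak, widx in zip(config.peaks, routing):
            elution = np.exp(-0.5 * ((rt - peak.rt_center) / peak.rt_sigma) ** 2)
            if elution < 1e-12:
                continue
            fold = peak.fold_change if (peak.discriminative and class_label == 1) else 1.0
            ms1_fold = fold if peak.signal_location == "ms1_and_ms2" else 1.0
            noise = rng.lognormal(0.0, config.noise_sigma)
            ms1_mz.append(peak.precursor_mz)
            ms1_int.append(peak.base_intensity * elution * noise * ms1_fold)
            for fmz, rel in peak.fragments:
                fnoise = rng.lognormal(0.0, config.noise_sigma)
                frag_mz[widx].append(fmz)
                frag_int[widx].append(peak.base_intensity * rel * elution * fnoise * fold)

        nbg = config.n_background_points
        if nbg:
            bg_mz = rng.uniform(*MS1_MZ_RANGE, size=nbg)
            bg_int = rng.exponential(config.background_scale, size=nbg)
            ms1_mz.extend(bg_mz)
            ms1_int.extend(bg_int)
        mz, inten = _merge_points(np.asarray(ms1_mz), np.asarray(ms1_int))
        ms1_scans.append(Scan(1, float(rt), mz, inten))

        for widx, (lo, hi) in enumerate(scheme.windows):
            wmz, wint = list(frag_mz[widx]), list(frag_int[widx])
            if nbg:
                bg_mz = rng.uniform(*MS2_MZ_RANGE, size=nbg)
                bg_int = rng.exponential(config.background_scale, size=nbg)
                wmz.extend(bg_mz)
                wint.extend(bg_int)
            mz, inten = _merge_points(np.asarray(wmz), np.asarray(wint))
            ms2_scans[widx].append(Scan(2, float(rt), mz, inten, (lo, hi)))

    run_id = f"sample_s{seed}_c{class_label}"
    return MsRun(run_id, ms1_scans, ms2_scans, scheme)


def generate_cohort(
    config: SyntheticCohortConfig,
) -> tuple[list[MsRun], pd.DataFrame]:
    """Simulate a balanced two-class cohort.

    Returns 2 * n_per_class runs (class 0 first) and a labels table with
    columns sample_id, label. Sample seeds derive from the cohort seed and
    the sample index.
    """
    if config.n_per_class < 2:
        raise ConfigError("n_per_class must be >= 2")
    runs, rows = [], []
    for i in range(2 * config.n_per_class):
        label = 0 if i < config.n_per_class else 1
        run = generate_run(label, config, derive_seed(config.seed, f"sample-{i}"))
        run.run_id = f"sample{i:03d}_c{label}"
        runs.append(run)
        rows.append({"sample_id": run.run_id, "label": label})
    return runs, pd.DataFrame(rows)
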