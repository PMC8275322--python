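import numpy as np
import pytest

from rawms.rasterize import RasterConfig
from rawms.spectra_io import MsRun, Scan, WindowScheme


@pytest.fixture
def tiny_run() -> MsRun:
    """Two MS1 scans and one isolation window with two MS2 scans."""
    ms1 = [
        Scan(1, 10.0, [450.0, 700.5, 1100.0], [5.0, 2.0, 9.5]),
        Scan(1, 70.0, [500.25, 900.0], [1.0, 4.0]),
    ]
    window = (400.0, 824.5)
    ms2 = {
        0: [
            Scan(2, 10.5, [150.0, 1200.0], [3.0, 6.0], window),
            Scan(2, 70.5, [333.25], [2.5], window),
        ]
    }
    return MsRun("tiny", ms1, ms2, WindowScheme([window]))


@pytest.fixture
def small_config() -> RasterConfig:
    return RasterConfig(grid_size=64)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_series(rng: np.random.Generator, n_scans: int, max_points: int) -> list[Scan]:
    """A random MS1-like scan series for oracle comparisons."""
    rts = np.sort(rng.uniform(0.0, 300.0, size=n_scans))
    rts[-1] = max(rts[-1], rts[0] + 1.0)  # guarantee RT extent
    scans = []
    for rt in rts:
        n = int(rng.integers(0, max_points + 1))
        mz = np.unique(rng.uniform(0.0, 2000.0, size=n))
        intensity = rng.exponential(10.0, size=mz.size)
        scans.append(Scan(1, float(rt), mz, intensity))
    return scans
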