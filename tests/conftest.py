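import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_dataset():
    """One synthetic dataset at the default study conditions, shared by the
    detection/classification tests to keep the suite fast."""
    from peakshift import SimulationConfig, simulate_dataset

    return simulate_dataset(SimulationConfig(seed=20230901))


@pytest.fixture(scope="session")
def default_peaks(default_dataset):
    from peakshift import PeakParams, call_peaks

    ds = default_dataset
    return call_peaks([ds.control, ds.mutant], PeakParams())


def reciprocal_overlap(a, b):
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    return min(inter / (a[1] - a[0]), inter / (b[1] - b[0]))


@pytest.fixture(scope="session")
def overlap():
    return reciprocal_overlap


def random_track(rng, n=None, chrom="chrT"):
    """A bumpy random depth track exercising all landmark kinds."""
    from peakshift import DepthTrack

    n = n or int(rng.integers(30, 121))
    values = rng.poisson(3.0, n).astype(float)
    for _ in range(int(rng.integers(0, 4))):
        center = int(rng.integers(0, n))
        width = int(rng.integers(2, 12))
        amp = float(rng.uniform(3, 25))
        x = np.arange(n)
        values += amp * np.exp(-0.5 * ((x - center) / max(width / 4, 1)) ** 2)
    return DepthTrack(chrom, 10, values)
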