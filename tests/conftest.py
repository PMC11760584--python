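import warnings

import numpy as np
import pytest

import inkpd

warnings.filterwarnings("ignore", message=".*non-positive timestamp.*")


@pytest.fixture(scope="session")
def small_cohort() -> inkpd.Cohort:
    """Tiny 3-class cohort for unit tests (short recordings, 3 per class)."""
    spec = inkpd.CohortSpec(n_per_class=3, duration=4.0, seed=7)
    return inkpd.generate_cohort(spec)


@pytest.fixture(scope="session")
def one_sample(small_cohort) -> inkpd.HandwritingSample:
    return next(iter(small_cohort.samples.values()))


def make_sample(x, y, *, pressure=None, tilt=None, azimuth=None, button=None,
                fs=200.0):
    """Hand-built recording with 5 ms integer-millisecond timestamps."""
    n = len(x)
    return inkpd.HandwritingSample(
        x=np.asarray(x, float), y=np.asarray(y, float),
        t=np.arange(n) * 5.0,
        button=np.ones(n) if button is None else np.asarray(button, float),
        azimuth=np.full(n, 45.0) if azimuth is None else np.asarray(azimuth, float),
        tilt=np.full(n, 50.0) if tilt is None else np.asarray(tilt, float),
        pressure=np.full(n, 100.0) if pressure is None else np.asarray(pressure, float),
        fs=fs, tick_duration=1e-3,
    )


@pytest.fixture
def sample_factory():
    return make_sample
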