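import numpy as np
import pytest

from icgfa.pipeline import CohortSettings, make_cohort
from icgfa.synthetic import (
    AcquisitionParams,
    NoiseParams,
    PerfusionCurveParams,
    generate_trace,
)
from icgfa.trace import FluorescenceTrace


@pytest.fixture
def linear_ramp_recording():
    """Noiseless linear-rise recording: F0=10, Fmax=110, onset 10 s, rise 20 s."""
    curve = PerfusionCurveParams(
        baseline_intensity=10.0,
        peak_intensity=110.0,
        onset_time=10.0,
        rise_shape="linear",
        rise_duration_or_rate=20.0,
        washout_rate=0.02,
        plateau_fraction=0.6,
    )
    return generate_trace(curve, AcquisitionParams(25.0, 120.0), NoiseParams(seed=0))


@pytest.fixture(scope="session")
def small_cohort():
    """Twelve seeded noisy recordings spanning the default steepness range."""
    return make_cohort(CohortSettings(n_recordings=12, seed=11))


@pytest.fixture
def noisy_trace():
    """Synthetic noisy monotone trace for smoother comparisons."""
    rng = np.random.default_rng(42)
    n = 2000
    times = np.arange(n) / 25.0
    clean = 10 + 100 / (1 + np.exp(-0.3 * (times - 40)))
    return FluorescenceTrace(times, clean + rng.normal(0, 1.5, n), 25.0)


def random_trace(rng, n_min=30, n_max=120, frame_rate=25.0):
    """Unstructured random trace used by the estimator-oracle tests."""
    n = int(rng.integers(n_min, n_max + 1))
    values = rng.uniform(0, 100, n)
    return FluorescenceTrace(np.arange(n) / frame_rate, values, frame_rate)
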