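import numpy as np
import pytest

from kayakforce import SessionSpec, generate_force_session


@pytest.fixture(scope="session")
def maximal_session():
    """Noiseless bout in the maximal-effort regime (125 SPM, ~400 N peaks)."""
    spec = SessionSpec(duration=20.0, stroke_rate=125.0, push_peak_left=400.0,
                       push_peak_right=380.0, push_duty=0.85, baseline=20.0,
                       noise_sd=0.0, seed=0)
    trace, truth = generate_force_session(spec)
    return spec, trace, truth


@pytest.fixture(scope="session")
def fifteen_push_session():
    """Noiseless session whose duration holds exactly 15 left pushes."""
    spec = SessionSpec(duration=15 * 2 * 60.0 / 125.0, stroke_rate=125.0,
                       push_peak_left=400.0, push_peak_right=400.0,
                       push_duty=0.85, baseline=20.0, noise_sd=0.0)
    trace, truth = generate_force_session(spec)
    assert len(truth.peak_times_left) == 15
    return spec, trace, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
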