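import pytest
from hypothesis import HealthCheck, settings

import ffr
from ffr.observers import SubsamplingParams, VeridicalParams

settings.register_profile(
    "repro", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def wheel48():
    return ffr.WHEEL48


@pytest.fixture(scope="session")
def small_filled_session():
    """300 trials from a sub-sampling observer (N=24, sigma=4)."""
    session = ffr.generate_session(300, observer_id="unit", seed=1234)
    return ffr.simulate_dataset(session, SubsamplingParams(24, 4.0), seed=4321)


@pytest.fixture(scope="session")
def veridical_sessions():
    """Three noiseless veridical observers: folded curves are ground truth."""
    out = []
    for i in range(3):
        s = ffr.generate_session(450, observer_id=f"v{i}", seed=50 + i)
        out.append(ffr.simulate_dataset(s, VeridicalParams(0.0), seed=60 + i))
    return out
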