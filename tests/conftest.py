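import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from osteoflow import CONTROL, NO_PMD, SynthConfig, Trace

settings.register_profile(
    "default", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_config() -> SynthConfig:
    return SynthConfig()


@pytest.fixture(scope="session")
def clean_config() -> SynthConfig:
    """No noise, drift or artifacts: rendered traces equal their truth."""
    return SynthConfig(noise_sd_frac=0.0, drift_slope=0.0, artifact_rate=0.0)


def flat_trace(values, dt: float = 1.73, **labels) -> Trace:
    values = np.asarray(values, dtype=float)
    defaults = dict(scaffold_id="S1", condition=CONTROL, roi_id="R1",
                    pmd_status=NO_PMD)
    defaults.update(labels)
    return Trace(times=np.arange(len(values)) * dt, fluorescence=values, **defaults)


@pytest.fixture
def make_trace():
    return flat_trace
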