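import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

import flowphantom as fp
from flowphantom.fileio import RunConfig
from flowphantom.pipeline import simulate_measurement


@pytest.fixture(scope="session")
def schedule():
    return fp.build_frame_schedule(fp.default_frame_spec())


@pytest.fixture(scope="session")
def fixtures():
    return fp.load_fixtures()


@pytest.fixture(scope="session")
def noiseless_measurement():
    """One noiseless simulated scan at the mid-grid condition (Qref=100 ml/min)."""
    cfg = RunConfig(noise_scale=0.0, qpump=200.0, constriction_fraction=0.5,
                    isf_true=0.1, delay_true_s=5.0)
    return cfg, simulate_measurement(cfg)
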