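import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cdvim.phantom import PhantomConfig, build_phantom
from cdvim.pipeline import track_dtcp
from cdvim.tracking import TrackingParams

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def det_config():
    """Noise-free study conditions: no orientation dispersion, no jitter."""
    return PhantomConfig(dispersion_deg=0.0, jitter_sd_mm=(0.0, 0.0, 0.0))


@pytest.fixture(scope="session")
def det_phantom(det_config):
    return build_phantom(det_config, seed=1)


@pytest.fixture(scope="session")
def default_phantom():
    """Default conditions (8 deg dispersion), single canonical subject."""
    return build_phantom(PhantomConfig(jitter_sd_mm=(0.0, 0.0, 0.0)), seed=1)


@pytest.fixture(scope="session")
def params():
    return TrackingParams()


@pytest.fixture(scope="session")
def det_dtcp_left(det_phantom, params):
    """Deterministic combined left-tract reconstruction, reused across tests."""
    combined, log = track_dtcp(det_phantom, "L", params, np.random.default_rng(0))
    return combined, log
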