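import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lamap import phantom as ph

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def brain_phantom() -> ph.Phantom:
    return ph.default_phantom()


@pytest.fixture(scope="session")
def group_params() -> ph.GroupParams:
    return ph.default_group_params()


@pytest.fixture()
def noiseless_instrument() -> ph.InstrumentModel:
    return ph.InstrumentModel(noise_model="none", drift_endpoint_factor=1.0)


def make_uniform_phantom(
    n_lines: int = 12, n_cols: int = 40, margin: int = 3, name: str = "cortex"
) -> ph.Phantom:
    """Single rectangular region on glass, default acquisition geometry."""
    rects = [(name, margin, n_lines - margin, margin, n_cols - margin)]
    return ph.build_phantom(rects, (n_lines, n_cols))


@pytest.fixture()
def uniform_phantom() -> ph.Phantom:
    return make_uniform_phantom()


def interior_mask(region_mask: np.ndarray, pad: int = 2) -> np.ndarray:
    """Region pixels whose ablation-spot window stays inside the region.

    Smearing acts only along the travel (column) direction, so the interior
    is the region eroded by ``pad`` columns on each side.
    """
    out = region_mask.copy()
    for shift in range(1, pad + 1):
        out &= np.roll(region_mask, shift, axis=1)
        out &= np.roll(region_mask, -shift, axis=1)
    return out
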