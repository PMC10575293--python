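import numpy as np
import pytest

from ossify import fem
from ossify.config import SimConfig
from ossify.geometry import (
    build_miniature_domain,
    uniform_box_domain,
)


@pytest.fixture(scope="session")
def mini_domain():
    """Miniature REG-style domain shared across tests (read-only)."""
    return build_miniature_domain("REG")


@pytest.fixture(scope="session")
def mini_config():
    return SimConfig(
        design_id="REG", miniature=True, total_days=4, seed=7, fe_coarsening=4
    )


@pytest.fixture()
def box_domain():
    """Small homogeneous callus box for mechanics unit tests."""
    return uniform_box_domain((4, 4, 4), spacing=0.05)


def homogeneous_materials(domain, E=0.2, nu=0.167):
    return fem.MaterialField(
        E=np.full(domain.dims, float(E)), nu=np.full(domain.dims, float(nu))
    )
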