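import numpy as np
import pytest

from rtfast import PipetteGeometry


@pytest.fixture
def geometry() -> PipetteGeometry:
    """A typical mid-sized nanopipette (30 nm tip diameter scale)."""
    return PipetteGeometry(
        tip_radius_nm=15.0,
        half_cone_angle_rad=0.1,
        conductivity_S_per_m=8.6,
        open_conductance_nS=37.7,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240916)
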