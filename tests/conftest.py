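import numpy as np
import pytest

from smslge.phantom import (
    PhantomConfig,
    make_coil_maps,
    make_phantom,
    render_single_shot,
)
from smslge.sms_encode import ProtocolParams


@pytest.fixture(scope="session")
def phantom_small():
    return make_phantom(PhantomConfig(), seed=0)


@pytest.fixture(scope="session")
def sms_params():
    return ProtocolParams(
        n_slices=2, multiband=2, inplane_accel=5, phase_oversampling=2.0,
        matrix=(64, 64),
    )


@pytest.fixture(scope="session")
def full_params():
    """Same geometry as the accelerated arm but fully sampled."""
    return ProtocolParams(
        n_slices=2, multiband=2, inplane_accel=1, phase_oversampling=2.0,
        matrix=(64, 64),
    )


@pytest.fixture(scope="session")
def coils8(sms_params):
    return make_coil_maps(8, (sms_params.ny_ext, 64), seed=2)


@pytest.fixture(scope="session")
def slice_images(phantom_small, sms_params):
    i1 = render_single_shot(phantom_small, 0, sms_params.ti)
    i2 = render_single_shot(phantom_small, 1, sms_params.ti)
    return i1, i2


@pytest.fixture(scope="session")
def unit_coils(sms_params):
    """Single uniform coil on the extended grid (exactness tests)."""
    from smslge.phantom import CoilMaps

    return CoilMaps(
        n_coils=1,
        maps=np.ones((1, sms_params.ny_ext, sms_params.matrix[1]), complex),
    )
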