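import numpy as np
import pytest

import forktime as ft


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def nominal():
    return ft.nominal_layout()


@pytest.fixture
def g4_layout():
    return ft.nominal_layout(obstacle=True)


@pytest.fixture
def acq():
    """Small, fast acquisition for unit tests (study z-geometry retained)."""
    return ft.AcquisitionConfig(n_frames=80, ny=64, nx=64)


@pytest.fixture
def det_params(acq):
    import forktime.foci as foci

    return foci.DetectionParams(
        sigma_z_vox=acq.psf_sigma_z / acq.z_step,
        sigma_xy_vox=acq.psf_sigma_xy / acq.pixel_size,
    )
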