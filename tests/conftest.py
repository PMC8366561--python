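import numpy as np
import pytest

from texhist import PhantomSpec, make_lesion_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def phantom_spec():
    return PhantomSpec()


@pytest.fixture
def lesion(phantom_spec):
    """One moderately heterogeneous synthetic lesion."""
    return make_lesion_phantom(phantom_spec, z=0.5, rng=0)


@pytest.fixture
def homogeneous_spec():
    """Phantom with no blobs, no noise, no air: constant-intensity ROI."""
    return PhantomSpec(
        ct_noise_sd_hu=0.0,
        blob_count_base=0.0,
        air_pocket_prob=0.0,
        pet_noise_sd_suv=0.0,
        pet_texture_sd_suv=0.0,
        pet_psf_sigma_px=0.0,
    )
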