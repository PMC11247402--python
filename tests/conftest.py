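import numpy as np
import pytest

from synthreg.synthesis import GenerationConfig, random_shape_labels


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def shape_map():
    """A 32x32 shape label map with 4 anatomy labels and a distractor shell."""
    return random_shape_labels((32, 32), num_labels=4, smoothness=8.0, seed=3)


@pytest.fixture
def desk_gen():
    return GenerationConfig.desk_2d()


@pytest.fixture
def quiet_gen():
    """Generation config with every randomized corruption/augmentation off."""
    return GenerationConfig(
        translation_range=0.0, rotation_range=0.0, scale_range=(1.0, 1.0),
        shear_range=0.0, warp_amplitude=0.0, crop_probability=0.0,
        noise_sd_range=(0.0, 0.0), blur_fwhm_range=(0.0, 0.0),
        bias_amplitude=0.0, gamma_log_sd=0.0,
        downsample_factor_range=(1.0, 1.0))
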