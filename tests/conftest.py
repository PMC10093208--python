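import numpy as np
import pytest

from astromito.simulate import AcquisitionConfig, FieldParams

# parameters for fast, noise-free rendering used across test modules
CLEAN = dict(shot_noise=False, read_noise=0.0, background=0.0, diffusion=0.0)


@pytest.fixture
def small_config():
    return AcquisitionConfig(n_frames=2, image_shape=(256, 256))


@pytest.fixture
def clean_params():
    return FieldParams(n_mitochondria=10, **CLEAN)


def capsule_mask(shape, center, length_um, width_um, theta, pixel_size=0.07):
    """Ideal (unrendered) capsule mask: tip-to-tip length, full width, µm."""
    from astromito.simulate import _dist_to_segment

    r = width_um / 2.0 / pixel_size
    half = (length_um - width_um) / 2.0 / pixel_size
    u = np.array([np.sin(theta), np.cos(theta)])
    c = np.asarray(center, float)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return _dist_to_segment(yy, xx, c - half * u, c + half * u) <= r
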