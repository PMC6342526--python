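import numpy as np
import pytest

from nucratio.synthetic import SynthParams, generate_ground_truth, render_stack


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_params():
    """A small, quick synthetic scene: a dozen nuclei in a 16x64x64 grid."""
    return SynthParams(
        grid_shape=(16, 64, 64),
        voxel_spacing=(1.0, 0.5, 0.5),
        n_nuclei_per_domain=6,
        nucleus_radius_range=(1.2, 1.8),
        seed=42,
    )


@pytest.fixture
def clean_params(small_params):
    """Same scene with noise and background off (exact forward model)."""
    p = small_params
    return SynthParams(
        grid_shape=p.grid_shape,
        voxel_spacing=p.voxel_spacing,
        n_nuclei_per_domain=p.n_nuclei_per_domain,
        nucleus_radius_range=p.nucleus_radius_range,
        background_level=0.0,
        gaussian_noise_sd=0.0,
        poisson_noise=False,
        seed=42,
    )


@pytest.fixture
def clean_scene(clean_params):
    gt = generate_ground_truth(clean_params)
    stack = render_stack(gt, clean_params, psf=None)
    return gt, stack, clean_params
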