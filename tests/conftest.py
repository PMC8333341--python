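import numpy as np
import pytest

from tensionmap.orientation import AlphaTriplet, DEFAULT_ALPHAS


@pytest.fixture
def alphas():
    return AlphaTriplet(*DEFAULT_ALPHAS)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def platelet_scene():
    from tensionmap.synthetic import make_platelet_scene

    return make_platelet_scene(shape=(96, 96), radius_um=2.0, n_lobes=2, seed=7)


def render_and_fit(scene, noise=None, phases=5, modulation=0.8, mask_quantile=60.0):
    """Convenience: scene -> raw montage -> corrected triplet -> map."""
    from tensionmap.orientation import fit_image_triplet
    from tensionmap.preprocess import correct_montage, phase_average
    from tensionmap.synthetic import NoiseModel, render_montage

    if noise is None:
        noise = NoiseModel(shot_noise=False, baseline=200.0)
    montage = render_montage(scene, phases=phases, modulation=modulation, noise=noise)
    triplet = phase_average(correct_montage(montage, subtract_percentile=False))
    return fit_image_triplet(triplet, mask_quantile=mask_quantile)
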