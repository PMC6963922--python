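import numpy as np
import pytest

from hsifruit.cube import ReferenceFrames, WavelengthAxis, correct_reflectance
from hsifruit.synthetic import SceneConfig, make_signature, render_scene


@pytest.fixture(scope="session")
def default_axis():
    return WavelengthAxis.default()


@pytest.fixture(scope="session")
def signatures():
    return tuple(make_signature(c, seed=7) for c in range(3))


@pytest.fixture(scope="session")
def noiseless_scene(signatures):
    """Small noise-free scene: corrected pixels equal the class signatures."""
    cfg = SceneConfig(
        n_fruits_per_class=(3, 3, 3),
        scene_width=160,
        scene_length_L=120,
        noise_sd_additive=0.0,
        illumination_gain_sd=0.0,
        fruit_scale_sd=0.0,
        seed=11,
    )
    return render_scene(signatures, cfg) + (cfg,)


@pytest.fixture(scope="session")
def noisy_scene(signatures):
    """20-fruit scene at the default noise level."""
    cfg = SceneConfig(
        n_fruits_per_class=(7, 7, 6),
        scene_width=240,
        scene_length_L=150,
        seed=13,
    )
    return render_scene(signatures, cfg) + (cfg,)


@pytest.fixture(scope="session")
def noisy_reflectance(noisy_scene):
    raw, dark, white, truth, cfg = noisy_scene
    return correct_reflectance(raw, ReferenceFrames(dark=dark, white=white)), truth
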