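import numpy as np
import pytest

from actintrace import (
    EnhancementConfig,
    LineResponseConfig,
    MCAConfig,
    ThresholdConfig,
    compose_scene,
    curvelet_dictionary,
    enhance,
    mca_decompose,
    multiscale_response,
    random_scene,
    udwt_dictionary,
    wellner_binarize,
)
from actintrace.synthetic import FilamentSpec


@pytest.fixture(scope="session")
def dictionaries():
    return curvelet_dictionary(), udwt_dictionary()


@pytest.fixture(scope="session")
def line_scene():
    """Clean scene: straight fibers only, no artifacts, no noise."""
    specs = [
        FilamentSpec(center=(40.0, 64.0), angle_deg=0.0, length_px=90, width_px=3),
        FilamentSpec(center=(80.0, 64.0), angle_deg=60.0, length_px=70, width_px=2),
        FilamentSpec(center=(64.0, 40.0), angle_deg=110.0, length_px=60, width_px=4),
    ]
    return compose_scene(specs, shape=(128, 128), n_blobs=0, noise_sigma=0.0, seed=0)


@pytest.fixture(scope="session")
def noisy_scene():
    """Small composed scene: fibers + blobs + noise (sigma 0.04)."""
    return random_scene(n_fibers=6, shape=(128, 128), seed=11)


@pytest.fixture(scope="session")
def decomposed_noisy_scene(noisy_scene, dictionaries):
    """Decomposition at a reduced iteration count for module-level tests."""
    d_f, d_a = dictionaries
    return mca_decompose(noisy_scene.composite, d_f, d_a, MCAConfig(n_iter=30))


@pytest.fixture(scope="session")
def detection_products(noisy_scene, decomposed_noisy_scene):
    """Enhanced image, response field and binary mask for the small scene."""
    u_E = enhance(decomposed_noisy_scene.fibers, EnhancementConfig())
    u_G = multiscale_response(u_E, LineResponseConfig())
    u_B = wellner_binarize(u_G, ThresholdConfig())
    return u_E, u_G, u_B
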