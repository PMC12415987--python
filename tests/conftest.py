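import numpy as np
import pytest

from nucleoquant import SceneConfig, generate_scene


@pytest.fixture(scope="session")
def clean_scene():
    """Noise-free scene with 20 well-separated mononucleated cells."""
    cfg = SceneConfig(n_cells=20, seed=42, poisson_noise=False,
                      gaussian_noise_sd=0.0)
    return generate_scene(cfg)


@pytest.fixture(scope="session")
def noisy_scene():
    """Default-noise scene, vehicle-like."""
    cfg = SceneConfig(n_cells=30, seed=7)
    return generate_scene(cfg)


@pytest.fixture(scope="session")
def mnc_scene():
    """Exposed-like scene containing giant and multinucleated cells."""
    cfg = SceneConfig(n_cells=30, seed=11, giant_fraction=0.3,
                      mnc_fraction=0.15)
    return generate_scene(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
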