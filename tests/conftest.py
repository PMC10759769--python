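"""Shared fixtures: small synthetic scenes and datasets.

Everything is generated at test time; heavier artifacts are session-scoped
so rendering and extraction run once.
"""

import numpy as np
import pytest

from kiwifuse.synth import (
    DatasetConfig,
    default_scene,
    generate_dataset,
    make_region_profiles,
    render_middle_cut,
    render_whole_fruit,
)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def profiles():
    """Full-separation, low-noise region profiles."""
    return make_region_profiles(separation=1.0, noise_scale=0.3)


@pytest.fixture(scope="session")
def noiseless_profiles():
    return make_region_profiles(separation=1.0, noise_scale=0.0)


@pytest.fixture(scope="session")
def scene512():
    return default_scene(512, noise_sd=0.75)


@pytest.fixture(scope="session")
def whole_render(scene512):
    return render_whole_fruit(scene512, np.random.default_rng(7))


@pytest.fixture(scope="session")
def cut_render(scene512):
    return render_middle_cut(scene512, np.random.default_rng(7))


@pytest.fixture(scope="session")
def small_dataset():
    """15 samples (5 per region) at 256 px, low noise."""
    return generate_dataset(DatasetConfig(
        n_per_region=5, seed=3, separation=1.0, noise_scale=0.3,
        image_size=256))
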