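import dataclasses

import numpy as np
import pytest

from larvalight.phantom import PhantomConfig


@pytest.fixture
def small_config():
    """A fast phantom: fewer cells, smaller frame, defaults otherwise."""
    return PhantomConfig(image_shape=(120, 400), n_cells=60)


@pytest.fixture
def clean_config(small_config):
    """Noiseless, background-free phantom for exact-recovery tests."""
    return dataclasses.replace(
        small_config,
        noise_sd=0.0,
        background_level=0.0,
        body_level=0.0,
        marker_background=0.0,
        intensity_cv=0.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
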