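import numpy as np
import pytest

from myoculture import ChannelStack, SceneParams, generate_field


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def clean_params():
    """Noise-free, blur-free, well-separated scene."""
    return SceneParams(
        n_nuclei=60,
        shape=(384, 384),
        noise_sd=0.0,
        blur_sigma_px=0.0,
        min_nucleus_spacing_px=14.0,
        p_green=0.5,
        p_red=0.4,
        p_double=0.2,
        seed=7,
    )


@pytest.fixture
def clean_field(clean_params):
    return generate_field(clean_params)


@pytest.fixture
def three_channel_stack(rng):
    shape = (64, 64)
    return ChannelStack(
        channels={
            name: rng.integers(0, 256, size=shape, dtype=np.uint8)
            for name in ("dapi", "green", "red")
        }
    )
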