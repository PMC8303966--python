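import numpy as np
import pytest

from numgen import stimuli
from numgen.model import ModelConfig, PixelTransformer, TransformerCore


@pytest.fixture
def rng():
    return np.random.default_rng(123)


#: 10x10 binary frames with unit-radius dots: the smallest geometry at which
#: two dots place easily, used for fast training checks (sequence length 101).
MINI_SPEC = stimuli.FrameSpec(width=10, height=10, intensity_levels=2,
                              background_level=0, foreground_level=1)
MINI_PARAMS = stimuli.DotParams(mu_frame=8.0, sigma_dot=1.0,
                                uniform_radius=1.0, margin=1.0)


@pytest.fixture(scope="session")
def mini_bundle():
    return stimuli.build_dataset("uniform", numerosities=(1, 2),
                                 split_sizes=(600, 120, 120), master_seed=11,
                                 spec=MINI_SPEC, params=MINI_PARAMS)


def mini_estimator(**overrides):
    kwargs = dict(n_layers=2, d_model=32, n_heads=4, vocab_size=2,
                  frame_shape=(10, 10), numerosities=(1, 2), ff_width=64,
                  dropout=0.0, batch_size=128, learning_rate=1e-3,
                  epochs=2, patience=5, seed=0)
    kwargs.update(overrides)
    return PixelTransformer(**kwargs)


def toy_core(n_pixels=9, vocab=3, d=8, heads=2, layers=2, seed=0,
             dtype=np.float64, numerosities=(1, 2)):
    """Small random-weight transformer used by the architectural oracles."""
    cfg = ModelConfig(n_layers=layers, d_model=d, n_heads=heads,
                      vocab_size=vocab, n_pixels=n_pixels,
                      numerosities=numerosities, ff_width=2 * d, dropout=0.0)
    return TransformerCore(cfg, seed=seed, dtype=dtype)


@pytest.fixture
def untrained_tiny_estimator():
    est = PixelTransformer(n_layers=2, d_model=32, n_heads=4, vocab_size=2,
                           frame_shape=(12, 12), numerosities=(1, 2, 3),
                           ff_width=128, dropout=0.0, seed=0)
    est.core_ = est._build_core()
    return est
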