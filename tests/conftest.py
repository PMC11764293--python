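import numpy as np
import pytest

from fnirsda.model import ModelConfig
from fnirsda.synthgen import GeneratorConfig, make_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_model_config():
    """A scaled-down configuration exercising every stage (float64 so numeric
    oracles hold to tight tolerances)."""
    return ModelConfig(in_channels=4, in_samples=40, time_reduce=20,
                       expand_width=8, gated_width=4, depthwise_kernel=5,
                       pointwise_out=3, fc_hidden=6, feature_dim=5,
                       dropout=0.0, dtype="float64")


@pytest.fixture(scope="session")
def small_dataset():
    """3 subjects x 3 classes x 4 trials, mild shift, deterministic."""
    cfg = GeneratorConfig(n_subjects=3, trials_per_class=4, seed=42)
    return make_dataset(cfg, shift_level="mild")
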