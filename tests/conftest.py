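import numpy as np
import pytest

from fazseg.models import ArchitectureConfig, build_model
from fazseg.synthetic import SynthConfig, dataset_arrays, make_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_arch():
    """A very small fixed-width network for fast training tests."""
    return ArchitectureConfig(
        input_height=32, input_width=32, width_policy="fixed",
        base_or_fixed_width=8, depth=2, attention_enabled=True,
        skip_mode="add", up_mode="upsample", midblock_min_channels=4,
        dropout_rate=0.1)


@pytest.fixture
def tiny_model(tiny_arch):
    return build_model(tiny_arch, seed=7)


@pytest.fixture(scope="session")
def tiny_clear_data():
    """Small clear synthetic dataset at 32x32 shared across tests."""
    cfg = SynthConfig.clear(height=32, width=32)
    train, _ = make_dataset(8, cfg, base_seed=50)
    val, _ = make_dataset(3, cfg, base_seed=200)
    test, _ = make_dataset(3, cfg, base_seed=300)
    return {
        "cfg": cfg,
        "train": dataset_arrays(train),
        "val": dataset_arrays(val),
        "test": dataset_arrays(test),
        "test_samples": test,
    }


class MapModel:
    """Duck-typed stand-in whose predict() returns fixed probability maps.

    Used to test evaluation and pipeline code without training a network.
    """

    def __init__(self, prob_maps):
        self.prob_maps = np.asarray(prob_maps, dtype=np.float32)
        self._i = 0

    def predict(self, images):
        n = len(images)
        out = self.prob_maps[self._i:self._i + n]
        if len(out) < n:                      # wrap around
            self._i = 0
            out = self.prob_maps[:n]
        self._i += n
        return out[..., None] if out.ndim == 3 else out


@pytest.fixture
def map_model_factory():
    return MapModel
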