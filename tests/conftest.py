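import numpy as np
import pytest

from mc4deep import DnaSample, GeneratorConfig, generate, stratified_folds
from mc4deep.pipeline import compact_network_config


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_samples():
    """60 windows with a strong planted motif (30 pos / 30 neg)."""
    return generate(GeneratorConfig(n_pos=30, n_neg=30, effect=0.9, seed=5))


@pytest.fixture
def tiny_folds(tiny_samples):
    return stratified_folds(tiny_samples, k=3, seed=5)


@pytest.fixture
def fast_net():
    """A very small extractor config for unit tests."""
    cfg = compact_network_config(seed=7)
    return cfg


def make_sample(seq: str, label: int = 1, sid: str = "s", modqv=None) -> DnaSample:
    return DnaSample(id=sid, sequence=seq, label=label, modqv=modqv)
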