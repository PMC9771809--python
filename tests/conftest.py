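import numpy as np
import pytest

from rnadeg.synthetic import SyntheticConfig, make_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """30 noisy constructs in the default Round-I regime (107/68, 5 channels)."""
    cfg = SyntheticConfig(n_constructs=30, seed=11)
    return cfg, make_dataset(cfg)


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Noise-free planted data, full-length scoring, no motif offsets."""
    cfg = SyntheticConfig(
        n_constructs=20, length=107, scored_length=107, seed=7, motif_effects={}
    ).noiseless()
    return cfg, make_dataset(cfg)


@pytest.fixture(scope="session")
def random_structures():
    """A pool of sampled dot-bracket structures of mixed lengths."""
    from rnadeg.synthetic import sample_structure

    rng = np.random.default_rng(99)
    structures = []
    for _ in range(60):
        n = int(rng.integers(15, 90))
        seq = "".join(rng.choice(list("ACGU"), size=n))
        structures.append((seq, sample_structure(seq, rng)))
    return structures
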