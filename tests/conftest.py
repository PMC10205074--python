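import numpy as np
import pytest

from segtag.forward import make_forward_model
from segtag.lexicon import build_lexicon, generate_sequence
from segtag.simulate import SimulationConfig, simulate_trials


@pytest.fixture(scope="session")
def fwd():
    return make_forward_model(32, (5, 5, 4), seed=0)


@pytest.fixture(scope="session")
def structured_lexicon():
    return build_lexicon(40, "native_like", seed=1)


@pytest.fixture(scope="session")
def foreign_lexicon():
    return build_lexicon(50, "foreign_like", seed=1)


@pytest.fixture(scope="session")
def random_lexicon():
    return build_lexicon(100, "random", seed=3)


def make_sequences(lexicon, n, seed, condition=""):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        s = generate_sequence(lexicon, 19, seed=int(rng.integers(2 ** 31)))
        s.condition = condition
        out.append(s)
    return out


@pytest.fixture(scope="session")
def make_seqs():
    return make_sequences


@pytest.fixture(scope="session")
def sim_dataset(fwd, structured_lexicon):
    """Small two-condition sensor dataset with a planted 2 Hz effect."""
    seqs = (make_sequences(structured_lexicon, 8, 0, "german")
            + make_sequences(structured_lexicon, 8, 1, "other"))
    cfg = SimulationConfig(
        fs_hz=600.0, snr=2.0,
        effect_2hz={"german": {"frontal": 1.0}, "other": {}},
        effect_4hz=1.0, seed=5)
    return simulate_trials(fwd, cfg, seqs)
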