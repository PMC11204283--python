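import numpy as np
import pytest

from lipwave.motion_sim import make_word_template, sample_word
from lipwave.scenarios import make_vocabulary


@pytest.fixture(scope="session")
def small_vocab():
    """Three distinct synthetic word templates."""
    return make_vocabulary(3, seed=0)


@pytest.fixture(scope="session")
def word_bank(small_vocab):
    """Four repetitions per word with mild natural variability."""
    return {
        w: sample_word(t, n=4, length_sd=0.08, amp_sd=0.08, seed=5)
        for w, t in small_vocab.items()
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
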