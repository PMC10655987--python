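import numpy as np
import pytest

from precoss.corpus import make_inventory, render_stimulus, sample_sentence
from precoss.inference import InferenceOptions


@pytest.fixture(scope="session")
def inventory():
    return make_inventory(10, seed=1)


@pytest.fixture(scope="session")
def single_syllable(inventory):
    """A noiseless 200 ms single-syllable stimulus."""
    sent = sample_sentence(inventory, 1, mean_dur_ms=200, cv=0, seed=3)
    stim = render_stimulus(sent, inventory, noise_sd=0.0, seed=3)
    return sent, stim


@pytest.fixture(scope="session")
def sentence_stimulus(inventory):
    """A noiseless multi-syllable sentence with constant durations."""
    sent = sample_sentence(inventory, 5, mean_dur_ms=200, cv=0, seed=11)
    stim = render_stimulus(sent, inventory, noise_sd=0.0, seed=11)
    return sent, stim


@pytest.fixture
def opts():
    return InferenceOptions()
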