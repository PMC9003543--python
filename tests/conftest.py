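import numpy as np
import pytest

from ambientkit import alarms, synthgen

SAMPLE_RATE = 22050


@pytest.fixture(scope="session")
def clean_corpus():
    """The 16-alarm synthetic corpus: (X, labels, waveforms)."""
    return alarms.build_clean_corpus(sample_rate=SAMPLE_RATE)


@pytest.fixture(scope="session")
def clean_result(clean_corpus):
    X, y, _ = clean_corpus
    return alarms.run_note_experiment(X, y, seed=7)


@pytest.fixture(scope="session")
def sweep_result(clean_corpus):
    """Speech-mixing sweep over the full alpha grid with the surrogate."""
    _, _, waveforms = clean_corpus
    max_len = max(len(w) for w in waveforms)
    speech = synthgen.synth_speech_surrogate(
        2 * max_len / SAMPLE_RATE, sample_rate=SAMPLE_RATE, seed=7
    )
    return alarms.speech_mixing_sweep(waveforms, speech, SAMPLE_RATE, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
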