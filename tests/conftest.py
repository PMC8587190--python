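import numpy as np
import pytest

import eanr


@pytest.fixture(scope="session")
def bank():
    return eanr.default_noise_bank()


@pytest.fixture(scope="session")
def speech():
    """One deterministic 2 s speech-like utterance."""
    return eanr.gen_speech_like(2.0, seed=7)


@pytest.fixture(scope="session")
def speech_long():
    """A 3 s utterance, long enough for stable intelligibility scoring."""
    return eanr.gen_speech_like(3.0, seed=21)


@pytest.fixture(scope="session")
def noisy_mix(speech_long, bank):
    """(clean, noisy at 0 dB, noise spec) triple used across metric tests."""
    noise = eanr.gen_noise(bank[2], 3.0, seed=5)
    return speech_long, eanr.mix_at_snr(speech_long, noise, 0.0), bank[2]
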