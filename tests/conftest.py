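import numpy as np
import pytest

from tympanomatch import (
    CENTRAL_CALL,
    SOUTHERN_CALL,
    Waveform,
    synthesize_harmonic_call,
)

try:
    from hypothesis import settings

    settings.register_profile("suite", max_examples=25, deadline=None, derandomize=True)
    settings.load_profile("suite")
except ImportError:  # pragma: no cover
    pass

AUDIO_RATE = 44100.0
VIBRO_RATE = 200000.0


@pytest.fixture(scope="session")
def central_call() -> Waveform:
    return synthesize_harmonic_call(CENTRAL_CALL)


@pytest.fixture(scope="session")
def southern_call() -> Waveform:
    return synthesize_harmonic_call(SOUTHERN_CALL)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def sine(freq_hz: float, duration_s: float = 0.5, rate: float = AUDIO_RATE,
         amplitude: float = 1.0) -> Waveform:
    t = np.arange(int(rate * duration_s)) / rate
    return Waveform(amplitude * np.sin(2 * np.pi * freq_hz * t), rate)
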