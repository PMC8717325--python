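"""Audio/trace I/O and shared signal plumbing.

Every stage of the pipeline exchanges sampled signals as :class:`Waveform` —
a plain real-valued signal plus its sample rate.  Distress-call audio
(44.1 kHz, 16-bit) and laser-vibrometer traces (200 kHz) use the same
container; only the rate differs.  Tabular results are long-format CSV and
per-run metadata is JSON, so downstream mixed-model software can consume
them directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal as sps
from scipy.io import wavfile


@dataclass(frozen=True)
class Waveform:
    """A uniformly sampled real signal.

    Parameters
    ----------
    samples
        Dimensionless amplitude values.  For 16-bit audio export the caller
        must keep ``|samples| <= 1``; vibrometer traces (velocity units) may
        exceed that and are written as float WAV.
    sample_rate
        Sampling rate in Hz, strictly positive.
    """

    samples: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("waveform must be a non-empty 1-D signal")
        if not np.all(np.isfinite(samples)):
            raise ValueError("waveform contains non-finite samples")
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be positive")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "sample_rate", float(self.sample_rate))

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.samples.size / self.sample_rate

    @property
    def nyquist(self) -> float:
        return self.sample_rate / 2.0

    def scaled(self, factor: float) -> "Waveform":
        return Waveform(self.samples * factor, self.sample_rate)

    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples**2)))


@dataclass(frozen=True)
class RunConfig:
    """Per-run plumbing: rates, the 200 Hz audio high-pass, seed, output dir.

    The seed is fixed per run and recorded in the run manifest so every
    simulated dataset is reproducible.
    """

    rng_seed: int
    output_dir: Path
    sample_rate_audio: float = 44100.0
    sample_rate_vibro: float = 200000.0
    highpass_cutoff: float = 200.0

    def __post_init__(self) -> None:
        if self.highpass_cutoff >= min(self.sample_rate_audio, self.sample_rate_vibro) / 2:
            raise ValueError("highpass cutoff must lie below the Nyquist of both streams")
        object.__setattr__(self, "output_dir", Path(self.output_dir))


def read_wav(path: str | Path) -> Waveform:
    """Read a RIFF/WAV file into a :class:`Waveform`.

    Integer PCM is rescaled to ``[-1, 1]``; float streams pass through
    unchanged.  Raises ``ValueError`` on an empty stream and lets scipy's
    format error propagate on a malformed header.
    """
    rate, data = wavfile.read(str(path))
    data = np.asarray(data)
    if data.size == 0:
        raise ValueError(f"empty audio stream: {path}")
    if data.ndim > 1:  # mixdown is out of scope; take the first channel
        data = data[:, 0]
    if data.dtype == np.int16:
        samples = data / 32768.0
    elif data.dtype == np.int32:
        samples = data / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    else:
        samples = data.astype(np.float64)
    return Waveform(samples, float(rate))


def write_wav(wave: Waveform, path: str | Path, bit_depth: str = "pcm16") -> Path:
    """Write a waveform as WAV.

    ``bit_depth`` is ``"pcm16"`` (audio; requires ``|samples| <= 1``) or
    ``"float32"`` (vibrometer traces in physical units, unbounded).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if bit_depth == "pcm16":
        peak = np.max(np.abs(wave.samples))
        if peak > 1.0 + 2**-15:
            raise ValueError("samples exceed full scale; normalize before PCM export")
        data = np.clip(np.round(wave.samples * 32768.0), -32768, 32767).astype(np.int16)
    elif bit_depth == "float32":
        data = wave.samples.astype(np.float32)
    else:
        raise ValueError(f"unsupported bit depth: {bit_depth!r}")
    wavfile.write(str(path), int(round(wave.sample_rate)), data)
    return path


def highpass(wave: Waveform, cutoff: float = 200.0) -> Waveform:
    """Zero-phase 4th-order Butterworth high-pass.

    Applied to call recordings before any measurement (cutoff 200 Hz by
    default).  Forward-backward filtering keeps temporal landmarks — onset,
    time-to-maximum — unshifted, at the price of squaring the magnitude
    response.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if cutoff >= wave.nyquist:
        raise ValueError("cutoff must lie below Nyquist")
    sos = sps.butter(4, cutoff, btype="highpass", fs=wave.sample_rate, output="sos")
    return Waveform(sps.sosfiltfilt(sos, wave.samples), wave.sample_rate)
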