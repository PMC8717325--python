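"""Parametric stimulus synthesis: tone schedules, harmonic calls, noisy calls.

The tone schedule and the two population calls mirror the stimuli used for
eardrum recordings: 100-ms pure tones with 10-ms linear ramps followed by an
equal silence, stepped from 0.1 to 40 kHz, and one synthetic distress call
per population built from that population's mean spectro-temporal
parameters.

Sound pressure level is represented as relative digital amplitude with a
declared reference: 94 dB SPL corresponds to digital full scale (amplitude
1.0).  Absolute microphone calibration is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

import numpy as np
from scipy import signal as sps

from .signal_io import Waveform

#: dB SPL that maps to digital amplitude 1.0.
SPL_FULL_SCALE_DB = 94.0

#: Short cosine taper appended after the nominal call end so the waveform
#: does not stop mid-cycle; it sits below the -20 dB envelope threshold and
#: therefore does not enter the measured duration.
_CALL_TAPER_MS = 2.0


def amplitude_for_spl(level_db_spl: float) -> float:
    """Digital amplitude of a tone at ``level_db_spl`` (re full scale = 94 dB)."""
    return 10.0 ** ((level_db_spl - SPL_FULL_SCALE_DB) / 20.0)


@dataclass(frozen=True)
class CallParams:
    """Parameters of a synthetic harmonic distress call.

    The fundamental holds at ``f0_start_hz`` through the amplitude rise and
    then sweeps linearly down to ``f0_end_hz`` at the call end, so the
    fundamental is also the dominant (loudest) frequency — the defining
    property of both population calls.  Harmonic ``k`` is attenuated by
    ``(k-1) * harmonic_rolloff_db``.
    """

    n_harmonics: int
    duration_ms: float
    time_to_max_ms: float
    f0_start_hz: float
    f0_end_hz: float
    harmonic_rolloff_db: float = 6.0
    sample_rate_hz: float = 44100.0

    def __post_init__(self) -> None:
        if not 0 < self.time_to_max_ms < self.duration_ms:
            raise ValueError("need 0 < time_to_max_ms < duration_ms")
        if self.n_harmonics < 1:
            raise ValueError("need at least one harmonic")
        if self.n_harmonics * max(self.f0_start_hz, self.f0_end_hz) >= self.sample_rate_hz / 2:
            raise ValueError("highest harmonic exceeds Nyquist (aliasing)")


#: Central-population call: 6 harmonics, 71 ms, peak at 26 ms, 2.7 -> 2.1 kHz.
CENTRAL_CALL = CallParams(
    n_harmonics=6, duration_ms=71.0, time_to_max_ms=26.0,
    f0_start_hz=2700.0, f0_end_hz=2100.0,
)

#: Southern-population call: 3 harmonics, 42 ms, peak at 19 ms, 6.3 -> 5.6 kHz.
SOUTHERN_CALL = CallParams(
    n_harmonics=3, duration_ms=42.0, time_to_max_ms=19.0,
    f0_start_hz=6300.0, f0_end_hz=5600.0,
)

POPULATION_CALLS = {"central": CENTRAL_CALL, "southern": SOUTHERN_CALL}


@dataclass(frozen=True)
class ToneStimulus:
    """A pure-tone stimulus: 100 ms with 10-ms linear ramps, then equal silence."""

    frequency_hz: float
    level_db_spl: float
    duration_ms: float = 100.0
    ramp_ms: float = 10.0
    silence_ms: float | None = None

    def __post_init__(self) -> None:
        if self.silence_ms is None:
            object.__setattr__(self, "silence_ms", self.duration_ms)
        if self.ramp_ms > self.duration_ms / 2:
            raise ValueError("ramps cannot overlap")
        if self.frequency_hz <= 0:
            raise ValueError("frequency must be positive")


class NonlinearKind(Enum):
    SUBHARMONIC = "subharmonic"
    FREQUENCY_JUMP = "frequency_jump"
    DETERMINISTIC_CHAOS = "deterministic_chaos"
    SILENCE_GAP = "silence_gap"


def schedule_frequencies_hz() -> np.ndarray:
    """The full tone-frequency schedule in Hz.

    0.1 kHz, then 0.2–9.0 kHz in 0.2-kHz steps, 9.5–20 kHz in 0.5-kHz
    steps, and 22–40 kHz in 2-kHz steps (78 frequencies; each step range
    starts above the previous range's endpoint so no frequency repeats).
    """
    return np.concatenate(
        [
            [100.0],
            np.arange(200, 9001, 200, dtype=np.float64),
            np.arange(9500, 20001, 500, dtype=np.float64),
            np.arange(22000, 40001, 2000, dtype=np.float64),
        ]
    )


def make_tone_schedule(
    spl_levels: list[float],
    counterbalance_seed: int | None = None,
    max_frequency_hz: float | None = None,
) -> list[ToneStimulus]:
    """Cross the frequency schedule with the SPL levels.

    Sorted (frequency-major) by default; pass ``counterbalance_seed`` for a
    seeded random presentation order.  ``max_frequency_hz`` truncates the
    schedule — used for reduced simulated designs.
    """
    if not spl_levels:
        raise ValueError("need at least one SPL level")
    freqs = schedule_frequencies_hz()
    if max_frequency_hz is not None:
        freqs = freqs[freqs <= max_frequency_hz]
    stimuli = [ToneStimulus(f, spl) for f in freqs for spl in spl_levels]
    if counterbalance_seed is not None:
        rng = np.random.default_rng(counterbalance_seed)
        stimuli = [stimuli[i] for i in rng.permutation(len(stimuli))]
    return stimuli


def synthesize_tone(stim: ToneStimulus, sample_rate: float) -> Waveform:
    """Render a tone stimulus followed by its silence period."""
    if stim.frequency_hz >= sample_rate / 2:
        raise ValueError("tone frequency at or above Nyquist")
    n_tone = int(round(stim.duration_ms * sample_rate / 1000.0))
    n_sil = int(round(stim.silence_ms * sample_rate / 1000.0))
    t = np.arange(n_tone) / sample_rate
    amp = amplitude_for_spl(stim.level_db_spl)
    tone = amp * np.sin(2 * np.pi * stim.frequency_hz * t)
    n_ramp = int(round(stim.ramp_ms * sample_rate / 1000.0))
    if n_ramp > 0:
        ramp = np.linspace(0.0, 1.0, n_ramp, endpoint=False)
        tone[:n_ramp] *= ramp
        tone[-n_ramp:] *= ramp[::-1]
    return Waveform(np.concatenate([tone, np.zeros(n_sil)]), sample_rate)


def call_envelope(params: CallParams) -> np.ndarray:
    """Amplitude envelope of a synthetic call, including the end taper.

    Square-root attack to the peak at ``time_to_max_ms`` (the -20 dB point
    is crossed at 1% of the rise, so measured onsets sit at the nominal call
    start), then exponential decay reaching -20 dB exactly at
    ``duration_ms``, then a short cosine taper to zero.
    """
    fs = params.sample_rate_hz
    n_call = int(round(params.duration_ms * fs / 1000.0))
    n_taper = int(round(_CALL_TAPER_MS * fs / 1000.0))
    t = np.arange(n_call + n_taper) / fs * 1000.0  # ms
    env = np.empty_like(t)
    attack = t < params.time_to_max_ms
    env[attack] = np.sqrt(t[attack] / params.time_to_max_ms)
    # decay: exp(-r (t - ttm)) with env(duration) = 0.1  (-20 dB)
    r = np.log(10.0) / (params.duration_ms - params.time_to_max_ms)
    env[~attack] = np.exp(-r * (t[~attack] - params.time_to_max_ms))
    taper = np.cos(np.linspace(0.0, np.pi / 2, n_taper)) if n_taper else np.empty(0)
    env[n_call:] *= taper**2
    return env


def _f0_trajectory(params: CallParams, n: int) -> np.ndarray:
    """Instantaneous fundamental: hold at f0_start to the peak, then sweep."""
    fs = params.sample_rate_hz
    t_ms = np.arange(n) / fs * 1000.0
    f0 = np.full(n, params.f0_start_hz)
    sweep = (t_ms >= params.time_to_max_ms) & (t_ms <= params.duration_ms)
    frac = (t_ms[sweep] - params.time_to_max_ms) / (params.duration_ms - params.time_to_max_ms)
    f0[sweep] = params.f0_start_hz + frac * (params.f0_end_hz - params.f0_start_hz)
    f0[t_ms > params.duration_ms] = params.f0_end_hz
    return f0


def synthesize_harmonic_call(params: CallParams, peak_amplitude: float = 0.9) -> Waveform:
    """Render a harmonic call with a downward frequency sweep.

    Harmonics are phase-coherent (harmonic ``k`` rides at ``k`` times the
    integrated instantaneous fundamental) and attenuated by
    ``(k-1) * harmonic_rolloff_db``.
    """
    fs = params.sample_rate_hz
    env = call_envelope(params)
    n = env.size
    f0 = _f0_trajectory(params, n)
    if params.n_harmonics * f0.max() >= fs / 2:
        raise ValueError("highest harmonic exceeds Nyquist (aliasing)")
    phase = 2 * np.pi * np.cumsum(f0) / fs
    x = np.zeros(n)
    for k in range(1, params.n_harmonics + 1):
        gain = 10.0 ** (-(k - 1) * params.harmonic_rolloff_db / 20.0)
        x += gain * np.sin(k * phase)
    x *= env
    x *= peak_amplitude / np.max(np.abs(x))
    return Waveform(x, fs)


def synthesize_noisy_call(
    duration_ms: float,
    band_low_hz: float,
    band_high_hz: float,
    time_to_max_ms: float,
    seed: int,
    sample_rate_hz: float = 44100.0,
    peak_amplitude: float = 0.9,
) -> Waveform:
    """Render a noisy (non-harmonic) call: band-limited turbulent noise
    under the same envelope model as the harmonic calls."""
    if not 0 < band_low_hz < band_high_hz < sample_rate_hz / 2:
        raise ValueError("noise band must lie inside (0, Nyquist)")
    env_params = CallParams(
        n_harmonics=1, duration_ms=duration_ms, time_to_max_ms=time_to_max_ms,
        f0_start_hz=band_low_hz, f0_end_hz=band_low_hz, sample_rate_hz=sample_rate_hz,
    )
    env = call_envelope(env_params)
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(env.size)
    sos = sps.butter(4, [band_low_hz, band_high_hz], btype="bandpass",
                     fs=sample_rate_hz, output="sos")
    x = sps.sosfiltfilt(sos, noise) * env
    x *= peak_amplitude / np.max(np.abs(x))
    return Waveform(x, sample_rate_hz)


def insert_nonlinearity(
    wave: Waveform,
    kind: NonlinearKind,
    start_ms: float,
    len_ms: float,
    f0_hz: float,
    seed: int = 0,
) -> Waveform:
    """Replace or augment a segment of a call with a nonlinear-phenomenon
    fixture (subharmonics, frequency jump, chaos-like noise, silence gap).

    These are test fixtures for segment-level detectors, not models of vocal
    dynamics; regions outside the segment are bit-identical to the input.
    """
    fs = wave.sample_rate
    i0 = int(round(start_ms * fs / 1000.0))
    i1 = i0 + int(round(len_ms * fs / 1000.0))
    if i0 < 0 or i1 > len(wave) or i1 <= i0:
        raise IndexError("segment outside waveform")
    x = wave.samples.copy()
    seg = x[i0:i1]
    n = seg.size
    t = np.arange(n) / fs
    seg_rms = np.sqrt(np.mean(seg**2))
    edge = int(round(min(1.0, len_ms / 4) * fs / 1000.0))
    ramp = np.ones(n)
    if edge:
        ramp[:edge] = np.linspace(0, 1, edge)
        ramp[-edge:] = np.linspace(1, 0, edge)
    if kind is NonlinearKind.SILENCE_GAP:
        x[i0:i1] = 0.0
    elif kind is NonlinearKind.SUBHARMONIC:
        x[i0:i1] = seg + np.sqrt(2.0) * seg_rms * ramp * np.sin(2 * np.pi * (f0_hz / 2) * t)
    elif kind is NonlinearKind.FREQUENCY_JUMP:
        jumped = np.sqrt(2.0) * seg_rms * np.sin(2 * np.pi * (1.4 * f0_hz) * t)
        x[i0:i1] = ramp * jumped + (1 - ramp) * seg
    elif kind is NonlinearKind.DETERMINISTIC_CHAOS:
        rng = np.random.default_rng(seed)
        noise = rng.standard_normal(n + 2 * int(fs * 0.005))
        lo, hi = 0.5 * f0_hz, min(4.0 * f0_hz, 0.95 * fs / 2)
        sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
        band = sps.sosfiltfilt(sos, noise)[int(fs * 0.005):][:n]
        am = 1.0 + 0.5 * np.sin(2 * np.pi * 37.0 * t + rng.uniform(0, 2 * np.pi))
        band *= am
        band *= seg_rms / np.sqrt(np.mean(band**2))
        x[i0:i1] = ramp * band + (1 - ramp) * seg
    else:  # pragma: no cover
        raise ValueError(f"unknown kind: {kind!r}")
    return Waveform(x, fs)


def vary_call_params(
    base: CallParams, rng: np.random.Generator, cv: float = 0.08
) -> CallParams:
    """Draw an individual call around a population mean (lognormal jitter of
    the continuous parameters, ±1 harmonic).  Used to build call cohorts."""
    def jitter(v: float) -> float:
        return float(v * np.exp(rng.normal(0.0, cv)))

    dur = jitter(base.duration_ms)
    ttm = min(jitter(base.time_to_max_ms), 0.8 * dur)
    nh = max(1, base.n_harmonics + int(rng.integers(-1, 2)))
    f0s = jitter(base.f0_start_hz)
    nyq = base.sample_rate_hz / 2
    while nh * f0s >= nyq:
        nh -= 1
    return replace(base, duration_ms=dur, time_to_max_ms=ttm,
                   n_harmonics=nh, f0_start_hz=f0s,
                   f0_end_hz=f0s * base.f0_end_hz / base.f0_start_hz)
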