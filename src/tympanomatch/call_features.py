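"""Spectro-temporal measurement of distress calls.

Reproduces the oscillogram/spectrogram variables used to characterize
calls: duration and time-to-maximum-amplitude from the amplitude envelope,
fundamental and dominant frequency and harmonic count from an averaged
magnitude spectrum (FFT length 1024, Hamming window, 87.5% overlap),
an ultrasound flag for energy reaching the 20–22 kHz band, harmonic/noisy
call-type classification, and the frequency-modulation pattern of the
fundamental contour.

Measurement conventions (the originals were read by eye off oscillograms
and spectrograms):

* call onset/offset are the first/last crossings of -20 dB relative to the
  envelope peak;
* spectral frequencies are measured in a segment at the beginning of the
  call (the part free of nonlinear phenomena in real recordings) — the
  first quarter of the call, extended to at least one FFT window;
* a harmonic counts when its spectral peak exceeds the spectrum median by
  at least 10 dB within ±3% of the expected comb frequency.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import signal as sps

from .matching import Spectrum
from .signal_io import Waveform

#: onset/offset threshold relative to the envelope peak.
ENVELOPE_THRESHOLD_DB = -20.0
#: tolerance around comb lines, as a fraction of the expected frequency.
COMB_TOLERANCE = 0.03
#: a spectral peak must exceed the spectrum median by this much (dB).
PEAK_PROMINENCE_DB = 10.0


class CallType(Enum):
    HARMONIC = "harmonic"
    NOISY = "noisy"


class FMPattern(Enum):
    DOWNWARD = "downward"
    UPWARD = "upward"
    INVARIANT = "invariant"
    BELL = "bell"
    U_SHAPED = "u_shaped"


@dataclass(frozen=True)
class CallFeatures:
    duration_ms: float
    time_to_max_ms: float
    fundamental_hz: float | None
    dominant_hz: float | None
    n_harmonics: int
    has_ultrasound: bool
    call_type: CallType
    fm_pattern: FMPattern | None


@dataclass(frozen=True)
class F0Track:
    """Frame-wise fundamental contour supporting FM-pattern classification."""

    times_ms: np.ndarray
    f0_hz: np.ndarray
    voiced: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_ms, dtype=np.float64)
        f = np.asarray(self.f0_hz, dtype=np.float64)
        v = np.asarray(self.voiced, dtype=bool)
        if not (t.shape == f.shape == v.shape) or t.ndim != 1:
            raise ValueError("track fields must be equal-length 1-D arrays")
        if np.any(f[v] <= 0):
            raise ValueError("voiced frames must have positive f0")
        object.__setattr__(self, "times_ms", t)
        object.__setattr__(self, "f0_hz", f)
        object.__setattr__(self, "voiced", v)


def amplitude_envelope(wave: Waveform, smooth_ms: float = 1.5) -> np.ndarray:
    """Hilbert-magnitude envelope, moving-average smoothed.

    Smoothing over a few fundamental periods removes the beat ripple a
    harmonic stack imprints on the analytic magnitude.
    """
    env = np.abs(sps.hilbert(wave.samples))
    n = max(1, int(round(smooth_ms * wave.sample_rate / 1000.0)))
    if n > 1:
        kernel = np.ones(n) / n
        env = np.convolve(env, kernel, mode="same")
    return env


def measure_envelope(wave: Waveform) -> tuple[float, float]:
    """(duration_ms, time_to_max_ms) from the -20 dB envelope crossings."""
    env = amplitude_envelope(wave)
    peak = env.max()
    if peak <= 0:
        raise ValueError("silent waveform; no envelope to measure")
    thr = peak * 10.0 ** (ENVELOPE_THRESHOLD_DB / 20.0)
    above = np.flatnonzero(env >= thr)
    onset, offset = above[0], above[-1]
    fs = wave.sample_rate
    duration_ms = (offset - onset + 1) / fs * 1000.0
    time_to_max_ms = (int(np.argmax(env)) - onset) / fs * 1000.0
    return duration_ms, time_to_max_ms


def spectrum(wave: Waveform, n_fft: int = 1024, window: str = "hamming",
             overlap: float = 0.875) -> Spectrum:
    """Welch-averaged magnitude spectrum (linear units).

    The frequency grid spacing is ``sample_rate / n_fft``; magnitudes are
    square roots of the integrated per-bin power, so ``sum(magnitude**2)``
    approximates the signal's mean-square amplitude (Parseval).
    """
    if n_fft & (n_fft - 1):
        raise ValueError("n_fft must be a power of two")
    if len(wave) < n_fft:
        raise ValueError("signal shorter than one FFT window")
    freqs, pxx = sps.welch(
        wave.samples, fs=wave.sample_rate, window=window, nperseg=n_fft,
        noverlap=int(overlap * n_fft), detrend=False, scaling="density",
    )
    df = wave.sample_rate / n_fft
    return Spectrum(freqs, np.sqrt(pxx * df), resolution_hz=df)


def _analysis_segment(wave: Waveform, n_fft: int, segment_frac: float) -> Waveform:
    n = max(n_fft, int(np.ceil(segment_frac * len(wave))))
    return Waveform(wave.samples[: min(n, len(wave))], wave.sample_rate)


def _spectral_peaks(spec: Spectrum, max_peaks: int = 10) -> np.ndarray:
    """Frequencies of prominent local maxima (>=10 dB over the median and
    within 30 dB of the strongest peak)."""
    mag = spec.magnitude
    floor = np.median(mag) * 10.0 ** (PEAK_PROMINENCE_DB / 20.0)
    idx, _ = sps.find_peaks(mag, height=max(floor, mag.max() * 10.0 ** (-30 / 20.0)))
    if idx.size == 0:
        return np.empty(0)
    order = np.argsort(mag[idx])[::-1][:max_peaks]
    return np.sort(spec.frequencies[idx[order]])


def fundamental_and_dominant(
    wave: Waveform, n_fft: int = 1024, segment_frac: float = 0.25
) -> tuple[float, float]:
    """(fundamental_hz, dominant_hz) from the beginning-of-call spectrum.

    Dominant is the global spectral maximum.  The fundamental is the
    harmonic-comb root: the largest divisor ``dominant / m`` whose integer
    multiples explain every prominent peak within ±3% — robust when the
    fundamental is weaker than the second harmonic.
    """
    seg = _analysis_segment(wave, n_fft, segment_frac)
    spec = spectrum(seg, n_fft=n_fft)
    peaks = _spectral_peaks(spec)
    if peaks.size == 0:
        raise ValueError("no spectral peaks above the noise floor (noisy call?)")
    dominant = float(spec.frequencies[int(np.argmax(spec.magnitude))])
    fundamental = dominant
    for m in range(1, 7):
        cand = dominant / m
        if cand < 2 * spec.resolution_hz:
            break
        ratios = peaks / cand
        if np.all(np.abs(ratios - np.round(ratios)) <= COMB_TOLERANCE * np.round(ratios)):
            fundamental = cand
            break
    return fundamental, dominant


def count_harmonics(
    wave: Waveform, fundamental_hz: float, n_fft: int = 1024, segment_frac: float = 0.25
) -> int:
    """Number of comb lines with a peak >= 10 dB above the spectrum median."""
    if fundamental_hz <= 0:
        raise ValueError("fundamental must be positive")
    seg = _analysis_segment(wave, n_fft, segment_frac)
    spec = spectrum(seg, n_fft=n_fft)
    median = np.median(spec.magnitude)
    # "recognizable": above the broadband floor AND within 40 dB of the
    # strongest line (keeps numerical leakage of clean signals from counting)
    floor = max(median * 10.0 ** (PEAK_PROMINENCE_DB / 20.0),
                spec.magnitude.max() * 10.0 ** (-40.0 / 20.0))
    count = 0
    k_max = int(wave.nyquist * 0.999 // fundamental_hz)
    for k in range(1, k_max + 1):
        f_k = k * fundamental_hz
        mask = np.abs(spec.frequencies - f_k) <= COMB_TOLERANCE * f_k
        if mask.any() and spec.magnitude[mask].max() >= floor:
            count += 1
    return count


def ultrasound_flag(wave: Waveform, band: tuple[float, float] = (20000.0, 22000.0),
                    within_db: float = 30.0) -> bool:
    """True when the 20–22 kHz band reaches within 30 dB of the dominant peak.

    The recording chain rolled off at 22 kHz, so energy reaching this band
    is taken as evidence of ultrasonic content continuing above it.
    """
    if wave.nyquist < band[1]:
        raise ValueError("sample rate too low to assess the 20-22 kHz band")
    spec = spectrum(wave)
    dom_power = spec.magnitude.max() ** 2
    mask = (spec.frequencies >= band[0]) & (spec.frequencies <= band[1])
    band_power = float(spec.magnitude[mask].max() ** 2)
    if band_power <= 0:
        return False
    return 10.0 * np.log10(band_power / dom_power) >= -within_db


def harmonicity_score(wave: Waveform, n_fft: int = 1024, segment_frac: float = 0.25) -> float:
    """Fraction of spectral energy lying within ±3% of the harmonic comb."""
    seg = _analysis_segment(wave, n_fft, segment_frac)
    spec = spectrum(seg, n_fft=n_fft)
    dominant = float(spec.frequencies[int(np.argmax(spec.magnitude))])
    try:
        f0, _ = fundamental_and_dominant(wave, n_fft=n_fft, segment_frac=segment_frac)
    except ValueError:
        f0 = dominant
    if f0 <= 0:
        return 0.0
    energy = spec.magnitude**2
    ratios = spec.frequencies / f0
    near = np.abs(ratios - np.round(ratios)) <= COMB_TOLERANCE * np.maximum(np.round(ratios), 1)
    near &= spec.frequencies >= 0.5 * f0
    return float(energy[near].sum() / energy.sum())


def classify_call_type(wave: Waveform, threshold: float = 0.5) -> CallType:
    """Harmonic when most spectral energy sits on a harmonic comb."""
    try:
        score = harmonicity_score(wave)
    except ValueError:
        return CallType.NOISY
    return CallType.HARMONIC if score > threshold else CallType.NOISY


def track_f0(wave: Waveform, n_fft: int = 1024, hop: int = 128,
             voiced_rel_db: float = -20.0) -> F0Track:
    """Frame-wise dominant-peak contour (parabolically interpolated).

    For harmonic calls whose fundamental dominates every frame this is the
    f0 contour; frames quieter than ``voiced_rel_db`` re the loudest frame
    are marked unvoiced.
    """
    x = wave.samples
    if x.size < n_fft:
        raise ValueError("signal shorter than one analysis frame")
    win = sps.get_window("hamming", n_fft)
    starts = np.arange(0, x.size - n_fft + 1, hop)
    times, f0s, rms = [], [], []
    for s in starts:
        frame = x[s: s + n_fft] * win
        mag = np.abs(np.fft.rfft(frame))
        i = int(np.argmax(mag[1:-1])) + 1
        # parabolic refinement around the peak bin
        a, b, c = mag[i - 1], mag[i], mag[i + 1]
        denom = a - 2 * b + c
        delta = 0.5 * (a - c) / denom if denom != 0 else 0.0
        f0s.append((i + delta) * wave.sample_rate / n_fft)
        times.append((s + n_fft / 2) / wave.sample_rate * 1000.0)
        rms.append(np.sqrt(np.mean(frame**2)))
    rms = np.asarray(rms)
    voiced = rms >= rms.max() * 10.0 ** (voiced_rel_db / 20.0)
    return F0Track(np.asarray(times), np.asarray(f0s), voiced)


def classify_fm_pattern(track: F0Track, invariant_tol: float = 0.05) -> FMPattern:
    """Classify the fundamental contour.

    Invariant when the total relative excursion stays below 5%; otherwise
    bell/U when an interior extremum exceeds the endpoint-to-endpoint span,
    else downward/upward by the sign of the net change.
    """
    f0 = track.f0_hz[track.voiced]
    if f0.size < 5:
        raise ValueError("need at least 5 voiced frames")
    mean = f0.mean()
    if (f0.max() - f0.min()) / mean < invariant_tol:
        return FMPattern.INVARIANT
    start, end = f0[0], f0[-1]
    net = end - start
    span = abs(net)
    bell_dev = f0.max() - max(start, end)
    u_dev = min(start, end) - f0.min()
    if bell_dev > max(span, u_dev):
        return FMPattern.BELL
    if u_dev > max(span, bell_dev):
        return FMPattern.U_SHAPED
    return FMPattern.DOWNWARD if net < 0 else FMPattern.UPWARD


def extract_features(wave: Waveform) -> CallFeatures:
    """Full per-call feature vector (the measurement battery in one shot)."""
    duration_ms, time_to_max_ms = measure_envelope(wave)
    call_type = classify_call_type(wave)
    has_us = ultrasound_flag(wave) if wave.nyquist >= 22000.0 else False
    if call_type is CallType.HARMONIC:
        f0, dom = fundamental_and_dominant(wave)
        nh = count_harmonics(wave, f0)
        try:
            fm = classify_fm_pattern(track_f0(wave))
        except ValueError:
            fm = None
        return CallFeatures(duration_ms, time_to_max_ms, f0, dom, nh,
                            has_us, call_type, fm)
    return CallFeatures(duration_ms, time_to_max_ms, None, None, 0,
                        has_us, call_type, None)
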