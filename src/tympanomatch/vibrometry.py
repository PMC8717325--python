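"""Laser-vibrometry analysis of tympanic responses.

Implements the replicate-level processing chain for eardrum velocity
recordings sampled at 200 kHz:

1. per-replicate signal-to-noise ratio — RMS of an 80-ms window centered in
   the 100-ms tone divided by the RMS of an equal window centered in the
   silence period;
2. discard of the lowest-SNR quartile (floor(n/4) of n replicates; 5 of
   20), then sample-wise averaging of the survivors;
3. velocity readout — an 8192-point FFT (24.41 Hz grid) centered at the
   stimulus midpoint, amplitude at the bin nearest the tone frequency,
   converted to m/s through the vibrometer sensitivity (5 mm/s per unit)
   and amplifier gain (20 dB);
4. the velocity transfer function across the tone schedule per SPL, and its
   summary: best frequency, maximum velocity, and the half-maximum
   sensitivity range with interpolated lower/upper limits;
5. for call stimuli: quartile filtering on whole-stimulus RMS and a
   2048-point (97.66 Hz) averaged response spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .matching import Spectrum
from .signal_io import Waveform
from .synthesis import ToneStimulus

#: vibrometer sensitivity: one trace unit corresponds to 5 mm/s ...
VIBROMETER_SENSITIVITY_M_S = 5e-3
#: ... after a 20 dB amplifier, so velocity = units * 5e-3 / 10**(20/20).
AMPLIFIER_GAIN_DB = 20.0
#: m/s of eardrum velocity per trace unit with the defaults above.
TRACE_UNIT_M_S = VIBROMETER_SENSITIVITY_M_S / 10 ** (AMPLIFIER_GAIN_DB / 20.0)

TONE_FFT_POINTS = 8192
CALL_FFT_POINTS = 2048
SNR_WINDOW_MS = 80.0
DB_VELOCITY_REF_M_S = 1e-6  # velocity level reference: 1 um/s


@dataclass(frozen=True)
class ReplicateSet:
    """The replicate traces recorded for one stimulus (nominally 20)."""

    stimulus: ToneStimulus | str
    traces: tuple[Waveform, ...]

    def __post_init__(self) -> None:
        traces = tuple(self.traces)
        if not traces:
            raise ValueError("need at least one trace")
        n = len(traces[0])
        fs = traces[0].sample_rate
        for tr in traces:
            if len(tr) != n or tr.sample_rate != fs:
                raise ValueError("replicate traces must share length and rate")
        object.__setattr__(self, "traces", traces)

    @property
    def n_replicates(self) -> int:
        return len(self.traces)

    @property
    def sample_rate(self) -> float:
        return self.traces[0].sample_rate


@dataclass(frozen=True)
class SNRRecord:
    replicate_id: int
    rms_stimulus: float
    rms_silence: float

    @property
    def ratio(self) -> float:
        if self.rms_silence == 0:
            return np.inf if self.rms_stimulus > 0 else 0.0
        return self.rms_stimulus / self.rms_silence


@dataclass(frozen=True)
class TransferFunction:
    """Eardrum velocity (m/s) versus tone frequency at one SPL."""

    spl: float
    frequencies: np.ndarray
    velocity: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=np.float64)
        v = np.asarray(self.velocity, dtype=np.float64)
        if f.shape != v.shape or f.ndim != 1:
            raise ValueError("frequencies and velocity must be equal-length 1-D")
        if not np.all(np.diff(f) > 0):
            raise ValueError("frequencies must be strictly increasing")
        if np.any(v < 0):
            raise ValueError("velocities must be non-negative")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "velocity", v)


@dataclass(frozen=True)
class TympanicSummary:
    """Best frequency and half-maximum sensitivity range of one transfer
    function.  ``edge_clamped`` flags a limit that never fell below
    half-max inside the measured band."""

    best_frequency_hz: float
    max_velocity: float
    lower_limit_hz: float
    upper_limit_hz: float
    velocity_db: float
    edge_clamped: bool

    @property
    def range_hz(self) -> float:
        return self.upper_limit_hz - self.lower_limit_hz


def _window_rms(x: np.ndarray, center_s: float, width_s: float, fs: float) -> float:
    i0 = int(round((center_s - width_s / 2) * fs))
    i1 = int(round((center_s + width_s / 2) * fs))
    if i0 < 0 or i1 > x.size or i1 <= i0:
        raise IndexError("RMS window outside trace")
    return float(np.sqrt(np.mean(x[i0:i1] ** 2)))


def replicate_snr(trace: Waveform, stim: ToneStimulus, replicate_id: int = 0,
                  window_ms: float = SNR_WINDOW_MS) -> SNRRecord:
    """RMS ratio between windows centered in the stimulus and the silence."""
    fs = trace.sample_rate
    dur_s = stim.duration_ms / 1000.0
    sil_s = stim.silence_ms / 1000.0
    width = min(window_ms / 1000.0, dur_s, sil_s)
    rms_stim = _window_rms(trace.samples, dur_s / 2, width, fs)
    rms_sil = _window_rms(trace.samples, dur_s + sil_s / 2, width, fs)
    return SNRRecord(replicate_id, rms_stim, rms_sil)


def _whole_stimulus_snr(trace: Waveform, replicate_id: int) -> SNRRecord:
    """SNR for call stimuli: whole first half (stimulus) vs second half
    (silence) of the acquisition window."""
    half = len(trace) // 2
    rms_stim = float(np.sqrt(np.mean(trace.samples[:half] ** 2)))
    rms_sil = float(np.sqrt(np.mean(trace.samples[half:] ** 2)))
    return SNRRecord(replicate_id, rms_stim, rms_sil)


def _quartile_filter_average(
    traces: Sequence[Waveform], records: Sequence[SNRRecord]
) -> Waveform:
    n = len(traces)
    if n < 4:
        raise ValueError("need at least 4 replicates to discard a quartile")
    ratios = np.array([r.ratio for r in records])
    order = np.argsort(ratios, kind="stable")  # ties keep replicate order
    keep = sorted(order[n // 4:])
    stack = np.stack([traces[i].samples for i in keep])
    return Waveform(stack.mean(axis=0), traces[0].sample_rate)


def filter_and_average(reps: ReplicateSet) -> Waveform:
    """Drop the lowest-SNR quartile and average the remaining replicates."""
    if isinstance(reps.stimulus, ToneStimulus):
        records = [replicate_snr(tr, reps.stimulus, i) for i, tr in enumerate(reps.traces)]
    else:
        records = [_whole_stimulus_snr(tr, i) for i, tr in enumerate(reps.traces)]
    return _quartile_filter_average(reps.traces, records)


def velocity_at_frequency(
    avg: Waveform,
    stim_freq: float,
    stim_duration_ms: float = 100.0,
    n_fft: int = TONE_FFT_POINTS,
    trace_unit_m_s: float = TRACE_UNIT_M_S,
) -> float:
    """Eardrum velocity (m/s) at the stimulated frequency.

    One ``n_fft``-point window centered at the stimulus midpoint; a flat-top
    window keeps the amplitude readout honest when the tone frequency falls
    between bins of the 24.41 Hz grid (scalloping < 0.1%); the amplitude at
    the bin nearest ``stim_freq`` is scaled to m/s.
    """
    fs = avg.sample_rate
    if stim_freq >= fs / 2:
        raise ValueError("stimulus frequency at or above Nyquist")
    center = int(round(stim_duration_ms / 1000.0 * fs / 2))
    i0 = center - n_fft // 2
    i1 = i0 + n_fft
    if i0 < 0 or i1 > len(avg):
        raise IndexError("averaged trace too short for the FFT window")
    win = sps.get_window("flattop", n_fft)
    seg = avg.samples[i0:i1] * win
    mag = np.abs(np.fft.rfft(seg)) * 2.0 / win.sum()
    k = int(round(stim_freq / (fs / n_fft)))
    return float(mag[k] * trace_unit_m_s)


def tone_grid_resolution_hz(sample_rate: float = 200000.0, n_fft: int = TONE_FFT_POINTS) -> float:
    """Frequency grid spacing of the tone velocity readout (24.41 Hz)."""
    return sample_rate / n_fft


def build_transfer_function(
    responses: Sequence[tuple[ToneStimulus, Waveform]],
    trace_unit_m_s: float = TRACE_UNIT_M_S,
) -> TransferFunction:
    """Velocity-vs-frequency curve from one averaged response per tone.

    All stimuli must share the SPL; duplicate frequencies are an input
    error and gaps are left as gaps (no interpolation).
    """
    if not responses:
        raise ValueError("no responses")
    spls = {stim.level_db_spl for stim, _ in responses}
    if len(spls) != 1:
        raise ValueError("responses mix SPL levels; build one TF per SPL")
    freqs = np.array([stim.frequency_hz for stim, _ in responses])
    if np.unique(freqs).size != freqs.size:
        raise ValueError("duplicate stimulus frequencies")
    order = np.argsort(freqs)
    vel = np.array(
        [
            velocity_at_frequency(avg, stim.frequency_hz, stim.duration_ms,
                                  trace_unit_m_s=trace_unit_m_s)
            for stim, avg in responses
        ]
    )
    return TransferFunction(spls.pop(), freqs[order], vel[order])


def summarize_tf(tf: TransferFunction) -> TympanicSummary:
    """Best frequency and interpolated half-maximum limits.

    Ties at the maximum resolve to the lowest frequency.  Walking outward
    from the peak, each limit is the linear interpolation of the first
    crossing below half-max; a curve still above half-max at the band edge
    clamps to the edge frequency and sets ``edge_clamped``.
    """
    if tf.frequencies.size < 3:
        raise ValueError("need at least 3 points")
    v = tf.velocity
    f = tf.frequencies
    if np.all(v == 0):
        raise ValueError("all-zero transfer function")
    best = int(np.argmax(v))
    vmax = float(v[best])
    half = vmax / 2.0
    clamped = False

    lower = f[0]
    for i in range(best, 0, -1):
        if v[i - 1] < half:
            lower = f[i] + (f[i - 1] - f[i]) * (v[i] - half) / (v[i] - v[i - 1])
            break
    else:
        clamped = True

    upper = f[-1]
    for i in range(best, f.size - 1):
        if v[i + 1] < half:
            upper = f[i] + (f[i + 1] - f[i]) * (v[i] - half) / (v[i] - v[i + 1])
            break
    else:
        clamped = True

    return TympanicSummary(
        best_frequency_hz=float(f[best]),
        max_velocity=vmax,
        lower_limit_hz=float(lower),
        upper_limit_hz=float(upper),
        velocity_db=20.0 * np.log10(vmax / DB_VELOCITY_REF_M_S),
        edge_clamped=clamped,
    )


def call_response_spectrum(
    reps: ReplicateSet,
    n_fft: int = CALL_FFT_POINTS,
    trace_unit_m_s: float = TRACE_UNIT_M_S,
) -> Spectrum:
    """Averaged tympanic response spectrum to a call stimulus.

    Quartile filtering uses the RMS of the whole stimulus half of the
    acquisition window (calls are too nonstationary for a centered 80-ms
    window); the averaged response is transformed with 2048-point Hamming
    windows, giving the coarser 97.66 Hz grid that smooths the spectra.
    """
    records = [_whole_stimulus_snr(tr, i) for i, tr in enumerate(reps.traces)]
    avg = _quartile_filter_average(reps.traces, records)
    half = len(avg) // 2
    response = Waveform(avg.samples[:half] * trace_unit_m_s, avg.sample_rate)
    freqs, pxx = sps.welch(
        response.samples, fs=response.sample_rate, window="hamming",
        nperseg=n_fft, noverlap=int(0.875 * n_fft), detrend=False,
        scaling="density",
    )
    df = response.sample_rate / n_fft
    return Spectrum(freqs, np.sqrt(pxx * df), resolution_hz=df)


def call_grid_resolution_hz(sample_rate: float = 200000.0, n_fft: int = CALL_FFT_POINTS) -> float:
    """Frequency grid spacing of the call-response spectrum (97.66 Hz)."""
    return sample_rate / n_fft
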