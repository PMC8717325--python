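"""Simulated eardrum: resonant-filter ground truth for the whole pipeline.

Real tympanic velocity curves are single-peaked with broad tuning and no
response above ~13 kHz.  The minimal phenomenological model with those
properties is a second-order resonator (peak at the center frequency,
bandwidth set by Q) cascaded with a 4th-order low-pass that imposes the
high-frequency null.  The model is linear: velocity scales with stimulus
amplitude, i.e. +1 dB SPL gives +1 dB velocity.

Traces come out in vibrometer units (1 unit = 0.5 mm/s of velocity after
the documented 5 mm/s sensitivity and 20 dB gain) with additive white
Gaussian measurement noise, so every downstream stage — SNR filtering,
averaging, FFT velocity readout, transfer functions, matching — can be
exercised and checked against known ground truth without animals.

Randomness: one integer seed per experiment, split per individual, per
stimulus, and per replicate through ``numpy.random.SeedSequence`` so any
subset of the design is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .signal_io import Waveform, write_wav
from .synthesis import (
    ToneStimulus,
    amplitude_for_spl,
    make_tone_schedule,
    synthesize_harmonic_call,
    POPULATION_CALLS,
)
from .vibrometry import TRACE_UNIT_M_S, ReplicateSet

VIBRO_RATE = 200000.0


@dataclass(frozen=True)
class EardrumModel:
    """Second-order resonator eardrum.

    Parameters
    ----------
    center_frequency_hz
        Resonance (the true best frequency), must lie below ``hf_cutoff_hz``.
    quality_factor
        Tuning sharpness.  The half-velocity bandwidth of a second-order
        resonator is sqrt(3) * fc / Q, so the default 4 gives the broad,
        ~2.5 kHz-wide half-max sensitivity ranges seen in real curves at
        fc near 6 kHz.
    peak_velocity_at_80db
        Steady-state velocity (m/s) at the center frequency for an 80 dB SPL
        tone; measured values run ~0.07 mm/s at 55 dB up to ~1.4 mm/s at
        80 dB.
    noise_sd
        Additive Gaussian noise, in trace units, per sample.
    hf_cutoff_hz
        4th-order low-pass corner above which the membrane stops responding
        (default 13 kHz).
    """

    center_frequency_hz: float
    quality_factor: float = 4.0
    peak_velocity_at_80db: float = 1.4e-3
    noise_sd: float = 0.05
    hf_cutoff_hz: float = 13000.0

    def __post_init__(self) -> None:
        if not 0 < self.center_frequency_hz < self.hf_cutoff_hz:
            raise ValueError("center frequency must lie below the HF cutoff")
        if self.quality_factor <= 0:
            raise ValueError("Q must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class PopulationSpec:
    """Cohort-level distribution of eardrum parameters."""

    name: str
    n_individuals: int
    mean_center_hz: float
    sd_center_hz: float
    mean_peak_velocity: float = 1.4e-3
    sd_peak_velocity: float = 2.0e-4
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("need at least one individual")
        if self.sd_center_hz < 0 or self.sd_peak_velocity < 0:
            raise ValueError("spreads must be non-negative")


def _filters(model: EardrumModel, fs: float):
    b, a = sps.iirpeak(model.center_frequency_hz, model.quality_factor, fs=fs)
    sos_lp = sps.butter(4, model.hf_cutoff_hz, btype="low", fs=fs, output="sos")
    return (b, a), sos_lp


def _gain_at(model: EardrumModel, freq: float, fs: float) -> float:
    (b, a), sos_lp = _filters(model, fs)
    w = 2 * np.pi * freq / fs
    _, h_peak = sps.freqz(b, a, worN=[w])
    _, h_lp = sps.sosfreqz(sos_lp, worN=[w])
    return float(np.abs(h_peak[0] * h_lp[0]))


def clean_response(model: EardrumModel, drive: Waveform) -> Waveform:
    """Noise-free velocity response, in trace units.

    The cascade gain is calibrated so that a tone at the center frequency
    at 80 dB SPL produces ``peak_velocity_at_80db`` in steady state;
    velocity is linear in drive amplitude above and below that.
    """
    fs = drive.sample_rate
    (b, a), sos_lp = _filters(model, fs)
    y = sps.lfilter(b, a, drive.samples)
    y = sps.sosfilt(sos_lp, y)
    gain_fc = _gain_at(model, model.center_frequency_hz, fs)
    velocity_scale = model.peak_velocity_at_80db / (amplitude_for_spl(80.0) * gain_fc)
    return Waveform(y * velocity_scale / TRACE_UNIT_M_S, fs)


def _noisy_replicates(
    clean: Waveform, noise_sd: float, n_reps: int, seed_seq: np.random.SeedSequence
) -> tuple[Waveform, ...]:
    traces = []
    for child in seed_seq.spawn(n_reps):
        rng = np.random.default_rng(child)
        traces.append(
            Waveform(clean.samples + rng.normal(0.0, noise_sd, len(clean)), clean.sample_rate)
            if noise_sd > 0
            else clean
        )
    return tuple(traces)


def simulate_tone_replicates(
    model: EardrumModel,
    stim: ToneStimulus,
    n_reps: int = 20,
    seed: int | np.random.SeedSequence = 0,
    sample_rate: float = VIBRO_RATE,
) -> ReplicateSet:
    """Replicate vibrometer traces for one tone stimulus."""
    if n_reps < 1:
        raise ValueError("need at least one replicate")
    if stim.frequency_hz >= sample_rate / 2:
        raise ValueError("stimulus frequency at or above Nyquist")
    from .synthesis import synthesize_tone

    clean = clean_response(model, synthesize_tone(stim, sample_rate))
    seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return ReplicateSet(stim, _noisy_replicates(clean, model.noise_sd, n_reps, seq))


def resample_to_vibro(call: Waveform, sample_rate: float = VIBRO_RATE) -> Waveform:
    """Resample a call waveform to the acquisition rate."""
    if call.sample_rate == sample_rate:
        return call
    up = int(round(sample_rate))
    down = int(round(call.sample_rate))
    return Waveform(sps.resample_poly(call.samples, up, down), sample_rate)


def call_drive(call: Waveform, spl: float, sample_rate: float = VIBRO_RATE) -> Waveform:
    """The call as broadcast: resampled to 200 kHz, peak-normalized, scaled
    to the requested SPL, followed by an equal silence window."""
    x = resample_to_vibro(call, sample_rate).samples
    x = x / np.max(np.abs(x)) * amplitude_for_spl(spl)
    return Waveform(np.concatenate([x, np.zeros_like(x)]), sample_rate)


def simulate_call_response(
    model: EardrumModel,
    call: Waveform,
    spl: float,
    n_reps: int = 20,
    seed: int | np.random.SeedSequence = 0,
    call_id: str = "call",
    sample_rate: float = VIBRO_RATE,
) -> ReplicateSet:
    """Replicate traces of the eardrum driven by a synthetic call."""
    if n_reps < 1:
        raise ValueError("need at least one replicate")
    clean = clean_response(model, call_drive(call, spl, sample_rate))
    seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return ReplicateSet(call_id, _noisy_replicates(clean, model.noise_sd, n_reps, seq))


def draw_cohort(spec: PopulationSpec) -> list[EardrumModel]:
    """Per-individual eardrum models drawn from the population spec."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xC0F0]))
    models = []
    for _ in range(spec.n_individuals):
        fc = float(np.clip(rng.normal(spec.mean_center_hz, spec.sd_center_hz),
                           500.0, 12000.0))
        pv = float(max(rng.normal(spec.mean_peak_velocity, spec.sd_peak_velocity),
                       0.1 * spec.mean_peak_velocity))
        models.append(EardrumModel(center_frequency_hz=fc, peak_velocity_at_80db=pv,
                                   noise_sd=spec.noise_sd))
    return models


def simulate_population_experiment(
    spec: PopulationSpec,
    spls: tuple[float, ...] = (55.0, 60.0, 70.0, 80.0),
    n_reps: int = 20,
    max_frequency_hz: float | None = None,
    calls: dict[str, Waveform] | None = None,
    out_dir=None,
) -> tuple[dict, pd.DataFrame, list[EardrumModel]]:
    """Run the full acquisition design over a simulated cohort.

    Returns ``(dataset, manifest, models)`` where ``dataset`` maps
    ``(individual, stimulus_label, spl)`` to a :class:`ReplicateSet`
    (``stimulus_label`` is a frequency in Hz for tones or a call name), and
    ``manifest`` is one row per recorded replicate.  With ``out_dir`` the
    traces are additionally written as float32 WAV plus ``manifest.csv`` in
    the layout the vibrometry stage reads.
    """
    models = draw_cohort(spec)
    if calls is None:
        calls = {name: synthesize_harmonic_call(p) for name, p in POPULATION_CALLS.items()}
    schedule = make_tone_schedule(list(spls), max_frequency_hz=max_frequency_hz)
    root = np.random.SeedSequence([spec.seed, 0xDA7A])
    ind_seqs = root.spawn(len(models))
    dataset: dict[tuple, ReplicateSet] = {}
    rows = []
    for i, (model, ind_seq) in enumerate(zip(models, ind_seqs)):
        ind = f"{spec.name}_{i:02d}"
        stim_seqs = iter(ind_seq.spawn(len(schedule) + len(calls) * len(spls)))
        for stim in schedule:
            reps = simulate_tone_replicates(model, stim, n_reps, next(stim_seqs))
            dataset[(ind, stim.frequency_hz, stim.level_db_spl)] = reps
            for r in range(n_reps):
                rows.append((ind, spec.name, "tone", stim.frequency_hz,
                             stim.level_db_spl, r))
        for call_name, call in calls.items():
            for spl in spls:
                reps = simulate_call_response(model, call, spl, n_reps,
                                              next(stim_seqs), call_id=call_name)
                dataset[(ind, call_name, spl)] = reps
                for r in range(n_reps):
                    rows.append((ind, spec.name, "call", call_name, spl, r))
    manifest = pd.DataFrame(
        rows, columns=["individual", "population", "kind", "stimulus", "spl_db", "replicate"]
    )
    if out_dir is not None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        files = []
        for (ind, label, spl), reps in dataset.items():
            for r, tr in enumerate(reps.traces):
                name = f"{ind}_{label}_{spl:g}dB_rep{r:02d}.wav"
                write_wav(tr, out / name, bit_depth="float32")
                files.append(name)
        manifest = manifest.assign(file=files)
        manifest.to_csv(out / "manifest.csv", index=False)
    return dataset, manifest, models
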