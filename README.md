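# tympanomatch

Sender–receiver matching analysis for acoustic communication in the
Weeping lizard (*Liolaemus chiliensis*), the only vocalizing species in
its genus.  Two widely separated populations differ in their distress
calls; this package quantifies how well each population's eardrum tuning
matches its own call — the question at the heart of whether signal and
receiver coevolve.

The package implements the complete measurement chain as a reusable
pipeline, with a simulated eardrum replacing the animals:

* **synthesis** — parametric harmonic distress calls (the central call:
  6 harmonics, 71 ms, 2.7 → 2.1 kHz sweep; the southern call: 3
  harmonics, 42 ms, 6.3 → 5.6 kHz), noisy calls, nonlinear-phenomena
  fixtures, and the pure-tone stimulus schedule (0.1–40 kHz, 78
  frequencies, at 55/60/70/80 dB SPL);
* **call_features** — duration and time-to-maximum from the amplitude
  envelope (−20 dB threshold), fundamental/dominant frequency and
  harmonic count from 1024-point Hamming spectra, ultrasound flagging,
  harmonic/noisy classification, FM-pattern classification;
* **vibrometry** — the tympanic analysis chain: per-replicate RMS
  signal-to-noise ratios, first-quartile discard, replicate averaging,
  8192-point FFT velocity readout (24.41 Hz grid), velocity transfer
  functions, and their summaries (best frequency `BF`, maximum velocity,
  and the half-maximum sensitivity range `[f_lo, f_hi]` where
  `v(f) ≥ v(BF)/2`);
* **matching** — the zero-lag spectral cross-correlation
  `r = corr(|S_call(f)|, |S_tympanum(f)|)` across frequency bins, plus
  the mismatch distance `|BF − dominant|` in kHz;
* **eardrum** — a second-order resonator eardrum simulator (calibrated
  peak velocity, 13 kHz high-frequency null, seeded Gaussian measurement
  noise) that generates replicate vibrometer traces with known ground
  truth;
* **stats** — Pearson χ² (no continuity correction) for ultrasound
  proportions, pooled/Welch t-tests, and stepwise two-group linear
  discriminant analysis with Wilks' λ and canonical eigenvalue;
* **pipeline** — `run_pipeline(PipelineConfig(...))` orchestrates
  simulate → vibrometry → matching → stats with persisted CSV/JSON
  intermediates, byte-reproducible per seed.

See `docs/methods.md` for the models, conventions and their rationale.

## Worked example

```python
import tympanomatch as tm

# synthesize the central-population call and re-measure it
call = tm.synthesize_harmonic_call(tm.CENTRAL_CALL)
f0, dominant = tm.fundamental_and_dominant(call)
duration, time_to_max = tm.measure_envelope(call)
print(f"dominant {dominant:.0f} Hz, duration {duration:.1f} ms, "
      f"time-to-max {time_to_max:.1f} ms, "
      f"harmonics {tm.count_harmonics(call, f0)}")

# simulate an eardrum tuned to 6 kHz and measure its transfer function
import numpy as np
model = tm.EardrumModel(center_frequency_hz=6000.0)
schedule = tm.make_tone_schedule([80.0], max_frequency_hz=12000.0)
responses = [
    (s, tm.filter_and_average(tm.simulate_tone_replicates(model, s, n_reps=8, seed=q)))
    for s, q in zip(schedule, np.random.SeedSequence(0).spawn(len(schedule)))
]
summary = tm.summarize_tf(tm.build_transfer_function(responses))
print(f"best frequency {summary.best_frequency_hz:.0f} Hz, "
      f"peak velocity {summary.max_velocity*1e3:.2f} mm/s, "
      f"half-max range {summary.lower_limit_hz:.0f}-{summary.upper_limit_hz:.0f} Hz")
```

prints

```
dominant 2713 Hz, duration 70.4 ms, time-to-max 25.2 ms, harmonics 6
best frequency 6000 Hz, peak velocity 1.40 mm/s, half-max range 4835-7428 Hz
```

— the call measurements land on the generating parameters (2.7 kHz, 71 ms,
26 ms, 6 harmonics) within one FFT bin / 2 ms, and the measured best
frequency recovers the simulated resonance exactly with the calibrated
1.4 mm/s peak velocity.

## The analysis

Numbered drivers under `analysis/` rebuild the result tables in
`results/`:

```sh
python analysis/01_synthesize_calls.py          # calls + feature round-trip
python analysis/02_measure_tympanic_sensitivity.py  # cohorts, TFs, summaries
python analysis/03_match_calls_to_eardrums.py   # cross-correlations
python analysis/04_population_statistics.py     # chi-square, t-tests, LDA
```

On the simulated cohorts (resonance means at the two populations'
measured best frequencies, 5.78 and 7.17 kHz) the matching stage shows
the same asymmetry the real experiment found: the southern cohort
correlates higher with its local call (mean r = 0.90 vs 0.72 nonlocal)
while the central cohort matches the nonlocal call better (0.82 local vs
0.89 nonlocal), and correlations increase with stimulus level.

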