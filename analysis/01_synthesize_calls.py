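#!/usr/bin/env python
"""Synthesize the two population distress calls and re-measure them.

Builds the central (6 harmonics, 71 ms, 2.7->2.1 kHz) and southern
(3 harmonics, 42 ms, 6.3->5.6 kHz) synthetic calls plus a noisy-call
example, runs the spectro-temporal feature battery on each, and writes
the measured-vs-generating table to results/call_features.csv.
"""

from pathlib import Path

import pandas as pd

from tympanomatch import (
    POPULATION_CALLS,
    extract_features,
    highpass,
    measure_envelope,
    classify_call_type,
    synthesize_harmonic_call,
    synthesize_noisy_call,
    write_wav,
)

OUT = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rows = []
    for name, params in POPULATION_CALLS.items():
        wave = highpass(synthesize_harmonic_call(params), 200.0)
        write_wav(wave, SCRATCH / f"call_{name}.wav")
        f = extract_features(wave)
        rows.append(
            dict(population=name,
                 true_duration_ms=params.duration_ms, duration_ms=round(f.duration_ms, 2),
                 true_time_to_max_ms=params.time_to_max_ms,
                 time_to_max_ms=round(f.time_to_max_ms, 2),
                 true_dominant_hz=params.f0_start_hz, dominant_hz=round(f.dominant_hz, 1),
                 true_n_harmonics=params.n_harmonics, n_harmonics=f.n_harmonics,
                 call_type=f.call_type.value, fm_pattern=f.fm_pattern.value)
        )
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "call_features.csv", index=False)
    print("Synthetic calls re-measured by the feature extractor:")
    print(df.to_string(index=False))

    noisy = synthesize_noisy_call(47.0, 1000.0, 8000.0, 18.0, seed=1)
    dur, _ = measure_envelope(noisy)
    print(f"\nNoisy-call example (southern mean 47 ms): measured duration "
          f"{dur:.1f} ms, classified {classify_call_type(noisy).value}")


if __name__ == "__main__":
    main()
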