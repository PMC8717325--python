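"""Call-eardrum matching statistics.

The matching question: does the eardrum vibrate most where the local call
carries its energy?  Two complementary statistics answer it:

* the zero-lag spectral cross-correlation — Pearson correlation across
  frequency bins between a call's magnitude spectrum and the tympanic
  response spectrum; and
* the mismatch distance — |best frequency − dominant frequency| in kHz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class Spectrum:
    """Magnitude versus frequency on a uniform grid."""

    frequencies: np.ndarray
    magnitude: np.ndarray
    resolution_hz: float

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=np.float64)
        m = np.asarray(self.magnitude, dtype=np.float64)
        if f.ndim != 1 or f.size < 2 or f.shape != m.shape:
            raise ValueError("frequencies and magnitude must be equal-length 1-D arrays")
        if not np.all(np.diff(f) > 0):
            raise ValueError("frequency grid must be strictly increasing")
        if not np.all(np.isfinite(m)):
            raise ValueError("magnitudes must be finite")
        step = np.diff(f)
        if not np.allclose(step, self.resolution_hz, rtol=1e-6, atol=1e-9):
            raise ValueError("frequency grid spacing does not match resolution_hz")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "magnitude", m)
        object.__setattr__(self, "resolution_hz", float(self.resolution_hz))

    def band(self, low_hz: float, high_hz: float) -> "Spectrum":
        """Restrict to frequencies in ``[low_hz, high_hz]``."""
        mask = (self.frequencies >= low_hz) & (self.frequencies <= high_hz)
        if mask.sum() < 2:
            raise ValueError("band restriction leaves fewer than two bins")
        return Spectrum(self.frequencies[mask], self.magnitude[mask], self.resolution_hz)


@dataclass(frozen=True)
class MatchResult:
    individual: str
    population: str
    spl: float
    call: str
    call_origin: str  # "local" | "nonlocal"
    correlation: float


def zero_lag_cross_correlation(a: Spectrum, b: Spectrum, db: bool = False) -> float:
    """Zero-lag normalized cross-correlation of two magnitude spectra.

    Both spectra are restricted to their common band, the finer one is
    resampled onto the coarser grid by linear interpolation, and the result
    is the Pearson correlation of the two magnitude vectors across bins.
    ``db=True`` correlates 20*log10 magnitudes instead of linear ones.
    """
    low = max(a.frequencies[0], b.frequencies[0])
    high = min(a.frequencies[-1], b.frequencies[-1])
    if high <= low:
        raise ValueError("spectra have no overlapping frequency band")
    coarse, fine = (a, b) if a.resolution_hz >= b.resolution_hz else (b, a)
    grid_mask = (coarse.frequencies >= low) & (coarse.frequencies <= high)
    grid = coarse.frequencies[grid_mask]
    if grid.size < 3:
        raise ValueError("common band holds fewer than three bins")
    x = coarse.magnitude[grid_mask]
    y = np.interp(grid, fine.frequencies, fine.magnitude)
    if db:
        floor = 1e-12 * max(x.max(), y.max(), 1e-300)
        x = 20.0 * np.log10(np.maximum(x, floor))
        y = 20.0 * np.log10(np.maximum(y, floor))
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance spectrum; correlation undefined")
    x = x - x.mean()
    y = y - y.mean()
    return float(np.dot(x, y) / np.sqrt(np.dot(x, x) * np.dot(y, y)))


def mismatch_distance(best_frequency_hz: float, dominant_hz: float) -> float:
    """|best frequency − dominant frequency| in kHz."""
    if best_frequency_hz <= 0 or dominant_hz <= 0:
        raise ValueError("frequencies must be positive")
    return abs(best_frequency_hz - dominant_hz) / 1000.0


def match_table(
    tympanic: Mapping[tuple, Spectrum],
    calls: Mapping[str, Spectrum],
    populations: Mapping[str, str],
    db: bool = False,
) -> pd.DataFrame:
    """Correlate every individual's tympanic spectra with every call.

    Parameters
    ----------
    tympanic
        Response spectra keyed ``(individual, spl)`` — one spectrum used
        against both calls — or ``(individual, spl, call)`` when the
        response to each call stimulus was recorded separately (the primary
        route here).
    calls
        Call magnitude spectra keyed by population name.
    populations
        Individual -> population label; a call is "local" to individuals of
        its own population.

    Returns a long-format table with one row per (individual, SPL, call);
    missing cells raise a warning and are omitted.
    """
    keyed_by_call = any(len(k) == 3 for k in tympanic)
    rows: list[MatchResult] = []
    cells = sorted({(k[0], k[1]) for k in tympanic})
    for individual, spl in cells:
        pop = populations.get(individual)
        if pop is None:
            warnings.warn(f"no population label for {individual!r}; row omitted")
            continue
        for call_name, call_spec in calls.items():
            key = (individual, spl, call_name) if keyed_by_call else (individual, spl)
            spec = tympanic.get(key)
            if spec is None:
                warnings.warn(f"missing tympanic spectrum for {key!r}; row omitted")
                continue
            rows.append(
                MatchResult(
                    individual=individual,
                    population=pop,
                    spl=float(spl),
                    call=call_name,
                    call_origin="local" if call_name == pop else "nonlocal",
                    correlation=zero_lag_cross_correlation(call_spec, spec, db=db),
                )
            )
    return pd.DataFrame([r.__dict__ for r in rows])
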