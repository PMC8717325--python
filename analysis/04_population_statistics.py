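#!/usr/bin/env python
"""Population-comparison statistics on call features and tympanic summaries.

Four analyses, writing results/stats.json:

1. chi-square on the ultrasound contingency table reconstructed from the
   published call totals (171 central / 190 southern) and ultrasound
   percentages (26.9% / 1.05%);
2. pooled t-test auditing the published total-call-count row from its
   summary statistics;
3. pooled t-test comparing best frequencies of the simulated cohorts from
   script 02;
4. stepwise two-group LDA separating simulated call cohorts (12 central /
   21 southern individuals, parameters jittered around the population
   means) on duration, dominant frequency and harmonic count.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from tympanomatch import (
    CENTRAL_CALL,
    SOUTHERN_CALL,
    ContingencyTable2x2,
    chisq_2x2,
    count_harmonics,
    fundamental_and_dominant,
    lda_two_group,
    measure_envelope,
    synthesize_harmonic_call,
    two_sample_t,
    two_sample_t_from_summary,
)
from tympanomatch.synthesis import vary_call_params

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 77


def simulated_call_cohort():
    rng = np.random.default_rng(SEED)
    rows = []
    for pop, base, n in (("central", CENTRAL_CALL, 12), ("southern", SOUTHERN_CALL, 21)):
        for _ in range(n):
            w = synthesize_harmonic_call(vary_call_params(base, rng))
            dur, _ = measure_envelope(w)
            f0, dom = fundamental_and_dominant(w)
            rows.append(dict(population=pop, duration_ms=dur, dominant_hz=dom,
                             n_harmonics=count_harmonics(w, f0)))
    return pd.DataFrame(rows)


def main() -> None:
    OUT.mkdir(exist_ok=True)
    out = {}

    table = ContingencyTable2x2(np.array([[46, 125], [2, 188]]))
    stat, df, p = chisq_2x2(table)
    out["ultrasound_chi_square"] = dict(chi2=round(stat, 2), df=df, p=p,
                                        row_pct=[round(x, 2) for x in table.row_percentages()])
    print(f"Ultrasound occurrence ({table.row_percentages()[0]:.1f}% vs "
          f"{table.row_percentages()[1]:.2f}%): chi2 = {stat:.2f}, p = {p:.2g}")

    audit = two_sample_t_from_summary(14.25, 2.61, 12, 7.31, 1.37, 26)
    out["total_calls_t_audit"] = dict(t=round(audit.t, 3), df=audit.df, p=round(audit.p, 4))
    print(f"Total-call-count audit from summaries: t({audit.df:.0f}) = {audit.t:.2f}, "
          f"p = {audit.p:.3f}")

    summary = pd.read_csv(OUT / "tympanic_summary.csv")
    best = summary.groupby(["population", "individual"])["best_frequency_hz"].mean()
    r = two_sample_t(best["central"], best["southern"])
    out["best_frequency_t"] = dict(t=round(r.t, 3), df=r.df, p=round(r.p, 4),
                                   means_khz={p_: round(best[p_].mean() / 1000, 2)
                                              for p_ in ("central", "southern")})
    print(f"Simulated best frequencies "
          f"({best['central'].mean()/1000:.2f} vs {best['southern'].mean()/1000:.2f} kHz): "
          f"t({r.df:.0f}) = {r.t:.2f}, p = {r.p:.3f}")

    cohort = simulated_call_cohort()
    X = cohort[["duration_ms", "dominant_hz", "n_harmonics"]].to_numpy()
    res = lda_two_group(X, cohort.population,
                        variable_names=["duration_ms", "dominant_hz", "n_harmonics"])
    out["call_lda"] = dict(
        selected=list(res.selected_variables),
        wilks_lambda=round(res.wilks_lambda, 3),
        eigenvalue=round(res.eigenvalue, 3),
        pct_correct=round(res.pct_correct, 1),
        confusion=res.confusion.tolist(),
    )
    print(f"Call LDA: selected {res.selected_variables}, Wilks lambda = "
          f"{res.wilks_lambda:.2f}, eigenvalue = {res.eigenvalue:.2f}, "
          f"{res.pct_correct:.1f}% correctly classified")

    (OUT / "stats.json").write_text(json.dumps(out, indent=2) + "\n")
    print(f"\nWrote {OUT / 'stats.json'}")


if __name__ == "__main__":
    main()
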