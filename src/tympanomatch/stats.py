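"""Population-comparison statistics for call features.

Covers the in-scope inferential toolkit: Pearson chi-square (no continuity
correction) for the 2x2 ultrasound contingency, two-sample t-tests
(pooled-variance by default, Welch optional), and two-group stepwise linear
discriminant analysis with the canonical summary (Wilks' lambda,
eigenvalue, standardized coefficients, in-sample classification).

Mixed-effects models, ANCOVA and least-square-means contrasts are left to
external software; the pipeline exports tidy long-format tables for them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as spstats


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Rows = populations, columns = ultrasound yes/no."""

    counts: np.ndarray
    row_labels: tuple[str, str] = ("central", "southern")
    col_labels: tuple[str, str] = ("ultrasound", "no_ultrasound")

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (2, 2):
            raise ValueError("counts must be 2x2")
        if np.any(c < 0) or c.sum() == 0:
            raise ValueError("counts must be non-negative with a positive total")
        object.__setattr__(self, "counts", c.astype(np.int64))

    def row_percentages(self) -> np.ndarray:
        return 100.0 * self.counts[:, 0] / self.counts.sum(axis=1)


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    variant: str


@dataclass(frozen=True)
class LDAResult:
    selected_variables: tuple[str, ...]
    coefficients: np.ndarray  # standardized discriminant weights
    wilks_lambda: float
    eigenvalue: float
    pct_correct: float
    confusion: np.ndarray  # rows true group, cols predicted


def chisq_2x2(table: ContingencyTable2x2) -> tuple[float, int, float]:
    """Pearson chi-square without continuity correction, df = 1."""
    c = table.counts
    if np.any(c.sum(axis=0) == 0) or np.any(c.sum(axis=1) == 0):
        raise ValueError("zero marginal; chi-square undefined")
    stat, p, df, _ = spstats.chi2_contingency(c, correction=False)
    return float(stat), int(df), float(p)


def two_sample_t(x: Sequence[float], y: Sequence[float], variant: str = "pooled") -> TTestResult:
    """Two-sample t-test; ``variant`` is ``"pooled"`` or ``"welch"``."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least two observations per sample")
    if np.var(x) == 0 and np.var(y) == 0 and np.mean(x) == np.mean(y):
        return TTestResult(0.0, float(x.size + y.size - 2), 1.0, variant)
    if variant == "pooled":
        res = spstats.ttest_ind(x, y, equal_var=True)
        df = x.size + y.size - 2
    elif variant == "welch":
        res = spstats.ttest_ind(x, y, equal_var=False)
        vx, vy = x.var(ddof=1) / x.size, y.var(ddof=1) / y.size
        df = (vx + vy) ** 2 / (vx**2 / (x.size - 1) + vy**2 / (y.size - 1))
    else:
        raise ValueError(f"unknown variant: {variant!r}")
    return TTestResult(float(res.statistic), float(df), float(res.pvalue), variant)


def two_sample_t_from_summary(
    mean1: float, se1: float, n1: int, mean2: float, se2: float, n2: int
) -> TTestResult:
    """Pooled-variance t reconstructed from per-group means and standard
    errors — for auditing published summary tables."""
    s1sq = (se1 * np.sqrt(n1)) ** 2
    s2sq = (se2 * np.sqrt(n2)) ** 2
    df = n1 + n2 - 2
    sp_sq = ((n1 - 1) * s1sq + (n2 - 1) * s2sq) / df
    t = (mean1 - mean2) / np.sqrt(sp_sq * (1 / n1 + 1 / n2))
    p = 2 * spstats.t.sf(abs(t), df)
    return TTestResult(float(t), float(df), float(p), "pooled")


def _wilks_lambda(X: np.ndarray, groups: np.ndarray, cols: Sequence[int]) -> float:
    """det(W)/det(T) for the selected columns."""
    Xs = X[:, list(cols)]
    overall = Xs.mean(axis=0)
    T = (Xs - overall).T @ (Xs - overall)
    W = np.zeros_like(T)
    for g in (0, 1):
        Xg = Xs[groups == g]
        W += (Xg - Xg.mean(axis=0)).T @ (Xg - Xg.mean(axis=0))
    detT = np.linalg.det(T)
    if detT <= 0:
        raise np.linalg.LinAlgError("singular total scatter")
    return float(np.linalg.det(W) / detT)


def lda_two_group(
    features: np.ndarray,
    labels: Iterable,
    variable_names: Sequence[str] | None = None,
    stepwise: bool = True,
    f_to_enter: float = 3.84,
) -> LDAResult:
    """Fisher two-group discriminant with forward stepwise selection.

    Variables enter one at a time, each step choosing the candidate that
    minimizes Wilks' lambda, and stopping when the partial F of the best
    candidate falls below ``f_to_enter``.  With two groups there is a
    single discriminant function, so the canonical eigenvalue is
    ``(1 - lambda) / lambda`` and ``lambda * (1 + eigenvalue) = 1`` holds
    identically.  Classification is in-sample: cases project onto the
    discriminant axis and split at the midpoint of the group mean scores.
    """
    X = np.asarray(features, dtype=np.float64)
    labels = np.asarray(list(labels))
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError("exactly two groups required")
    groups = (labels == uniq[1]).astype(int)
    n, p = X.shape
    if min(np.bincount(groups)) < 2:
        raise ValueError("need at least 2 cases per group")
    if variable_names is None:
        variable_names = [f"x{j}" for j in range(p)]

    if stepwise:
        selected: list[int] = []
        lam_current = 1.0
        remaining = list(range(p))
        while remaining:
            lams = []
            for j in remaining:
                try:
                    lams.append(_wilks_lambda(X, groups, selected + [j]))
                except np.linalg.LinAlgError:
                    lams.append(np.inf)
            j_best = remaining[int(np.argmin(lams))]
            lam_best = min(lams)
            if not np.isfinite(lam_best) or lam_best <= 0:
                break
            p_after = len(selected) + 1
            f_partial = (n - 2 - p_after + 1 - 1) * (lam_current / lam_best - 1.0)
            if f_partial < f_to_enter:
                break
            selected.append(j_best)
            remaining.remove(j_best)
            lam_current = lam_best
        if not selected:  # nothing discriminates; keep the least-bad variable
            selected = [int(np.argmin([_wilks_lambda(X, groups, [j]) for j in range(p)]))]
            lam_current = _wilks_lambda(X, groups, selected)
    else:
        selected = list(range(p))
        lam_current = _wilks_lambda(X, groups, selected)

    Xs = X[:, selected]
    m0 = Xs[groups == 0].mean(axis=0)
    m1 = Xs[groups == 1].mean(axis=0)
    W = np.zeros((len(selected), len(selected)))
    for g in (0, 1):
        Xg = Xs[groups == g]
        W += (Xg - Xg.mean(axis=0)).T @ (Xg - Xg.mean(axis=0))
    Sw = W / (n - 2)  # pooled within-group covariance
    w = np.linalg.solve(Sw, m1 - m0)
    eigenvalue = (1.0 - lam_current) / lam_current

    # standardized coefficients: weight per within-group SD of each variable
    std_coef = w * np.sqrt(np.diag(Sw))
    std_coef = std_coef / np.linalg.norm(std_coef)

    scores = Xs @ w
    cut = 0.5 * (scores[groups == 0].mean() + scores[groups == 1].mean())
    sign = 1.0 if scores[groups == 1].mean() > scores[groups == 0].mean() else -1.0
    pred = (sign * (scores - cut) > 0).astype(int)
    confusion = np.array(
        [[np.sum((groups == g) & (pred == q)) for q in (0, 1)] for g in (0, 1)]
    )
    pct_correct = 100.0 * np.trace(confusion) / n
    return LDAResult(
        selected_variables=tuple(variable_names[j] for j in selected),
        coefficients=std_coef,
        wilks_lambda=float(lam_current),
        eigenvalue=float(eigenvalue),
        pct_correct=float(pct_correct),
        confusion=confusion,
    )


def ultrasound_contingency(
    flags: Sequence[bool], populations: Sequence[str],
    row_labels: tuple[str, str] = ("central", "southern"),
) -> ContingencyTable2x2:
    """Count ultrasound-positive calls per population into a 2x2 table."""
    flags = np.asarray(flags, dtype=bool)
    populations = np.asarray(populations)
    counts = np.zeros((2, 2), dtype=np.int64)
    for i, pop in enumerate(row_labels):
        mask = populations == pop
        counts[i, 0] = int(np.sum(flags[mask]))
        counts[i, 1] = int(np.sum(~flags[mask]))
    return ContingencyTable2x2(counts, row_labels=row_labels)
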