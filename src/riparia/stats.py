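"""Shared statistical primitives: Spearman matrices, BH-FDR, Wilson bands,
rank-sum stratum comparisons, and seed stream management."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as ss

__all__ = [
    "spearman_matrix",
    "bh_fdr",
    "wilson_interval",
    "compare_strata",
    "StratumComparison",
    "spawn_seeds",
]


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent child seeds from a global seed.

    Uses numpy's SeedSequence spawning so stages consume non-overlapping
    streams; children are reduced to 31-bit ints for portability.
    """
    ss_ = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss_.spawn(n)]


def spearman_matrix(counts: np.ndarray):
    """All-pairs Spearman rho and two-sided p over columns of ``counts``.

    Ties are handled by average ranks; p comes from the t approximation on
    rho.  Zero-variance columns have no defined correlation: their entries
    are recorded as rho = 0 with p = 1, and the column indices are returned
    so callers can flag them.
    """
    x = np.asarray(counts, dtype=float)
    n, m = x.shape
    if n < 4:
        raise ValueError("need >= 4 samples for Spearman p-values")
    constant = np.where(x.std(axis=0) == 0)[0]
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, p = ss.spearmanr(x, axis=0)
    if m == 2:  # scipy collapses the 2-column case to scalars
        rho = np.array([[1.0, rho], [rho, 1.0]])
        p = np.array([[0.0, p], [p, 0.0]])
    rho = np.atleast_2d(np.asarray(rho, dtype=float))
    p = np.atleast_2d(np.asarray(p, dtype=float))
    bad = np.isnan(rho)
    rho[bad] = 0.0
    p[bad] = 1.0
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(p, 0.0)
    return rho, p, constant.tolist()


def bh_fdr(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1, in the input order.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("bh_fdr expects a 1-D vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def wilson_interval(successes: float, trials: int, z: float = 1.96):
    """Wilson score confidence interval for a binomial proportion.

    ``successes`` may be non-integer (e.g. a model-predicted frequency times
    the number of samples); the closed form only needs p-hat = k/n.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if not 0 <= successes <= trials:
        raise ValueError("successes must lie in [0, trials]")
    n = float(trials)
    phat = successes / n
    denom = 1.0 + z**2 / n
    centre = (phat + z**2 / (2 * n)) / denom
    half = z * np.sqrt(phat * (1 - phat) / n + z**2 / (4 * n**2)) / denom
    return max(0.0, centre - half), min(1.0, centre + half)


@dataclass
class StratumComparison:
    metric: str
    levels: tuple
    medians: tuple
    statistic: float
    p_value: float


def compare_strata(values: pd.DataFrame, labels: pd.Series) -> list[StratumComparison]:
    """Two-sided Wilcoxon rank-sum test of each metric between two strata.

    Exact null distribution for small untied samples, normal approximation
    with tie correction otherwise (scipy's ``method='auto'``).  The reported
    statistic is the conventional Mann-Whitney U = min(U1, U2).  Metrics
    with an empty stratum are skipped with a warning.
    """
    labels = labels.loc[values.index]
    levels = sorted(set(labels))
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 strata, got {levels}")
    out = []
    for metric in values.columns:
        a = values.loc[labels == levels[0], metric].dropna()
        b = values.loc[labels == levels[1], metric].dropna()
        if len(a) < 2 or len(b) < 2:
            warnings.warn(f"stratum too small for {metric!r}; skipped", stacklevel=2)
            continue
        res = ss.mannwhitneyu(a, b, alternative="two-sided", method="auto")
        u = float(min(res.statistic, len(a) * len(b) - res.statistic))
        out.append(
            StratumComparison(
                metric=metric,
                levels=tuple(levels),
                medians=(float(a.median()), float(b.median())),
                statistic=u,
                p_value=float(res.pvalue),
            )
        )
    return out
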