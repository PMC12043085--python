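"""Shared statistical primitives: exact binomial tails, BH step-up FDR,
and the contingency/rank tests used for cohort comparisons.

Each primitive has a brute-force oracle in the test suite; the implementations
here delegate to scipy where a standard routine exists and keep the step-up
adjustment explicit because its family definition (which p-values enter) is a
design decision of the triage screen, not a library default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


class StatsError(ValueError):
    """Domain error in a statistical primitive."""


@dataclass(frozen=True)
class ContingencyTable:
    """An r x 2 table of non-negative integer counts with optional labels."""

    counts: tuple[tuple[int, ...], ...]
    row_labels: tuple[str, ...] | None = None
    col_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
            raise StatsError("contingency table must be r x 2 with r >= 2")
        if (arr < 0).any():
            raise StatsError("counts must be non-negative")
        if not (arr.sum(axis=1) > 0).any():
            raise StatsError("at least one row total must be positive")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)


def binomial_upper_tail(observed: int, trials: int, p: float) -> float:
    """P(X >= observed) for X ~ Binomial(trials, p).

    The one-sided overrepresentation test of the variant screen: the observed
    allele count is compared against its population expectation.
    """
    if not 0.0 <= p <= 1.0:
        raise StatsError(f"success probability must lie in [0, 1], got {p!r}")
    if not 0 <= observed <= trials:
        raise StatsError(f"need 0 <= observed <= trials, got {observed}/{trials}")
    if observed == 0:
        return 1.0
    # sf(k) = P(X > k); upper tail including the observation is sf(observed - 1)
    return float(sps.binom.sf(observed - 1, trials, p))


def poisson_upper_tail(observed: int, trials: int, p: float) -> float:
    """Poisson approximation to :func:`binomial_upper_tail` with mean trials*p."""
    if not 0.0 <= p <= 1.0:
        raise StatsError(f"success probability must lie in [0, 1], got {p!r}")
    if observed == 0:
        return 1.0
    return float(sps.poisson.sf(observed - 1, trials * p))


def bh_adjust(pvalues, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted q-values and rejection flags.

    Returns ``(qvalues, reject)`` in the input order. ``reject[i]`` is true
    iff ``qvalues[i] <= alpha``; rejections form a prefix of the p-values
    sorted ascending.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if ((p < 0) | (p > 1)).any():
        raise StatsError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q, q <= alpha


def chi_square_test(table: ContingencyTable, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square test of independence on an r x 2 table.

    No continuity correction by default. A zero marginal makes the statistic
    undefined; the error message points to Fisher's exact test.
    """
    arr = table.array
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise StatsError(
            "chi-square undefined with a zero marginal; use fisher_exact_2x2"
        )
    stat, p, _, _ = sps.chi2_contingency(arr, correction=correction)
    return float(stat), float(p)


def fisher_exact_2x2(table: ContingencyTable, alternative: str = "two-sided") -> float:
    """Fisher's exact test p-value on a 2x2 table."""
    arr = table.array
    if arr.shape != (2, 2):
        raise StatsError("Fisher's exact test requires a 2x2 table")
    _, p = sps.fisher_exact(arr, alternative=alternative)
    return float(p)


def mann_whitney(group_a, group_b, alternative: str = "two-sided") -> float:
    """Mann-Whitney U test p-value comparing two non-empty samples."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise StatsError("both groups must be non-empty")
    _, p = sps.mannwhitneyu(a, b, alternative=alternative)
    return float(p)
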