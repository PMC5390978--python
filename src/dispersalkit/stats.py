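"""Small self-contained tests used alongside the dispersal analysis:
Yates-corrected chi-square for 2x2 tables (pigment effect on flight),
exact two-sided binomial sex-ratio tests, and the Benjamini-Hochberg
false-discovery-rate screen across releases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["TwoByTwo", "yates_chi_square", "pearson_chi_square", "binom_two_sided",
           "benjamini_hochberg"]


@dataclass(frozen=True)
class TwoByTwo:
    """2x2 contingency table; rows = group, columns = outcome."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        rows = (self.a + self.b, self.c + self.d)
        cols = (self.a + self.c, self.b + self.d)
        if min(rows) == 0 or min(cols) == 0:
            raise ValueError("all margins must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], float)


def yates_chi_square(table: TwoByTwo) -> tuple[float, float]:
    """Pearson chi-square with continuity correction, df = 1.

    The correction shrinks each |O - E| by 0.5 (floored at zero), so the
    statistic never exceeds the uncorrected one.
    """
    obs = table.as_array()
    stat, p, _, _ = stats.chi2_contingency(obs, correction=True)
    return float(stat), float(p)


def pearson_chi_square(table: TwoByTwo) -> tuple[float, float]:
    """Uncorrected Pearson chi-square, df = 1."""
    stat, p, _, _ = stats.chi2_contingency(table.as_array(), correction=False)
    return float(stat), float(p)


def binom_two_sided(k: int, n: int) -> float:
    """Exact two-sided binomial test against p0 = 1/2.

    Equal-tail doubling: p = min(1, 2 * min(P(X <= k), P(X >= k))).  At a
    symmetric null this coincides with the minimum-likelihood convention.
    """
    if n < 1 or not 0 <= k <= n:
        raise ValueError("need n >= 1 and 0 <= k <= n")
    lower = stats.binom.cdf(k, n, 0.5)
    upper = stats.binom.sf(k - 1, n, 0.5)
    return float(min(1.0, 2.0 * min(lower, upper)))


def benjamini_hochberg(p_values, q: float = 0.2) -> np.ndarray:
    """Step-up FDR screen; returns a boolean rejection flag per input p.

    Rejects all p <= p_(k*) where k* = max{k : p_(k) <= k q / m}.
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie in (0, 1)")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject
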