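"""Small shared statistical utilities.

These are thin, well-tested wrappers kept in one place so that every module
applies multiple-testing correction, p-value combination and ranked-retrieval
metrics identically.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "bh_adjust",
    "stouffer_combine",
    "average_precision",
    "hypergeom_sf",
    "fisher_one_sided",
]


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (FDR) for one family of tests."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def stouffer_combine(p_a: float, p_b: float) -> float:
    """Combine two one-sided p-values with equal-weight Stouffer's method.

    z_i = Phi^{-1}(1 - p_i); combined p = Phi(-(z_a + z_b) / sqrt(2)).
    Degenerate inputs (p == 1, z = -inf) propagate to a combined p of 1.
    """
    z = stats.norm.isf([p_a, p_b])
    with np.errstate(invalid="ignore"):
        z_comb = (z[0] + z[1]) / np.sqrt(2.0)
    if np.isnan(z_comb):  # only when one z is +inf and the other -inf
        return 0.5
    return float(stats.norm.sf(z_comb))


def average_precision(labels_in_rank_order: Sequence[int]) -> float:
    """Average precision of an explicit ranking (1 = positive, 0 = negative).

    Step-wise estimator: mean over positives of precision at each positive's
    rank.  Using the explicit order (rather than scores) keeps deterministic
    tie-breaking decisions made by the caller intact.
    """
    y = np.asarray(labels_in_rank_order, dtype=float)
    n_pos = y.sum()
    if n_pos == 0:
        raise ValueError("average precision undefined without positives")
    cum_hits = np.cumsum(y)
    ranks = np.arange(1, y.size + 1)
    return float(np.sum((cum_hits / ranks) * y) / n_pos)


def hypergeom_sf(overlap: int, background: int, n_annotation: int, n_draw: int) -> float:
    """One-sided over-representation p-value: P(X >= overlap)."""
    return float(stats.hypergeom.sf(overlap - 1, background, n_annotation, n_draw))


def fisher_one_sided(table: np.ndarray) -> float:
    """One-tailed (greater) Fisher's exact test on a 2x2 contingency table."""
    return float(stats.fisher_exact(np.asarray(table), alternative="greater")[1])
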