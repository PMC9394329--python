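"""Exact paired statistics: Wilcoxon signed-rank test and Bonferroni correction.

The signed-rank null distribution is enumerated exactly over all 2^n
equally likely sign assignments of the ranked absolute differences
(computed by convolution rather than explicit enumeration, so n up to 25 is
instantaneous). Zero differences are dropped before ranking and tied
absolute values receive mid-ranks, the standard conventions for the exact
test. The two-sided p-value is the null probability of a signed-rank sum at
least as far from its mean as the observed one; for the symmetric null this
equals the doubled smaller tail.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.stats import rankdata

__all__ = ["wilcoxon_exact", "bonferroni"]


def _signed_rank_distribution(double_ranks: np.ndarray) -> np.ndarray:
    """Exact pmf of W+ over doubled mid-ranks (so support is integer).

    Returns an array ``pmf`` where ``pmf[k]`` is the probability that the
    doubled positive-rank sum equals k, under random independent signs.
    """
    total = int(double_ranks.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in double_ranks:
        r = int(r)
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[: total + 1 - r]
        pmf = 0.5 * (pmf + shifted)
    return pmf


def wilcoxon_exact(differences) -> float:
    """Two-sided exact Wilcoxon signed-rank p-value for paired differences.

    Parameters
    ----------
    differences
        Paired differences (at most 25 after dropping zeros — the exact
        enumeration regime).
    """
    d = np.asarray(differences, dtype=float)
    if d.ndim != 1 or d.size == 0:
        raise ValueError("differences must be a non-empty 1-d sample")
    if np.isnan(d).any():
        raise ValueError("differences contain missing values")
    d = d[d != 0.0]
    if d.size == 0:
        warnings.warn("all differences are zero; p = 1", stacklevel=2)
        return 1.0
    if d.size > 25:
        raise ValueError(f"n = {d.size} exceeds the exact enumeration regime (25)")

    ranks = rankdata(np.abs(d))            # mid-ranks for ties
    double_ranks = np.round(2 * ranks).astype(int)
    w_plus2 = float(double_ranks[d > 0].sum())
    pmf = _signed_rank_distribution(double_ranks)
    mean = double_ranks.sum() / 2.0
    dist_from_mean = abs(w_plus2 - mean)
    support = np.arange(pmf.size)
    p = float(pmf[np.abs(support - mean) >= dist_from_mean - 1e-9].sum())
    return min(p, 1.0)


def bonferroni(p_values, m: int | None = None):
    """Bonferroni-corrected p-values: min(m * P, 1).

    ``m`` defaults to the number of tests and must be at least that.
    """
    p = np.asarray(p_values, dtype=float)
    scalar = p.ndim == 0
    p = np.atleast_1d(p)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError(f"m = {m} is smaller than the number of tests ({p.size})")
    out = np.minimum(m * p, 1.0)
    return float(out[0]) if scalar else out
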