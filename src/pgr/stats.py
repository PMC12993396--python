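"""Rank-based statistics for the pruning experiment.

``wilcoxon_rank_sum`` enumerates the exact null distribution for small
samples and falls back to the tie-corrected normal approximation; the
Benjamini-Hochberg step-up converts the resulting p values into q values.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.stats import mannwhitneyu, rankdata

#: Combined sample size at or below which the exact permutation null is used.
EXACT_LIMIT = 12


def wilcoxon_rank_sum(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns (W, p) where W is the rank sum of ``a`` within the pooled
    sample (midranks under ties).  For ``len(a)+len(b) <= 12`` the p value
    comes from full enumeration of rank assignments, counting assignments
    at least as far from the null mean as observed; otherwise from the
    normal approximation with tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    w = float(ranks[:n_a].sum())

    if n_a + n_b <= EXACT_LIMIT:
        mu = n_a * (n_a + n_b + 1) / 2.0
        dev = abs(w - mu)
        count = total = 0
        for idx in combinations(range(n_a + n_b), n_a):
            ws = ranks[list(idx)].sum()
            total += 1
            if abs(ws - mu) >= dev - 1e-12:
                count += 1
        return w, count / total

    res = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic", use_continuity=True)
    return w, float(res.pvalue)


def benjamini_hochberg(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment.

    ``q_i = min_{j >= rank(i)} (m * p_(j) / j)``, capped at 1; monotone in
    the input order of p values.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(adjusted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(adjusted, 1.0)
    return q
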