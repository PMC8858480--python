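"""Independent definition-level oracles used to cross-check the package.

These are deliberately naive (pair counting, rank-walking, exhaustive
enumeration) and share no code with the implementation they check.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np


def auroc_pair_counting(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUROC as the fraction of concordant (positive, negative) pairs, ties 1/2."""
    pos = scores[labels.astype(bool)]
    neg = scores[~labels.astype(bool)]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def average_precision_by_rank(scores: np.ndarray, labels: np.ndarray) -> float:
    """AP as the mean over positives of precision at that positive's rank.

    Tied scores share the precision computed at the bottom of their tie
    group (the threshold-based convention).
    """
    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    y = labels[order].astype(bool)
    precisions = []
    i = 0
    n = len(s)
    seen_pos = 0
    while i < n:
        j = i
        while j < n and s[j] == s[i]:
            j += 1
        group_pos = int(y[i:j].sum())
        seen_pos += group_pos
        if group_pos:
            precision = seen_pos / j  # precision at the bottom of the tie group
            precisions.extend([precision] * group_pos)
        i = j
    return float(np.mean(precisions))


def mann_whitney_enumeration(x, y) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney test by enumerating all rank assignments.

    Valid only for tie-free pooled samples.  Returns (U of x, exact p).
    """
    x = list(map(float, x))
    y = list(map(float, y))
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "enumeration oracle requires no ties"
    n1, n2 = len(x), len(y)

    def u_of(xvals, yvals):
        return sum(1.0 for a in xvals for b in yvals if a > b)

    u_obs = u_of(x, y)
    counts: dict[float, int] = {}
    for idx in combinations(range(n1 + n2), n1):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(n1 + n2) if i not in set(idx)]
        u = u_of(xs, ys)
        counts[u] = counts.get(u, 0) + 1
    total = comb(n1 + n2, n1)
    p_le = sum(c for u, c in counts.items() if u <= u_obs) / total
    p_ge = sum(c for u, c in counts.items() if u >= u_obs) / total
    return u_obs, min(1.0, 2.0 * min(p_le, p_ge))
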