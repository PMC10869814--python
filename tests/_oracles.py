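"""Brute-force enumeration oracles for the exact rank tests.

These deliberately share no code with the implementation: the null
distributions are built by explicit enumeration of every group assignment
(Mann-Whitney) or every sign pattern (Wilcoxon signed-rank) over the pooled
midranks.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.stats import rankdata


def mwu_exact_two_sided(x, y) -> float:
    """Two-sided exact Mann-Whitney p: double the smaller rank-sum tail."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n = len(pooled)
    n_x = len(x)
    observed = ranks[:n_x].sum()
    sums = [sum(ranks[list(idx)]) for idx in itertools.combinations(range(n), n_x)]
    total = len(sums)
    eps = 1e-9
    p_le = sum(1 for s in sums if s <= observed + eps) / total
    p_ge = sum(1 for s in sums if s >= observed - eps) / total
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_exact_two_sided(diffs) -> float:
    """Two-sided exact signed-rank p over all 2^n sign patterns (zeros dropped)."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        return 1.0
    ranks = rankdata(np.abs(d))
    observed = ranks[d > 0].sum()
    n = d.size
    w_plus = []
    for signs in itertools.product((0, 1), repeat=n):
        w_plus.append(sum(r for r, s in zip(ranks, signs) if s))
    total = len(w_plus)
    eps = 1e-9
    p_le = sum(1 for w in w_plus if w <= observed + eps) / total
    p_ge = sum(1 for w in w_plus if w >= observed - eps) / total
    return min(1.0, 2.0 * min(p_le, p_ge))


def spearman_exact_two_sided(x, y) -> tuple[float, float]:
    """Exact permutation p of |rho| over all orderings of y."""
    rx = rankdata(x)
    ry = rankdata(y)
    rho_obs = float(np.corrcoef(rx, ry)[0, 1])
    count = total = 0
    for perm in itertools.permutations(ry):
        r = float(np.corrcoef(rx, np.asarray(perm))[0, 1])
        total += 1
        if abs(r) >= abs(rho_obs) - 1e-12:
            count += 1
    return rho_obs, count / total
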