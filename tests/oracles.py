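"""Brute-force enumeration oracles, independent of the implementation."""

from itertools import permutations, product

import numpy as np
import scipy.stats as sps


def wilcoxon_enumeration_p(diffs):
    """Two-sided signed-rank p by full 2^n sign enumeration (zero-drop,
    midranks)."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in product([0, 1], repeat=n):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.array(ws)
    lo = (ws <= w_obs + 1e-9).mean()
    hi = (ws >= w_obs - 1e-9).mean()
    return min(1.0, 2 * min(lo, hi))


def friedman_enumeration_p(values):
    """Exact Friedman p by enumerating all (3!)^n within-row label
    permutations of the rank patterns."""
    v = np.asarray(values, float)
    n, k = v.shape
    ranks = np.array([sps.rankdata(row) for row in v])
    t_obs = np.sum((ranks.sum(axis=0) - n * (k + 1) / 2) ** 2)
    perms = list(permutations(range(k)))
    count = total = 0
    for arrangement in product(range(len(perms)), repeat=n):
        sums = np.zeros(k)
        for row, ai in zip(ranks, arrangement):
            sums += row[list(perms[ai])]
        t = np.sum((sums - n * (k + 1) / 2) ** 2)
        total += 1
        if t >= t_obs - 1e-9:
            count += 1
    return count / total
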