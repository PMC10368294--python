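"""Independent brute-force oracles used to validate the fast implementations.

Each oracle is deliberately naive (full enumeration / direct formula) and
shares no code with the implementation it checks.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.stats import rankdata


def bh_bruteforce(pvals) -> np.ndarray:
    """Step-up BH from the definition: q_i = min_{j >= i} p_(j) * n / j."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = []
    for i in range(n):
        q = min(p[order[j]] * n / (j + 1) for j in range(i, n))
        q_sorted.append(min(q, 1.0))
    out = np.empty(n)
    for rank, idx in enumerate(order):
        out[idx] = q_sorted[rank]
    return out


def wilcoxon_enumerate(diffs) -> tuple[float, float]:
    """(W+, two-sided exact p) by full 2^n sign enumeration with midranks."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.asarray(ws)
    lo = np.mean(ws <= w_obs + 1e-12)
    hi = np.mean(ws >= w_obs - 1e-12)
    return float(w_obs), float(min(1.0, 2 * min(lo, hi)))


def nussinov_enumerate(seq: str, allow_gu: bool = True, min_loop: int = 3) -> int:
    """Maximum base pairs over all valid non-crossing structures, by recursion."""
    s = seq.upper().replace("U", "T")
    wc = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
    gu = {("G", "T"), ("T", "G")}
    allowed = wc | gu if allow_gu else wc

    def best(i, j):
        if j - i < min_loop + 2:
            return 0
        options = [best(i + 1, j)]
        for k in range(i + min_loop + 1, j):
            if (s[i], s[k]) in allowed:
                options.append(1 + best(i + 1, k) + best(k + 1, j))
        return max(options)

    return best(0, len(s))


def pearson_chi2(table) -> float:
    """Pearson statistic directly from the textbook formula."""
    obs = np.asarray(table, dtype=float)
    total = obs.sum()
    stat = 0.0
    for i in range(obs.shape[0]):
        for j in range(obs.shape[1]):
            e = obs[i].sum() * obs[:, j].sum() / total
            stat += (obs[i, j] - e) ** 2 / e
    return stat
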