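"""Independent brute-force oracles, kept deliberately literal and slow.

These implement the definitions directly — O(G·N²) double loops for percent
ranks, exhaustive labeling enumeration for the rank-sum null — and are never
shared with the package implementation they check.
"""

from itertools import combinations

import numpy as np


def brute_percent_rank(dense: np.ndarray) -> np.ndarray:
    """Literal percent rank: rank(c) = 1 + #{c' : x(c') < x(c)}, scaled.

    dense is genes × cells. O(G·N²).
    """
    G, N = dense.shape
    out = np.zeros((G, N))
    for g in range(G):
        for c in range(N):
            rank = 1 + int(np.sum(dense[g] < dense[g, c]))
            out[g, c] = (rank - 1) / (N - 1)
    return out


def brute_scgps(dense: np.ndarray, gene_rows) -> np.ndarray:
    """Mean of brute-force percent ranks over the given gene rows."""
    pr = brute_percent_rank(dense)
    return pr[list(gene_rows), :].mean(axis=0)


def exhaustive_rank_sum_p(a, b) -> float:
    """Exact two-sided rank-sum p by enumerating every group labeling.

    Computes U for group a and the null distribution of U over all
    C(n_a+n_b, n_a) assignments of the pooled values to group a. Two-sided p
    is the null probability of a U at least as far from its mean n_a·n_b/2
    as the observed one (the null distribution of U is symmetric).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    n_a = len(a)

    def u_stat(group_a_vals, group_b_vals):
        u = 0
        for x in group_a_vals:
            for y in group_b_vals:
                if x > y:
                    u += 1
                elif x == y:
                    u += 0.5
        return u

    u_obs = u_stat(a, b)
    mu = n_a * len(b) / 2.0
    count = 0
    total = 0
    idx = np.arange(len(pooled))
    for comb in combinations(idx, n_a):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(comb)] = True
        u = u_stat(pooled[mask], pooled[~mask])
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
        total += 1
    return count / total


def brute_bh(p: np.ndarray) -> np.ndarray:
    """Step-up BH: sort, scale by m/i, enforce monotonicity, cap at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for i in range(m - 1, -1, -1):
        running = min(running, p[order[i]] * m / (i + 1))
        adj[order[i]] = running
    return np.minimum(adj, 1.0)
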