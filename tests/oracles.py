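"""Independent brute-force oracles used to cross-check the implementations.

Each oracle recomputes a quantity from its definition with no shared
code path: O(N^2) distance scans for the neighbour MI estimator and
full enumeration of sign assignments / group assignments for the exact
Wilcoxon null distributions.
"""

from itertools import combinations, product

import numpy as np
from scipy.special import digamma
from scipy.stats import rankdata


def brute_knn_mi_bits(labels, responses, k):
    """Neighbour MI by naive per-point distance scans, in bits."""
    labels = np.asarray(labels)
    r = np.asarray(responses, dtype=float)
    n = len(r)
    contributions = []
    for i in range(n):
        same = np.flatnonzero(labels == labels[i])
        n_s = same.size
        if n_s < 2:
            continue
        k_i = min(k, n_s - 1)
        dists = np.sort(np.abs(r[same] - r[i]))  # position 0 is the self-distance
        d = dists[k_i]
        m = int((np.abs(r - r[i]) <= d).sum()) - 1
        contributions.append(digamma(n) - digamma(n_s) + digamma(k_i) - digamma(m))
    if not contributions:
        raise ValueError("no estimable points")
    return float(np.mean(contributions) / np.log(2))


def signed_rank_p_oracle(x, y, direction="greater"):
    """One-tailed exact signed-rank p by enumerating every sign assignment."""
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    hits = 0
    for signs in product([0, 1], repeat=n):
        w = sum(rk for s, rk in zip(signs, ranks) if s)
        if direction == "greater":
            hits += w >= w_obs - 1e-9
        else:
            hits += w <= w_obs + 1e-9
    return hits / 2**n


def rank_sum_p_oracle(a, b, direction="greater"):
    """One-tailed exact rank-sum p by enumerating every group assignment."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    m = a.size
    w_obs = ranks[:m].sum()
    hits = total = 0
    for comb in combinations(range(pooled.size), m):
        w = ranks[list(comb)].sum()
        if direction == "greater":
            hits += w >= w_obs - 1e-9
        else:
            hits += w <= w_obs + 1e-9
        total += 1
    return hits / total
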