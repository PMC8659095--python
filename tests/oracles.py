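"""Independent brute-force oracles used to check the package's metric code.

These deliberately share no code with screenaudit: AUC by explicit
active-inactive pair counting, EF by literal top-k selection, Mann-Whitney by
exhaustive enumeration of label assignments, and Spearman by the
rank-difference formula.
"""

from itertools import combinations

import numpy as np


def auc_pair_counting(labels, scores):
    """AUC = (wins + ties/2) / (n_act * n_inact) over all active-inactive pairs."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    act = scores[labels == 1]
    inact = scores[labels == 0]
    wins = sum(1.0 for a in act for i in inact if a > i)
    ties = sum(1.0 for a in act for i in inact if a == i)
    return (wins + 0.5 * ties) / (len(act) * len(inact))


def ef_top_k(labels, scores, alpha, ids=None):
    """EF by literal sort on (score desc, id asc) and top-k counting."""
    import math

    labels = list(labels)
    scores = list(scores)
    n = len(labels)
    ids = list(ids) if ids is not None else list(range(n))
    order = sorted(range(n), key=lambda j: (-scores[j], ids[j]))
    k = math.ceil(alpha * n)
    a = sum(labels[j] for j in order[:k])
    total_act = sum(labels)
    return (a / k) / (total_act / n)


def _u_statistic(a, b):
    """Mann-Whitney U for sample a vs b, with half credit for ties."""
    return sum(1.0 if x > y else (0.5 if x == y else 0.0) for x in a for y in b)


def mannwhitney_exact_p(a, b):
    """Two-sided exact p by enumerating all assignments of the pooled values.

    p = min(1, 2 * min(P(U <= u_obs), P(U >= u_obs))) under the permutation
    null, matching the standard exact two-sided convention.
    """
    a = list(a)
    b = list(b)
    pooled = a + b
    n_a = len(a)
    u_obs = _u_statistic(a, b)
    us = []
    for idx in combinations(range(len(pooled)), n_a):
        sel = set(idx)
        xa = [pooled[i] for i in idx]
        xb = [pooled[i] for i in range(len(pooled)) if i not in sel]
        us.append(_u_statistic(xa, xb))
    us = np.asarray(us)
    p_le = np.mean(us <= u_obs + 1e-12)
    p_ge = np.mean(us >= u_obs - 1e-12)
    return min(1.0, 2.0 * min(p_le, p_ge))


def spearman_rank_formula(x, y):
    """Spearman rho = 1 - 6*sum(d^2)/(n(n^2-1)) for tie-free data."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rx = np.argsort(np.argsort(x)) + 1
    ry = np.argsort(np.argsort(y)) + 1
    d2 = float(np.sum((rx - ry) ** 2))
    n = x.size
    return 1.0 - 6.0 * d2 / (n * (n * n - 1))
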