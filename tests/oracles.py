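"""Independent reference implementations used only to check the package.

Each oracle recomputes a quantity by a different route than the production
code: dense linear algebra instead of sparse power iteration, exact rational
arithmetic instead of scipy's hypergeometric survival function, explicit ROC
geometry instead of the closed-form rank estimator.
"""

from fractions import Fraction
from math import comb

import numpy as np

from signprop import GeneNetwork


def dense_normalized_adjacency(net: GeneNetwork) -> tuple[np.ndarray, list[str]]:
    """Brute-force W'_ij = w_ij / sqrt(d_i d_j) as a dense matrix."""
    order = net.node_list()
    n = len(order)
    w = np.zeros((n, n))
    for i, a in enumerate(order):
        for j, b in enumerate(order):
            if net.graph.has_edge(a, b):
                w[i, j] = net.graph[a][b]["weight"]
    d = w.sum(axis=1)
    out = np.zeros_like(w)
    for i in range(n):
        for j in range(n):
            if w[i, j] and d[i] > 0 and d[j] > 0:
                out[i, j] = w[i, j] / np.sqrt(d[i] * d[j])
    return out, order


def rwr_linear_solve(
    net: GeneNetwork, seed_weights: dict[str, float], gamma: float
) -> dict[str, float]:
    """Closed form p = gamma (I - (1-gamma) W')^-1 p0 by dense solve."""
    wn, order = dense_normalized_adjacency(net)
    n = len(order)
    p0 = np.zeros(n)
    for g, wt in seed_weights.items():
        p0[order.index(g)] = wt
    p0 = p0 / p0.sum()
    p = gamma * np.linalg.solve(np.eye(n) - (1.0 - gamma) * wn, p0)
    return dict(zip(order, p))


def exact_hypergeom_tail(n_network: int, s0: int, k: int, ks: int) -> Fraction:
    """Exact tail sum_{i=ks..min(k,s0)} C(s0,i) C(N-s0,k-i) / C(N,k)."""
    total = Fraction(0)
    for i in range(ks, min(k, s0) + 1):
        if k - i > n_network - s0:
            continue
        total += Fraction(comb(s0, i) * comb(n_network - s0, k - i), comb(n_network, k))
    return total


def diamond_bruteforce(
    net: GeneNetwork, seed: set[str], max_iter: int
) -> list[tuple[str, int, Fraction]]:
    """Greedy expansion recomputing every candidate p exactly each iteration."""
    n_network = net.n_nodes
    cluster = set(seed)
    out: list[tuple[str, int, Fraction]] = []
    for iteration in range(1, max_iter + 1):
        candidates = []
        for g in sorted(net.nodes - cluster):
            ks = len(net.neighbors(g) & cluster)
            if ks == 0:
                continue
            k = net.degree(g)
            p = exact_hypergeom_tail(n_network, len(cluster), k, ks)
            candidates.append((p, -ks, k, g))
        if not candidates:
            break
        p, neg_ks, k, g = min(candidates)
        out.append((g, iteration, p))
        cluster.add(g)
    return out


def trapezoid_roc_auc(ranks_and_pools: list[tuple[int, int]]) -> float:
    """AUC by explicit ROC geometry over pooled normalized ranks.

    Each trial contributes one true-positive step at the false-positive rate
    (r - 1) / (M - 1) it forces; the curve is integrated with the trapezoid
    rule over the explicit step polyline.
    """
    fprs = sorted((r - 1) / (m - 1) for r, m in ranks_and_pools)
    p = len(fprs)
    xs: list[float] = [0.0]
    ys: list[float] = [0.0]
    for i, x in enumerate(fprs):
        xs.extend([x, x])
        ys.extend([i / p, (i + 1) / p])
    xs.append(1.0)
    ys.append(1.0)
    return float(np.trapezoid(ys, xs))
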