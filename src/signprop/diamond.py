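"""DIAMOnD-style greedy disease-module expansion.

Each iteration scores every candidate node with at least one link to the
current cluster by the hypergeometric tail probability of observing that
many links by chance, and absorbs the most significant one.  For a network
of N nodes, a cluster of s0 nodes, and a candidate of degree k with ks
links into the cluster, the connectivity significance is

    p(N, s0, k, ks) = sum_{i = ks..min(k, s0)} C(s0, i) C(N - s0, k - i) / C(N, k)

The rank of a gene is the iteration at which it joins the cluster; a gene
not absorbed within the iteration cap has a censored rank (its true rank is
only known to exceed the cap).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .io import GeneNetwork

__all__ = [
    "DiamondTrace",
    "connectivity_pvalue",
    "diamond_expand",
    "diamond_rank",
]


@dataclass(frozen=True)
class DiamondTrace:
    """Ordered record of one greedy expansion.

    ``added`` lists (gene, iteration, p_value) with iterations 1-based and
    strictly increasing; added genes are disjoint from ``seed0``.
    """

    added: tuple[tuple[str, int, float], ...]
    seed0: frozenset[str]
    max_iter: int
    n_network: int

    def iteration_of(self, gene: str) -> int | None:
        for g, it, _ in self.added:
            if g == gene:
                return it
        return None

    def genes(self) -> list[str]:
        return [g for g, _, _ in self.added]


def connectivity_pvalue(n_network: int, s0: int, k: int, ks: int) -> float:
    """Hypergeometric tail P[X >= ks] for X ~ Hypergeom(N, s0, k).

    Probability that a random degree-k node would have at least ks of its
    links falling inside a cluster of s0 nodes drawn from an N-node network.
    Returns 1.0 when ks = 0 (the whole support).
    """
    if ks > k:
        raise ValueError(f"ks={ks} exceeds candidate degree k={k}")
    if k > n_network:
        raise ValueError(f"degree k={k} exceeds network size N={n_network}")
    if ks > s0:
        raise ValueError(f"ks={ks} exceeds cluster size s0={s0}")
    if ks < 0 or k < 1:
        raise ValueError("require ks >= 0 and k >= 1")
    if ks == 0:
        return 1.0
    return float(hypergeom.sf(ks - 1, n_network, s0, k))


def diamond_expand(
    net: GeneNetwork, seed: set[str] | frozenset[str], max_iter: int = 1000
) -> DiamondTrace:
    """Greedy expansion by connectivity significance.

    At each iteration every node with >= 1 link to the current cluster
    (seed plus previously added genes) is scored with
    :func:`connectivity_pvalue` and the minimum-p node joins.  Expansion
    stops after ``max_iter`` iterations or when no candidate touches the
    cluster.  Ties on p are broken toward larger ks, then smaller degree k,
    then lexicographically smaller gene id, making the trace deterministic.
    """
    seed = frozenset(seed)
    if not seed:
        raise ValueError("DIAMOnD requires a nonempty seed")
    if not seed <= net.nodes:
        missing = sorted(seed - net.nodes)[:5]
        raise KeyError(f"seed genes not in network: {missing}")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")

    n_network = net.n_nodes
    # index nodes once (sorted, so index order == lexicographic order) and
    # keep per-node link counts into the cluster as flat arrays
    order = net.node_list()
    index = {g: i for i, g in enumerate(order)}
    degree = np.array([net.degree(g) for g in order])
    neighbor_idx = [
        np.array(sorted(index[nb] for nb in net.neighbors(g)), dtype=np.intp)
        for g in order
    ]
    in_cluster = np.zeros(n_network, dtype=bool)
    ks = np.zeros(n_network, dtype=np.int64)
    for s in seed:
        in_cluster[index[s]] = True
    for s in seed:
        ks[neighbor_idx[index[s]]] += 1

    added: list[tuple[str, int, float]] = []
    for iteration in range(1, max_iter + 1):
        cand = np.flatnonzero((ks > 0) & ~in_cluster)
        if cand.size == 0:
            break
        s0 = int(in_cluster.sum())
        ks_c = ks[cand]
        k_c = degree[cand]
        # p depends only on (k, ks) at fixed s0: evaluate unique pairs once
        key = ks_c * (int(degree.max()) + 1) + k_c
        uniq, inv = np.unique(key, return_inverse=True)
        kmax1 = int(degree.max()) + 1
        p_uniq = hypergeom.sf((uniq // kmax1) - 1, n_network, s0, uniq % kmax1)
        pvals = p_uniq[inv]
        # tie rule: min p, then larger ks, then smaller degree, then
        # lexicographically smaller gene id (== smaller index, stable sort)
        best = cand[np.lexsort((k_c, -ks_c, pvals))[0]]
        pos = int(np.searchsorted(cand, best))
        added.append((order[best], iteration, float(pvals[pos])))
        in_cluster[best] = True
        ks[neighbor_idx[best]] += 1

    return DiamondTrace(
        added=tuple(added), seed0=seed, max_iter=max_iter, n_network=n_network
    )


def diamond_rank(trace: DiamondTrace, test_gene: str) -> tuple[int, bool, int]:
    """Rank of the held-out gene: the iteration at which it was absorbed.

    Returns ``(rank, censored, M)``; when the gene was never absorbed the
    rank is the iteration cap and ``censored`` is True.  M is the candidate
    pool size N - |seed|.
    """
    if test_gene in trace.seed0:
        raise ValueError(f"test gene {test_gene!r} is in the seed")
    m = trace.n_network - len(trace.seed0)
    it = trace.iteration_of(test_gene)
    if it is None:
        return trace.max_iter, True, m
    return it, False, m
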