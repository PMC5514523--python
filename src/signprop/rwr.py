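"""Random walk with restart over the normalized interactome.

The walker iterates  p(t+1) = (1 - gamma) * W' p(t) + gamma * p0  from
p(0) = p0, where W' is the symmetrically normalized adjacency and p0 the
seed distribution.  gamma is the restart probability: at gamma = 1 the walk
never leaves the seeds; gamma = 0.4 (the default) propagates 60% of the
probability mass per step.  Because W' has spectral radius <= 1 the
iteration contracts at rate (1 - gamma) and converges geometrically for any
gamma in (0, 1].

With the symmetric (PRINCE) normalization the converged vector is not a
probability distribution; scores are used only ordinally, so no
renormalization is applied after convergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .io import NormalizedAdjacency

__all__ = [
    "PropagationConfig",
    "SeedVector",
    "PropagationResult",
    "ConvergenceError",
    "rwr_scores",
    "rwr_scores_batch",
    "rwr_rank",
]


class ConvergenceError(RuntimeError):
    """Raised when the power iteration fails to reach tolerance.

    Carries the last L1 residual in :attr:`residual`.
    """

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


@dataclass(frozen=True)
class PropagationConfig:
    """Restart probability and convergence controls for the walk."""

    gamma: float = 0.4
    tol: float = 1e-10
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError(f"gamma must be in (0, 1], got {self.gamma}")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass(frozen=True)
class SeedVector:
    """Nonnegative seed weights over a subset of network genes.

    Weights are normalized to sum to one before propagation.
    """

    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.weights:
            raise ValueError("seed vector is empty")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("seed weights must be nonnegative")
        if not any(w > 0 for w in self.weights.values()):
            raise ValueError("seed vector has no positive weight")

    @classmethod
    def uniform(cls, genes) -> "SeedVector":
        genes = list(genes)
        return cls({g: 1.0 for g in genes})

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(g for g, w in self.weights.items() if w > 0)

    def as_array(self, index: Mapping[str, int], n: int) -> np.ndarray:
        p0 = np.zeros(n)
        for g, w in self.weights.items():
            if g not in index:
                raise KeyError(f"seed gene {g!r} not in network")
            p0[index[g]] = w
        return p0 / p0.sum()


@dataclass
class PropagationResult:
    """Converged scores plus convergence diagnostics."""

    scores: dict[str, float]
    n_iter: int
    converged: bool
    residual: float
    _array: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]


def _iterate(matrix, p0: np.ndarray, gamma: float, tol: float, max_iter: int):
    """Shared power iteration; p0 may be a vector or an (n, s) column stack."""
    p = p0.copy()
    decay = 1.0 - gamma
    residual = np.inf
    for it in range(1, max_iter + 1):
        p_next = decay * (matrix @ p) + gamma * p0
        residual = float(np.max(np.sum(np.abs(p_next - p), axis=0)))
        p = p_next
        if residual < tol:
            return p, it, True, residual
    return p, max_iter, False, residual


def rwr_scores(
    adjacency: NormalizedAdjacency,
    seed: SeedVector,
    cfg: PropagationConfig = PropagationConfig(),
) -> PropagationResult:
    """Propagate the seed distribution to convergence.

    Nodes in components containing no seed gene score exactly zero.  Raises
    :class:`ConvergenceError` (carrying the last residual) if the L1 change
    between iterations does not drop below ``cfg.tol`` within
    ``cfg.max_iter`` steps.
    """
    p0 = seed.as_array(adjacency.index, adjacency.n)
    if cfg.gamma == 1.0:
        return PropagationResult(
            scores=dict(zip(adjacency.nodes, p0)), n_iter=0, converged=True,
            residual=0.0, _array=p0,
        )
    p, n_iter, converged, residual = _iterate(
        adjacency.matrix, p0, cfg.gamma, cfg.tol, cfg.max_iter
    )
    if not converged:
        raise ConvergenceError(
            f"RWR did not converge in {cfg.max_iter} iterations (residual {residual:.3e})",
            residual,
        )
    return PropagationResult(
        scores=dict(zip(adjacency.nodes, p)), n_iter=n_iter, converged=True,
        residual=residual, _array=p,
    )


def rwr_scores_batch(
    adjacency: NormalizedAdjacency,
    p0_columns: np.ndarray,
    cfg: PropagationConfig = PropagationConfig(),
) -> np.ndarray:
    """Propagate many seed distributions at once.

    ``p0_columns`` is an (n, s) array whose columns are already-normalized
    seed distributions; returns the (n, s) converged score columns.  Used by
    the leave-one-out drivers, where the s seed vectors of one gene set
    share the sparse matrix and converge together.
    """
    if p0_columns.ndim != 2:
        raise ValueError("p0_columns must be 2-D (n, s)")
    if cfg.gamma == 1.0:
        return p0_columns.copy()
    p, _, converged, residual = _iterate(
        adjacency.matrix, p0_columns, cfg.gamma, cfg.tol, cfg.max_iter
    )
    if not converged:
        raise ConvergenceError(
            f"batched RWR did not converge in {cfg.max_iter} iterations "
            f"(residual {residual:.3e})",
            residual,
        )
    return p


def rwr_rank(
    scores: Mapping[str, float],
    seed: SeedVector,
    test_gene: str,
) -> tuple[int, int]:
    """Rank of the held-out gene among all non-seed network nodes.

    Candidates are every scored node except the seed genes, so the pool size
    M equals N - |seed|.  Ties are broken pessimistically: the test gene is
    placed after every candidate sharing its score, so rank = 1 + #{better}
    + #{tied, != test}.  This makes zero-score test genes rank last among
    the unreachable candidates rather than benefiting from arbitrary order.
    """
    seed_genes = seed.genes
    if test_gene in seed_genes:
        raise ValueError(f"test gene {test_gene!r} is in the seed")
    if test_gene not in scores:
        raise KeyError(f"test gene {test_gene!r} has no score")
    s_test = scores[test_gene]
    rank = 1
    m = 0
    for g, s in scores.items():
        if g in seed_genes:
            continue
        m += 1
        if s > s_test:
            rank += 1
        elif s == s_test and g != test_gene:
            rank += 1
    return rank, m
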