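"""Cell–cell graph construction, pruning, and normalization.

Cells are nodes; edges connect mutual-or-one-way K nearest neighbors in an
embedding space. Long incident edges are pruned per node by an edge-length
quantile rule (with a connectivity guard), and the adjacency is normalized
either symmetrically with self-loops (GCN style) or by the iterative mixing
rule that blends the pruned graph of the first round with the row-normalized
current adjacency.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)


@dataclass
class CellGraph:
    """Symmetric unweighted-or-weighted adjacency over cells, zero diagonal."""

    adjacency: np.ndarray
    pruned: bool = False

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.allclose(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if np.any(a < 0):
            raise ValueError("adjacency must be nonnegative")
        self.adjacency = a

    @property
    def n_cells(self) -> int:
        return self.adjacency.shape[0]

    @property
    def degree(self) -> np.ndarray:
        return np.diag(self.adjacency.sum(axis=1))

    def edge_list(self) -> list[tuple[int, int, float]]:
        """Upper-triangle edges as (i, j, weight)."""
        ii, jj = np.nonzero(np.triu(self.adjacency, k=1))
        return [(int(i), int(j), float(self.adjacency[i, j])) for i, j in zip(ii, jj)]


@dataclass
class NormalizedAdjacency:
    """A normalized N×N propagation matrix and the scheme that produced it."""

    matrix: np.ndarray
    scheme: str  # "symmetric" | "iterative_mix"


def build_knn_graph(embedding: np.ndarray, k: int | None = None) -> CellGraph:
    """Unweighted KNN graph, OR-symmetrized, no self-edges.

    ``k`` defaults to max(5, round(N/10)). Edge (i, j) exists iff j is among
    the k Euclidean-nearest neighbors of i or vice versa.
    """
    emb = np.asarray(embedding, dtype=float)
    n = emb.shape[0]
    if k is None:
        k = max(5, round(n / 10))
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells {n}")
    d = cdist(emb, emb)
    np.fill_diagonal(d, np.inf)
    # ties broken by index order via stable argsort
    nn = np.argsort(d, axis=1, kind="stable")[:, :k]
    a = np.zeros((n, n))
    rows = np.repeat(np.arange(n), k)
    a[rows, nn.ravel()] = 1.0
    a = np.maximum(a, a.T)
    return CellGraph(adjacency=a, pruned=False)


def prune_graph(g: CellGraph, embedding: np.ndarray, quantile: float = 0.9) -> CellGraph:
    """Drop each node's longest incident edges beyond a length quantile.

    For every node, incident edges whose Euclidean length exceeds the given
    quantile of that node's incident edge lengths are removed; symmetry is
    restored by OR (an edge survives if either endpoint keeps it). A node
    that would lose all its edges retains its single shortest edge.
    """
    emb = np.asarray(embedding, dtype=float)
    a = g.adjacency.copy()
    n = g.n_cells
    d = cdist(emb, emb)
    keep = np.zeros_like(a, dtype=bool)
    for i in range(n):
        nbrs = np.nonzero(a[i])[0]
        if nbrs.size == 0:
            continue
        lengths = d[i, nbrs]
        cut = np.quantile(lengths, quantile)
        kept = nbrs[lengths <= cut]
        if kept.size == 0:
            kept = nbrs[[int(np.argmin(lengths))]]
        keep[i, kept] = True
    keep |= keep.T
    pruned = np.where(keep, a, 0.0)
    # connectivity guard: re-attach any isolated node by its shortest original edge
    for i in range(n):
        if pruned[i].sum() == 0:
            nbrs = np.nonzero(a[i])[0]
            if nbrs.size == 0:
                continue
            j = nbrs[int(np.argmin(d[i, nbrs]))]
            pruned[i, j] = pruned[j, i] = a[i, j]
    return CellGraph(adjacency=pruned, pruned=True)


def normalize_adjacency(g: CellGraph) -> NormalizedAdjacency:
    """Symmetric GCN normalization with self-loops.

    Returns D̃^(−1/2) (A + I) D̃^(−1/2) where D̃ is the degree of A + I.
    Self-loops guarantee strictly positive degrees, so the result is defined
    for isolated nodes and has spectral radius ≤ 1.
    """
    a_loop = g.adjacency + np.eye(g.n_cells)
    d_inv_sqrt = 1.0 / np.sqrt(a_loop.sum(axis=1))
    mat = a_loop * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]
    return NormalizedAdjacency(matrix=mat, scheme="symmetric")


def update_adjacency_iteration(
    L0: np.ndarray, A: np.ndarray, mix: float = 0.5
) -> NormalizedAdjacency:
    """Blend the first-round pruned graph with the current adjacency.

    Ã = μ·L0 + (1 − μ)·RowNorm(A), RowNorm(A)_ij = A_ij / Σ_j A_ij. A row of
    A that sums to zero is replaced by the uniform distribution over that
    row's L0 neighbors (or over all nodes if L0 is empty there too).
    """
    L0 = np.asarray(L0, dtype=float)
    A = np.asarray(A, dtype=float)
    if L0.shape != A.shape:
        raise ValueError("L0 and A shapes differ")
    if not 0.0 <= mix <= 1.0:
        raise ValueError("mix must lie in [0, 1]")
    rowsum = A.sum(axis=1)
    rn = np.zeros_like(A)
    ok = rowsum > 0
    rn[ok] = A[ok] / rowsum[ok, None]
    for i in np.nonzero(~ok)[0]:
        nbrs = np.nonzero(L0[i])[0]
        if nbrs.size == 0:
            rn[i] = 1.0 / A.shape[0]
        else:
            rn[i, nbrs] = 1.0 / nbrs.size
        logger.warning("zero-degree row %d in adjacency mix; using uniform fallback", i)
    return NormalizedAdjacency(matrix=mix * L0 + (1.0 - mix) * rn, scheme="iterative_mix")


def adjacency_delta(prev: np.ndarray, curr: np.ndarray) -> float:
    """Relative Frobenius change between consecutive propagation matrices."""
    denom = np.linalg.norm(prev)
    if denom == 0:
        return np.inf
    return float(np.linalg.norm(curr - prev) / denom)
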