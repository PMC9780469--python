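"""Cluster-count selection, cell assignment, and the outer iteration.

Louvain modularity optimization on the pruned cell graph fixes the number
of clusters; k-means on the learned graph embedding assigns cells to them.
The outer loop alternates feature autoencoder → cell-graph refinement →
graph autoencoder → clustering → per-cluster autoencoders, feeding each
round's reconstruction back as the next round's input, until the
propagation matrix and the labeling both stabilize. The imputation
autoencoder then runs once on the original pretreated matrix with the
final graph and cell-type relationships.
"""

from __future__ import annotations

import logging
import random as _pyrandom
from dataclasses import dataclass, field

import igraph
import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .cellgraph import (
    CellGraph,
    adjacency_delta,
    build_knn_graph,
    normalize_adjacency,
    prune_graph,
    update_adjacency_iteration,
)
from .config import RunConfig
from .ltmg import TRSMatrix
from .metrics import ari
from .networks import (
    ReconstructedMatrix,
    gae_decode,
    train_cluster_ae,
    train_feature_ae,
    train_gae,
    train_imputation_ae,
)
from .preprocess import ExpressionMatrix

logger = logging.getLogger(__name__)


def _l2_normalize_rows(z: np.ndarray) -> np.ndarray:
    """Project embeddings onto the unit sphere; inner-product encoders put
    cluster identity in the direction of Z rows, not their magnitude."""
    norms = np.linalg.norm(z, axis=1, keepdims=True)
    return z / np.maximum(norms, 1e-12)


@dataclass
class ClusterAssignment:
    """Per-cell labels (0-based, contiguous, size-sorted) and the B matrix."""

    labels: np.ndarray
    n_clusters: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        present = np.unique(self.labels)
        if not np.array_equal(present, np.arange(self.n_clusters)):
            raise ValueError("labels must be contiguous 0..k-1 with every label present")

    @property
    def same_type_matrix(self) -> np.ndarray:
        """B_ij = 1 iff cells i and j share a label (unit diagonal)."""
        return (self.labels[:, None] == self.labels[None, :]).astype(float)


@dataclass
class IterationState:
    """Convergence bookkeeping of the outer loop."""

    round: int = 0
    adjacency_delta: float = np.inf
    label_ari_prev: float = -1.0
    converged: bool = False
    history: list[dict] = field(default_factory=list)


def louvain_n_clusters(
    g: CellGraph,
    seed: int = 0,
    resolution: float = 1.0,
    min_cluster_size: int = 1,
    embedding: np.ndarray | None = None,
) -> int:
    """Number of communities found by Louvain modularity optimization.

    Communities smaller than ``min_cluster_size`` are merged into the
    nearest larger community — by mean embedding distance when an embedding
    is given, otherwise by strongest total edge weight. python-igraph draws
    its randomness from Python's ``random`` module, which is seeded here.
    """
    a = g.adjacency
    if a.sum() == 0:
        raise ValueError("empty graph: no edges to cluster")
    ii, jj = np.nonzero(np.triu(a, k=1))
    ig = igraph.Graph(
        n=g.n_cells,
        edges=list(zip(ii.tolist(), jj.tolist())),
        edge_attrs={"weight": a[ii, jj].tolist()},
    )
    _pyrandom.seed(seed)
    membership = np.asarray(
        ig.community_multilevel(weights="weight", resolution=resolution).membership
    )
    labels, counts = np.unique(membership, return_counts=True)
    big = labels[counts >= min_cluster_size]
    if big.size == 0:
        return 1
    small = labels[counts < min_cluster_size]
    for lab in small:
        idx = membership == lab
        if embedding is not None:
            centroid = embedding[idx].mean(axis=0, keepdims=True)
            dists = [
                cdist(centroid, embedding[membership == b].mean(axis=0, keepdims=True))[0, 0]
                for b in big
            ]
            target = big[int(np.argmin(dists))]
        else:
            weights = [a[np.ix_(np.nonzero(idx)[0], np.nonzero(membership == b)[0])].sum() for b in big]
            target = big[int(np.argmax(weights))]
        membership[idx] = target
    return int(np.unique(membership).size)


def kmeans_assign(z: np.ndarray, k: int, seed: int = 0) -> ClusterAssignment:
    """k-means (k-means++ init, n_init=10) with size-canonicalized labels.

    If the embedding has fewer distinct rows than k, k is reduced to that
    count (duplicate-centroid guard). Labels are relabeled by descending
    cluster size (ties by first occurrence) so identical partitions always
    serialize identically.
    """
    z = np.asarray(z, dtype=float)
    if k > z.shape[0]:
        raise ValueError("k exceeds the number of cells")
    n_distinct = np.unique(z, axis=0).shape[0]
    if k > n_distinct:
        logger.warning("k=%d exceeds %d distinct embedding rows; reducing", k, n_distinct)
        k = n_distinct
    raw = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(z)
    uniq, counts = np.unique(raw, return_counts=True)
    order = np.argsort(-counts, kind="stable")
    remap = {int(uniq[o]): rank for rank, o in enumerate(order)}
    labels = np.array([remap[int(r)] for r in raw])
    return ClusterAssignment(labels=labels, n_clusters=k)


def run_iterative_pipeline(
    x: ExpressionMatrix | np.ndarray,
    trs: TRSMatrix | None,
    cfg: RunConfig,
) -> tuple[ClusterAssignment, ReconstructedMatrix, IterationState]:
    """The full alternating workflow, then one imputation pass.

    Each round trains the feature autoencoder on the current input matrix
    (round 1: the pretreated matrix; later rounds: the previous round's
    cluster-autoencoder reconstruction), rebuilds and prunes the KNN cell
    graph (round 1 from the feature embedding, afterwards from the graph
    embedding), blends the propagation matrix with the first round's pruned
    graph (μ-mix), trains the graph autoencoder, fixes the cluster count by
    Louvain, assigns cells by k-means, and re-fits per-cluster autoencoders.
    The iteration stops when either stop criterion fires: the relative
    Frobenius change of the propagation matrix falls below ``tol_adj``
    (graph stabilized) or the ARI between consecutive labelings exceeds
    ``tol_ari`` (clustering result no longer changes). ``max_rounds`` caps
    the loop with a warning. Finally the imputation autoencoder is trained
    on the original pretreated matrix with the final graph and cell types.
    """
    x_arr = x.values if isinstance(x, ExpressionMatrix) else np.asarray(x, float)
    trs_w = trs.weight_matrix(cfg.trs_weight_mode) if trs is not None else np.ones_like(x_arr)

    state = IterationState()
    l0_norm = None
    prev_prop = None
    prev_labels = None
    z_prev = None
    input_matrix = x_arr
    assignment: ClusterAssignment | None = None
    pruned: CellGraph | None = None

    for rnd in range(1, cfg.max_rounds + 1):
        state.round = rnd
        feat_cfg = cfg.feature_ae_config(seed=cfg.seed + 100 + rnd)
        emb, xhat_f, feat_trace = train_feature_ae(input_matrix, trs_w, feat_cfg)

        use_prev_z = cfg.knn_on_gae_embedding and cfg.use_gae and z_prev is not None
        knn_emb = z_prev if use_prev_z else emb
        graph = build_knn_graph(knn_emb, cfg.knn_k)
        pruned = prune_graph(graph, knn_emb, cfg.prune_quantile)

        if l0_norm is None:
            l0_norm = normalize_adjacency(pruned).matrix
            prop = l0_norm
        else:
            prop = update_adjacency_iteration(l0_norm, pruned.adjacency, cfg.mix).matrix

        if cfg.use_gae:
            ge = train_gae(
                prop,
                xhat_f.values,
                pruned.adjacency,
                heads=cfg.heads,
                dims=cfg.gae_dims,
                learning_rate=cfg.gae_learning_rate,
                epochs=cfg.gae_epochs,
                seed=cfg.seed + 200 + rnd,
            )
            z = _l2_normalize_rows(ge.Z)
            gae_final_loss = float(ge.loss_trace[-1])
            # the cluster count comes from the cell graph the GAE learned:
            # its thresholded reconstruction is dense within cell types
            ahat = gae_decode(ge.Z).values
            learned = (ahat > 0.5).astype(float)
            np.fill_diagonal(learned, 0.0)
            louvain_graph = (
                CellGraph(adjacency=learned, pruned=True) if learned.sum() else pruned
            )
        else:
            z = emb
            gae_final_loss = np.nan
            louvain_graph = pruned

        k = louvain_n_clusters(
            louvain_graph,
            seed=cfg.seed + 300,
            resolution=cfg.louvain_resolution,
            min_cluster_size=cfg.min_cluster_size,
            embedding=z,
        )
        assignment = kmeans_assign(z, k, seed=cfg.seed + 400)

        state.adjacency_delta = (
            adjacency_delta(prev_prop, prop) if prev_prop is not None else np.inf
        )
        state.label_ari_prev = (
            ari(prev_labels, assignment.labels) if prev_labels is not None else -1.0
        )
        state.history.append(
            {
                "round": rnd,
                "n_clusters": k,
                "adjacency_delta": state.adjacency_delta,
                "label_ari_prev": state.label_ari_prev,
                "feature_loss": float(feat_trace[-1]),
                "gae_loss": gae_final_loss,
            }
        )
        logger.info(
            "round %d: k=%d delta=%.2e ari_prev=%.3f", rnd, k,
            state.adjacency_delta, state.label_ari_prev,
        )
        state.converged = (
            state.adjacency_delta < cfg.tol_adj or state.label_ari_prev > cfg.tol_ari
        )
        prev_prop, prev_labels, z_prev = prop, assignment.labels, z
        if state.converged:
            break

        cluster_cfg = cfg.feature_ae_config(seed=cfg.seed + 500 + rnd)
        xhat_c = train_cluster_ae(
            xhat_f, assignment.labels, cluster_cfg,
            trs_weight=trs_w, min_cluster_size=cfg.min_cluster_size,
        )
        input_matrix = xhat_c.values

    if not state.converged:
        logger.warning("iteration hit max_rounds=%d without converging", cfg.max_rounds)

    imp_cfg = cfg.feature_ae_config(seed=cfg.seed + 600)
    imp_cfg.epochs = cfg.imputation_epochs
    imputed, _ = train_imputation_ae(
        x_arr,
        (pruned.adjacency > 0).astype(float),
        assignment.same_type_matrix,
        trs_w,
        cfg.imputation_loss_config(),
        imp_cfg,
    )
    return assignment, imputed, state
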