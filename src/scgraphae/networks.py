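"""The four autoencoders: feature, graph (multi-head GAT), cluster, imputation.

The feature autoencoder compresses the log-normalized expression matrix to a
per-cell embedding under a TRS-weighted squared-error loss. The graph
autoencoder encodes the pruned cell graph through two graph-attention
convolutions (dot-product attention, softmax over neighbors, head-averaged)
and reconstructs the adjacency with a sigmoid inner-product decoder trained
by cross entropy. Cluster autoencoders re-fit each cell type separately.
The imputation autoencoder re-trains the feature architecture on the
pretreated matrix under graph, cell-type, and L1 regularizers; its
reconstruction is the imputation result.

All training is full-batch Adam on NumPy; every run is deterministic given
its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

import numpy as np

from ._nn import MLP, Adam, glorot, train_autoencoder
from .cellgraph import NormalizedAdjacency

logger = logging.getLogger(__name__)

_EPS = 1e-7


# ---------------------------------------------------------------------------
# configs and result containers


@dataclass
class FeatureAEConfig:
    """Dense autoencoder hyperparameters (shared by feature/cluster/imputation AEs)."""

    hidden_dim: int = 512
    latent_dim: int = 128
    learning_rate: float = 1e-3
    epochs: int = 500
    alpha: float = 0.5  # TRS-regularization mix weight
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.hidden_dim <= 0 or self.latent_dim <= 0:
            raise ValueError("layer dims must be positive")


@dataclass
class ImputationLossConfig:
    """Weights of the imputation loss terms."""

    alpha: float = 0.5   # TRS mix
    beta: float = 0.5    # L1 strength
    gamma1: float = 0.1  # cell-graph regularizer
    gamma2: float = 0.1  # cell-type regularizer

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [0, 1]")
        if min(self.alpha, self.gamma1, self.gamma2) < 0:
            raise ValueError("loss weights must be nonnegative")


@dataclass
class ReconstructedMatrix:
    """An N×G reconstruction and which autoencoder produced it."""

    values: np.ndarray
    source: str  # "feature_ae" | "cluster_ae" | "imputation_ae"


@dataclass
class AdjacencyReconstruction:
    """Sigmoid inner-product adjacency reconstruction, entries in (0, 1)."""

    values: np.ndarray


@dataclass
class GraphEmbedding:
    """GAT encoder state: final embedding, hidden layer, attention, weights."""

    Z: np.ndarray                       # N × d2 embedding
    H1: np.ndarray                      # N × d1 hidden activations
    weights: dict[str, np.ndarray]      # per-layer, per-head weight matrices
    attention: list[list[np.ndarray]]   # [layer][head] softmaxed coefficients
    n_heads: int
    loss_trace: np.ndarray = field(default_factory=lambda: np.empty(0))


# ---------------------------------------------------------------------------
# feature autoencoder


def feature_ae_loss(
    x: np.ndarray, xhat: np.ndarray, trs_weight: np.ndarray, alpha: float
) -> float:
    """(1−α)·Σ(X−X̂)² + α·Σ((X−X̂)² ∘ TRS weight). α=0 is plain summed MSE."""
    x, xhat = np.asarray(x, float), np.asarray(xhat, float)
    if x.shape != xhat.shape:
        raise ValueError("X and X̂ shapes differ")
    sq = (x - xhat) ** 2
    return float((1.0 - alpha) * sq.sum() + alpha * (sq * trs_weight).sum())


def train_feature_ae(
    x: np.ndarray, trs_weight: np.ndarray | float, cfg: FeatureAEConfig
) -> tuple[np.ndarray, ReconstructedMatrix, np.ndarray]:
    """Train the G→hidden→latent→hidden→G autoencoder.

    Returns (embedding N×latent, reconstruction, per-epoch loss trace).
    The element weight is (1−α) + α·TRSweight, which reproduces
    :func:`feature_ae_loss` exactly.
    """
    w = (1.0 - cfg.alpha) + cfg.alpha * np.asarray(trs_weight, dtype=float)
    _, emb, xhat, trace = train_autoencoder(
        x,
        [cfg.hidden_dim, cfg.latent_dim],
        weight=w,
        lr=cfg.learning_rate,
        epochs=cfg.epochs,
        seed=cfg.seed,
    )
    return emb, ReconstructedMatrix(values=xhat, source="feature_ae"), trace


# ---------------------------------------------------------------------------
# graph attention pieces


def attention_coefficients(
    h: np.ndarray, w: np.ndarray, mask: np.ndarray
) -> np.ndarray:
    """Dot-product attention, softmax-normalized over each node's neighbors.

    e_ij = (W h_i)·(W h_j) for masked pairs; rows softmax to 1 over the
    neighborhood (mask must include self-loops so no row is empty).
    """
    mask = np.asarray(mask, bool)
    if not mask.any(axis=1).all():
        raise ValueError("node with empty neighborhood; add self-loops")
    m = np.asarray(h, float) @ np.asarray(w, float)
    scores = m @ m.T
    scores = np.where(mask, scores, -np.inf)
    scores -= scores.max(axis=1, keepdims=True)
    ex = np.exp(scores)
    return ex / ex.sum(axis=1, keepdims=True)


def gat_layer(
    h: np.ndarray,
    atilde: NormalizedAdjacency | np.ndarray,
    heads: int,
    w_heads: list[np.ndarray],
    activation=lambda z: np.maximum(z, 0.0),
) -> np.ndarray:
    """One graph convolution: attention-weighted (K≥1) or plain GCN (K=0).

    K≥1: h′ = σ((1/K) Σ_k A_att^k (H W_k)) with A_att^k the softmaxed
    dot-product coefficients over the adjacency mask. K=0 ablates attention:
    h′ = σ(Ã H W).
    """
    a = atilde.matrix if isinstance(atilde, NormalizedAdjacency) else np.asarray(atilde, float)
    h = np.asarray(h, float)
    if heads == 0:
        return activation(a @ h @ w_heads[0])
    mask = (a + np.eye(a.shape[0])) > 0
    acc = np.zeros((h.shape[0], w_heads[0].shape[1]))
    for k in range(heads):
        att = attention_coefficients(h, w_heads[k], mask)
        acc += att @ (h @ w_heads[k])
    return activation(acc / heads)


def gae_decode(z: np.ndarray) -> AdjacencyReconstruction:
    """Â = sigmoid(Z Zᵀ); symmetric with entries strictly in (0, 1)."""
    z = np.asarray(z, float)
    s = z @ z.T
    with np.errstate(over="ignore"):
        vals = 1.0 / (1.0 + np.exp(-s))
    return AdjacencyReconstruction(values=np.clip(vals, _EPS, 1.0 - _EPS))


def gae_loss(a: np.ndarray, ahat: AdjacencyReconstruction | np.ndarray) -> float:
    """Mean binary cross entropy between 0/1 adjacency targets and Â."""
    a = np.asarray(a, float)
    v = ahat.values if isinstance(ahat, AdjacencyReconstruction) else np.asarray(ahat, float)
    if a.shape != v.shape:
        raise ValueError("adjacency shapes differ")
    v = np.clip(v, _EPS, 1.0 - _EPS)
    n2 = a.size
    return float(-(a * np.log(v) + (1.0 - a) * np.log(1.0 - v)).sum() / n2)


class _GATEncoder:
    """Two-layer GAT/GCN encoder trained to reconstruct the adjacency.

    Keeps per-head weight matrices for each layer and implements the exact
    gradient of the cross-entropy reconstruction loss through the sigmoid
    inner-product decoder, the head-averaged attention aggregation, and the
    ReLU activations.
    """

    def __init__(self, d_in: int, dims: tuple[int, int], heads: int, seed: int,
                 final_linear: bool = True):
        rng = np.random.default_rng(seed)
        self.heads = heads
        self.dims = dims
        # a linear embedding layer keeps the inner-product decoder sign-rich;
        # a ReLU there kills gradients for non-edges and stalls training
        self.final_linear = final_linear
        k = max(heads, 1)
        self.params: dict[str, np.ndarray] = {}
        for h in range(k):
            self.params[f"W0_{h}"] = glorot(rng, d_in, dims[0])
            self.params[f"W1_{h}"] = glorot(rng, dims[0], dims[1])

    # -- forward -----------------------------------------------------------
    def _activate(self, layer: int, pre: np.ndarray) -> np.ndarray:
        if layer == 1 and self.final_linear:
            return pre
        return np.maximum(pre, 0.0)

    def _layer_forward(self, layer: int, h: np.ndarray, a: np.ndarray, mask: np.ndarray):
        k = max(self.heads, 1)
        cache = {"h": h, "heads": []}
        if self.heads == 0:
            w = self.params[f"W{layer}_0"]
            z = a @ h @ w
            cache["pre"] = z
            return self._activate(layer, z), cache
        acc = 0.0
        for i in range(k):
            w = self.params[f"W{layer}_{i}"]
            m = h @ w
            scores = np.where(mask, m @ m.T, -np.inf)
            smax = scores.max(axis=1, keepdims=True)
            ex = np.exp(scores - smax)
            att = ex / ex.sum(axis=1, keepdims=True)
            acc = acc + att @ m
            cache["heads"].append({"m": m, "att": att})
        pre = acc / k
        cache["pre"] = pre
        return self._activate(layer, pre), cache

    def forward(self, features: np.ndarray, a: np.ndarray, mask: np.ndarray):
        h1, c1 = self._layer_forward(0, features, a, mask)
        z, c2 = self._layer_forward(1, h1, a, mask)
        return h1, z, (c1, c2)

    # -- backward ----------------------------------------------------------
    def _layer_backward(self, layer: int, d_out: np.ndarray, a: np.ndarray,
                        mask: np.ndarray, cache: dict):
        grads: dict[str, np.ndarray] = {}
        if layer == 1 and self.final_linear:
            d_pre = d_out
        else:
            d_pre = d_out * (cache["pre"] > 0)
        h = cache["h"]
        if self.heads == 0:
            w = self.params[f"W{layer}_0"]
            grads[f"W{layer}_0"] = (a @ h).T @ d_pre
            d_h = a.T @ (d_pre @ w.T)
            return grads, d_h
        k = self.heads
        d_h = np.zeros_like(h)
        for i in range(k):
            hc = cache["heads"][i]
            m, att = hc["m"], hc["att"]
            d_p = d_pre / k                      # P_k = att @ m
            d_att = d_p @ m.T
            d_m = att.T @ d_p
            # softmax backward, row-wise over the mask
            row_dot = (att * d_att).sum(axis=1, keepdims=True)
            d_scores = att * (d_att - row_dot)   # zero off-mask since att=0 there
            # scores = m @ m.T (masked)
            d_m = d_m + (d_scores + d_scores.T) @ m
            w = self.params[f"W{layer}_{i}"]
            grads[f"W{layer}_{i}"] = h.T @ d_m
            d_h = d_h + d_m @ w.T
        return grads, d_h

    def backward(self, d_z: np.ndarray, a: np.ndarray, mask: np.ndarray, caches):
        c1, c2 = caches
        g2, d_h1 = self._layer_backward(1, d_z, a, mask, c2)
        g1, _ = self._layer_backward(0, d_h1, a, mask, c1)
        return {**g1, **g2}


def train_gae(
    atilde: NormalizedAdjacency | np.ndarray,
    features: np.ndarray,
    target_adjacency: np.ndarray,
    heads: int = 3,
    dims: tuple[int, int] = (32, 16),
    learning_rate: float = 1e-3,
    epochs: int = 200,
    seed: int = 0,
) -> GraphEmbedding:
    """Train the two-layer graph autoencoder against the cell graph.

    ``atilde`` is the normalized propagation matrix (used directly when
    heads=0 and as the neighborhood mask when heads≥1). ``target_adjacency``
    is the 0/1 adjacency (self-loops added here) the decoder reconstructs.
    Input features are standardized per column before encoding — without
    this the raw reconstruction's scale saturates the inner-product decoder
    at initialization and gradient descent kills the ReLU layer. Returns
    the final embedding with attention state and the loss trace.
    """
    a = atilde.matrix if isinstance(atilde, NormalizedAdjacency) else np.asarray(atilde, float)
    x = np.asarray(features, float)
    x = (x - x.mean(axis=0)) / np.maximum(x.std(axis=0), 1e-8)
    n = x.shape[0]
    target = (np.asarray(target_adjacency, float) > 0).astype(float)
    np.fill_diagonal(target, 1.0)
    mask = (a + np.eye(n)) > 0

    enc = _GATEncoder(x.shape[1], dims, heads, seed)
    opt = Adam(lr=learning_rate)

    h1, z, caches = enc.forward(x, a, mask)
    trace = [gae_loss(target, gae_decode(z))]
    for _ in range(epochs):
        ahat = gae_decode(z).values
        # d loss / d score where Â = sigmoid(Z Zᵀ); symmetric
        d_s = (ahat - target) / (n * n)
        d_z = 2.0 * d_s @ z
        grads = enc.backward(d_z, a, mask, caches)
        opt.step(enc.params, grads)
        h1, z, caches = enc.forward(x, a, mask)
        loss = gae_loss(target, gae_decode(z))
        if not np.isfinite(loss):
            raise FloatingPointError("graph autoencoder loss is non-finite")
        trace.append(loss)

    c1, c2 = caches
    attention = [
        [hc["att"] for hc in c["heads"]] if heads else [] for c in (c1, c2)
    ]
    return GraphEmbedding(
        Z=z,
        H1=h1,
        weights=dict(enc.params),
        attention=attention,
        n_heads=heads,
        loss_trace=np.asarray(trace),
    )


# ---------------------------------------------------------------------------
# cluster autoencoders


def train_cluster_ae(
    xhat: ReconstructedMatrix | np.ndarray,
    labels: np.ndarray,
    cfg: FeatureAEConfig,
    trs_weight: np.ndarray | float = 1.0,
    min_cluster_size: int = 10,
) -> ReconstructedMatrix:
    """Re-fit one autoencoder per cell cluster; reassemble in original order.

    Clusters smaller than ``min_cluster_size`` cannot train a meaningful
    model and are passed through unchanged (logged).
    """
    x = xhat.values if isinstance(xhat, ReconstructedMatrix) else np.asarray(xhat, float)
    labels = np.asarray(labels)
    if labels.shape[0] != x.shape[0]:
        raise ValueError("label vector length must match cell count")
    out = np.empty_like(x)
    w_full = np.broadcast_to(np.asarray(trs_weight, dtype=float), x.shape)
    for ci, lab in enumerate(np.unique(labels)):
        idx = np.nonzero(labels == lab)[0]
        if idx.size < min_cluster_size:
            logger.info("cluster %s has %d cells (< %d); passed through untrained",
                        lab, idx.size, min_cluster_size)
            out[idx] = x[idx]
            continue
        sub_cfg_seed = cfg.seed + 1000 + ci
        w = (1.0 - cfg.alpha) + cfg.alpha * w_full[idx]
        _, _, rec, _ = train_autoencoder(
            x[idx],
            [cfg.hidden_dim, cfg.latent_dim],
            weight=w,
            lr=cfg.learning_rate,
            epochs=cfg.epochs,
            seed=sub_cfg_seed,
        )
        out[idx] = rec
    return ReconstructedMatrix(values=out, source="cluster_ae")


# ---------------------------------------------------------------------------
# imputation autoencoder


def imputation_loss(
    x: np.ndarray,
    xhat: np.ndarray,
    trs_weight: np.ndarray,
    a: np.ndarray,
    b: np.ndarray,
    cfg: ImputationLossConfig,
    weights_l1: float,
    graph_mode: str = "per_cell",
) -> float:
    """Five-term imputation loss.

    (1−α)Σ(X−X̂)² + αΣ((X−X̂)²∘TRS) + βΣ|w|
    + γ1·Σ_ij A_ij‖(X−X̂)_i‖² + γ2·Σ_ij B_ij‖(X−X̂)_i‖²   (graph_mode="per_cell")

    graph_mode="pairwise" swaps the γ terms for the smoothness reading
    Σ_ij A_ij‖X̂_i−X̂_j‖² (and likewise for B).
    """
    x, xhat = np.asarray(x, float), np.asarray(xhat, float)
    if x.shape != xhat.shape:
        raise ValueError("X and X̂ shapes differ")
    b = np.asarray(b, float)
    if not np.array_equal(b, b.T) or not np.isin(b, (0.0, 1.0)).all():
        raise ValueError("B must be a symmetric 0/1 matrix")
    sq = (x - xhat) ** 2
    base = (1.0 - cfg.alpha) * sq.sum() + cfg.alpha * (sq * trs_weight).sum()
    if graph_mode == "per_cell":
        row_err = sq.sum(axis=1)
        g1 = cfg.gamma1 * float(np.asarray(a).sum(axis=1) @ row_err)
        g2 = cfg.gamma2 * float(b.sum(axis=1) @ row_err)
    elif graph_mode == "pairwise":
        def smooth(w):
            d2 = ((xhat[:, None, :] - xhat[None, :, :]) ** 2).sum(axis=2)
            return float((w * d2).sum())
        g1 = cfg.gamma1 * smooth(np.asarray(a, float))
        g2 = cfg.gamma2 * smooth(b)
    else:
        raise ValueError(f"unknown graph_mode {graph_mode!r}")
    return float(base + cfg.beta * weights_l1 + g1 + g2)


def train_imputation_ae(
    x: np.ndarray,
    a: np.ndarray,
    b: np.ndarray,
    trs_weight: np.ndarray,
    loss_cfg: ImputationLossConfig,
    ae_cfg: FeatureAEConfig,
) -> tuple[ReconstructedMatrix, np.ndarray]:
    """Train the feature architecture under the full imputation loss.

    With the per-cell reading of the graph/type regularizers the loss is an
    element-weighted squared error with per-row weight
    (1−α) + α·TRS + γ1·deg(A)_i + γ2·|cluster(i)|, plus the β L1 penalty on
    the network weights, so training reuses the weighted autoencoder core.
    Returns the reconstruction (the imputation result) and the loss trace.
    """
    x = np.asarray(x, float)
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    row_w = loss_cfg.gamma1 * a.sum(axis=1) + loss_cfg.gamma2 * b.sum(axis=1)
    w = (1.0 - loss_cfg.alpha) + loss_cfg.alpha * np.asarray(trs_weight, float) + row_w[:, None]
    _, _, rec, trace = train_autoencoder(
        x,
        [ae_cfg.hidden_dim, ae_cfg.latent_dim],
        weight=w,
        lr=ae_cfg.learning_rate,
        epochs=ae_cfg.epochs,
        seed=ae_cfg.seed,
        l1_beta=loss_cfg.beta,
    )
    return ReconstructedMatrix(values=rec, source="imputation_ae"), trace
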