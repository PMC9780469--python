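"""Run configuration for the full iterative workflow."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .networks import FeatureAEConfig, ImputationLossConfig


@dataclass
class RunConfig:
    """Every knob of the iterative pipeline in one serializable object.

    The mixing parameter ``mix`` (μ) of the adjacency update defaults to
    0.5 and the attention head count to 3, the settings under which the
    method performs best; ``heads=0`` ablates attention to plain GCN
    propagation and ``use_gae=False`` removes the graph autoencoder
    entirely (clustering then runs on the feature-autoencoder embedding).
    """

    seed: int = 0
    # preprocessing
    min_cells_frac: float = 0.01
    min_genes_per_cell: int = 200
    log_scale: float = 1e4
    n_top_genes: int = 2000
    # rank genes by raw-count sd instead of post-log sd
    rank_genes_before_log: bool = False
    # LTMG
    ltmg_k_max: int = 5
    trunc_threshold: float = 0.0
    trs_weight_mode: str = "binary"
    # cell graph
    knn_k: int | None = None
    prune_quantile: float = 0.9
    mix: float = 0.5
    # build each round's KNN graph from the feature-AE embedding (stable
    # geometry) rather than the previous round's graph embedding, whose
    # near-coincident clusters make neighbor structure noise
    knn_on_gae_embedding: bool = False
    # networks
    use_gae: bool = True
    heads: int = 3
    gae_dims: tuple[int, int] = (32, 16)
    gae_learning_rate: float = 1e-3
    gae_epochs: int = 200
    hidden_dim: int = 512
    latent_dim: int = 128
    learning_rate: float = 1e-3
    feature_epochs: int = 500
    imputation_epochs: int = 500
    alpha: float = 0.5
    beta: float = 0.5
    gamma1: float = 0.1
    gamma2: float = 0.1
    # clustering / iteration
    louvain_resolution: float = 1.0
    min_cluster_size: int = 10
    tol_adj: float = 1e-3
    tol_ari: float = 0.99
    max_rounds: int = 10

    def feature_ae_config(self, seed: int) -> FeatureAEConfig:
        return FeatureAEConfig(
            hidden_dim=self.hidden_dim,
            latent_dim=self.latent_dim,
            learning_rate=self.learning_rate,
            epochs=self.feature_epochs,
            alpha=self.alpha,
            seed=seed,
        )

    def imputation_loss_config(self) -> ImputationLossConfig:
        return ImputationLossConfig(
            alpha=self.alpha, beta=self.beta, gamma1=self.gamma1, gamma2=self.gamma2
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=list) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        if "gae_dims" in data:
            data["gae_dims"] = tuple(data["gae_dims"])
        return cls(**data)
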