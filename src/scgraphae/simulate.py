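"""Synthetic scRNA-seq count data with planted clusters and dropout.

The generator draws negative-binomial counts (gamma–Poisson mixture) around
per-cluster gene means: every gene has a baseline log-mean, and a random
subset of genes per cluster is shifted upward to create differential
expression. Technical dropout then zeroes entries with a probability that
decays logistically with the gene's underlying log-mean, mimicking the
capture inefficiency of real protocols: lowly expressed genes drop out
more. A censored Gaussian-mixture sampler is included for exercising the
LTMG fitter against a known generator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .preprocess import ExpressionMatrix, Space


@dataclass
class SimulationConfig:
    """Study conditions for the planted-cluster benchmark.

    Defaults describe a small but realistic regime: 200 cells in 3 balanced
    clusters over 300 genes, 20% of genes differentially expressed per
    cluster with a +1.5 natural-log fold change, moderate negative-binomial
    overdispersion, and logistic technical dropout centred so that weakly
    expressed genes lose roughly a third of their entries.
    """

    n_cells: int = 200
    n_genes: int = 300
    n_clusters: int = 3
    de_frac: float = 0.2
    log_mean_range: tuple[float, float] = (0.5, 2.5)
    de_log_fc: float = 1.5
    dispersion: float = 0.3
    dropout_mid: float = 0.0
    dropout_slope: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_cells, self.n_genes, self.n_clusters) <= 0:
            raise ValueError("counts must be positive")
        if self.n_clusters > self.n_cells:
            raise ValueError("more clusters than cells")
        if not 0.0 <= self.de_frac <= 1.0:
            raise ValueError("de_frac must lie in [0, 1]")


def generate_dataset(cfg: SimulationConfig):
    """Draw a counts matrix plus ground truth.

    Returns (ExpressionMatrix in raw counts, truth dict with ``labels``
    (per-cell cluster), ``true_log_means`` (clusters × genes), and
    ``dropout_mask`` (entries zeroed by technical dropout that were
    non-zero before)). Fully deterministic from cfg.seed.
    """
    rng = np.random.default_rng(cfg.seed)
    n, g, k = cfg.n_cells, cfg.n_genes, cfg.n_clusters
    if k > 1 and round(cfg.de_frac * g) == 0:
        warnings.warn("de_frac yields 0 DE genes; clusters will be indistinguishable")

    labels = np.arange(n) % k  # balanced assignment
    base = rng.uniform(*cfg.log_mean_range, size=g)
    log_means = np.tile(base, (k, 1))
    n_de = round(cfg.de_frac * g)
    for c in range(k):
        de_genes = rng.choice(g, size=n_de, replace=False)
        log_means[c, de_genes] += cfg.de_log_fc

    mu = np.exp(log_means[labels])  # cells × genes
    if cfg.dispersion > 0:
        lam = rng.gamma(shape=1.0 / cfg.dispersion, scale=mu * cfg.dispersion)
    else:
        lam = mu
    counts = rng.poisson(lam).astype(float)

    # logistic technical dropout keyed to the true underlying log-mean
    logit = cfg.dropout_mid - cfg.dropout_slope * log_means[labels]
    p_drop = 1.0 / (1.0 + np.exp(-logit))
    dropped = rng.random((n, g)) < p_drop
    dropout_mask = dropped & (counts > 0)
    counts[dropped] = 0.0

    m = ExpressionMatrix(
        values=counts,
        cell_ids=[f"cell{i}" for i in range(n)],
        gene_ids=[f"gene{j}" for j in range(g)],
        space=Space.RAW_COUNTS,
    )
    truth = {"labels": labels, "true_log_means": log_means, "dropout_mask": dropout_mask}
    return m, truth


def generate_censored_mixture(
    n: int,
    weights,
    means,
    sds,
    censor_at: float = -np.inf,
    seed: int = 0,
):
    """Sample a Gaussian mixture and left-censor at a threshold.

    Values at or below ``censor_at`` are recorded as ``censor_at`` itself
    (the observable), while the uncensored draws are returned as truth.
    Returns (observed vector, dict with ``uncensored`` draws and
    ``components``).
    """
    weights = np.asarray(weights, dtype=float)
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError("mixture weights must sum to 1")
    rng = np.random.default_rng(seed)
    comp = rng.choice(len(weights), size=n, p=weights)
    raw = rng.normal(np.asarray(means, float)[comp], np.asarray(sds, float)[comp])
    observed = np.where(raw <= censor_at, censor_at, raw)
    return observed, {"uncensored": raw, "components": comp}
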