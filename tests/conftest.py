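"""Shared fixtures: simulated datasets and preprocessed inputs.

Everything is generated programmatically at session scope so that the
expensive pieces (LTMG fits on 300 genes) run once per session.
"""

from __future__ import annotations

import numpy as np
import pytest

from scgraphae import (
    RunConfig,
    SimulationConfig,
    assign_trs,
    filter_low_expression,
    fit_all_genes,
    generate_dataset,
    log_normalize,
    select_top_variance_genes,
)


@pytest.fixture(scope="session")
def default_dataset():
    """The planted 3-cluster study dataset (200 cells × 300 genes)."""
    cfg = SimulationConfig(seed=1)
    m, truth = generate_dataset(cfg)
    return m, truth


@pytest.fixture(scope="session")
def preprocessed(default_dataset):
    """Filtered, log-normalized, variance-selected matrix plus LTMG TRS."""
    m, truth = default_dataset
    filt = filter_low_expression(m, min_cells_frac=0.01, min_genes_per_cell=10)
    norm = log_normalize(filt)
    top = select_top_variance_genes(norm, 2000)
    assert top.n_cells == m.n_cells, "fixture assumes no cell is filtered"
    fits = fit_all_genes(top, k_max=5, trunc_threshold=0.0)
    trs = assign_trs(top, fits)
    return top, fits, trs, truth


@pytest.fixture(scope="session")
def fast_run_config():
    """Scaled-down training schedule used by end-to-end tests.

    The architecture and study conditions are the defaults; only training
    lengths are shortened to keep the suite quick.
    """
    return RunConfig(
        seed=1,
        feature_epochs=200,
        gae_epochs=100,
        imputation_epochs=300,
        max_rounds=10,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
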