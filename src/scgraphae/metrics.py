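"""Evaluation metrics and the synthetic-dropout benchmark protocol.

Imputation quality is scored on deliberately zeroed ("flipped") entries:
per-entry absolute deviation (L1 mean/median/max), per-cell cosine
similarity, and RMSE. Clustering quality is scored against labels with the
pair-counting indices (Rand-adjusted ARI, Fowlkes–Mallows), the
information-theoretic family (MI, NMI, AMI with the hypergeometric expected
MI, homogeneity/completeness/V-measure), and the label-free geometry scores
(silhouette, Davies–Bouldin).

All scores are computed from first principles (contingency tables, entropy
sums, pairwise distances); no external metric implementation is called.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import gammaln

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# synthetic dropout


@dataclass
class DropoutMask:
    """Positions flipped to zero for the recovery benchmark."""

    flipped_indices: np.ndarray  # (m, 2) array of (cell, gene)
    rate: float
    seed: int


def apply_synthetic_dropout(
    x: np.ndarray, rate: float, seed: int
) -> tuple[np.ndarray, DropoutMask]:
    """Flip round(rate · nnz) uniformly chosen non-zero entries to zero."""
    x = np.asarray(x, dtype=float)
    if not 0.0 < rate < 1.0:
        raise ValueError("rate must lie in (0, 1)")
    nz = np.argwhere(x != 0)
    n_flip = round(rate * len(nz))
    if n_flip == 0:
        raise ValueError("rate too small: no entries would be flipped")
    rng = np.random.default_rng(seed)
    chosen = nz[rng.choice(len(nz), size=n_flip, replace=False)]
    corrupted = x.copy()
    corrupted[chosen[:, 0], chosen[:, 1]] = 0.0
    return corrupted, DropoutMask(flipped_indices=chosen, rate=rate, seed=seed)


# ---------------------------------------------------------------------------
# imputation metrics


def imputation_metrics(
    original: np.ndarray,
    imputed: np.ndarray,
    mask: DropoutMask | None = None,
    scope: str = "masked_only",
    axis: str = "cells",
) -> dict[str, float]:
    """L1 statistics, per-row cosine similarity, and RMSE.

    scope="masked_only" (the benchmark default) restricts every statistic
    to the flipped positions; scope="all" uses the whole matrix. Cosine is
    averaged over rows — cells by default, genes with axis="genes"; rows
    where either vector has zero norm are skipped (if every row is skipped
    the cosine is reported as 0).
    """
    x = np.asarray(original, dtype=float)
    y = np.asarray(imputed, dtype=float)
    if x.shape != y.shape:
        raise ValueError("original and imputed shapes differ")
    if axis == "genes":
        x, y = x.T, y.T
        if mask is not None:
            mask = DropoutMask(
                flipped_indices=mask.flipped_indices[:, ::-1],
                rate=mask.rate,
                seed=mask.seed,
            )
    elif axis != "cells":
        raise ValueError(f"unknown axis {axis!r}")
    if scope == "masked_only":
        if mask is None:
            raise ValueError("masked_only scope requires a DropoutMask")
        sel = np.zeros(x.shape, dtype=bool)
        sel[mask.flipped_indices[:, 0], mask.flipped_indices[:, 1]] = True
    elif scope == "all":
        sel = np.ones(x.shape, dtype=bool)
    else:
        raise ValueError(f"unknown scope {scope!r}")

    diffs = np.abs(x - y)[sel]
    out = {
        "l1_mean": float(diffs.mean()),
        "l1_median": float(np.median(diffs)),
        "l1_max": float(diffs.max()),
        "rmse": float(np.sqrt(((x - y)[sel] ** 2).mean())),
    }

    cosines = []
    skipped = 0
    for i in range(x.shape[0]):
        cols = sel[i]
        if not cols.any():
            continue
        xi, yi = x[i, cols], y[i, cols]
        nx, ny = np.linalg.norm(xi), np.linalg.norm(yi)
        if nx == 0 or ny == 0:
            skipped += 1
            continue
        cosines.append(float(xi @ yi / (nx * ny)))
    if skipped:
        logger.info("cosine: skipped %d zero-norm rows", skipped)
    out["cosine"] = float(np.mean(cosines)) if cosines else 0.0
    return out


# ---------------------------------------------------------------------------
# partition-comparison helpers


def _contingency(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if a.size != b.size:
        raise ValueError("label vectors differ in length")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    table = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(table, (ai, bi), 1)
    return table


def _comb2(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v * (v - 1) / 2.0


def ari(true_labels, pred_labels) -> float:
    """Adjusted Rand index via the contingency-table formulation.

    ARI = (RI − E[RI]) / (max(RI) − E[RI]); 1 for identical partitions up
    to relabeling, ≈0 for independent ones. Degenerate pairs (both
    partitions all-singletons or both single-cluster) score 1.
    """
    t = _contingency(true_labels, pred_labels)
    n = t.sum()
    if n < 2:
        raise ValueError("need at least 2 samples")
    sum_nij = _comb2(t).sum()
    sum_a = _comb2(t.sum(axis=1)).sum()
    sum_b = _comb2(t.sum(axis=0)).sum()
    expected = sum_a * sum_b / _comb2(np.array(n)).item()
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0
    return float((sum_nij - expected) / (max_index - expected))


def _entropy(counts: np.ndarray) -> float:
    counts = counts[counts > 0].astype(float)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def _mutual_information(t: np.ndarray) -> float:
    n = t.sum()
    a = t.sum(axis=1, keepdims=True)
    b = t.sum(axis=0, keepdims=True)
    nz = t > 0
    tij = t[nz].astype(float)
    outer = (a @ b)[nz].astype(float)
    return float((tij / n * (np.log(tij * n) - np.log(outer))).sum())


def _expected_mi(t: np.ndarray) -> float:
    """Expected MI of a random contingency table with fixed margins."""
    n = int(t.sum())
    a = t.sum(axis=1).astype(int)
    b = t.sum(axis=0).astype(int)
    emi = 0.0
    lg = gammaln
    for ai in a:
        for bj in b:
            lo = max(1, ai + bj - n)
            hi = min(ai, bj)
            for nij in range(lo, hi + 1):
                term1 = nij / n * np.log(n * nij / (ai * bj))
                logp = (
                    lg(ai + 1) + lg(bj + 1) + lg(n - ai + 1) + lg(n - bj + 1)
                    - lg(n + 1) - lg(nij + 1) - lg(ai - nij + 1)
                    - lg(bj - nij + 1) - lg(n - ai - bj + nij + 1)
                )
                emi += term1 * np.exp(logp)
    return float(emi)


def information_scores(true_labels, pred_labels) -> dict[str, float]:
    """AMI, NMI, completeness, V-measure, and homogeneity.

    NMI and AMI use the mean-entropy normalization; AMI subtracts the
    hypergeometric expected MI. Homogeneity = 1 − H(true|pred)/H(true)
    (each cluster holds one class), completeness = 1 − H(pred|true)/H(pred)
    (each class stays in one cluster); V-measure is their harmonic mean.
    Degenerate zero-entropy cases follow the usual conventions (a score of
    1 when the corresponding requirement is vacuously met).
    """
    t = _contingency(true_labels, pred_labels)
    n = t.sum()
    h_true = _entropy(t.sum(axis=1))
    h_pred = _entropy(t.sum(axis=0))
    mi = _mutual_information(t)

    # conditional entropies from the joint table
    pij = t.astype(float) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        # H(true|pred) = -sum pij log(pij / p_pred_j)
        p_pred = pij.sum(axis=0, keepdims=True)
        p_true = pij.sum(axis=1, keepdims=True)
        nz = pij > 0
        h_true_given_pred = float(-(pij[nz] * (np.log(pij) - np.log(p_pred * np.ones_like(pij)))[nz]).sum())
        h_pred_given_true = float(-(pij[nz] * (np.log(pij) - np.log(p_true * np.ones_like(pij)))[nz]).sum())

    hs = 1.0 if h_true == 0 else 1.0 - h_true_given_pred / h_true
    cs = 1.0 if h_pred == 0 else 1.0 - h_pred_given_true / h_pred
    vms = 0.0 if (hs + cs) == 0 else 2.0 * hs * cs / (hs + cs)

    mean_h = 0.5 * (h_true + h_pred)
    nmi = 1.0 if mean_h == 0 else mi / mean_h

    if mean_h == 0:
        ami = 1.0
    else:
        emi = _expected_mi(t)
        denom = mean_h - emi
        ami = 1.0 if denom == 0 else (mi - emi) / denom

    return {"ami": float(ami), "nmi": float(nmi), "cs": float(cs),
            "vms": float(vms), "hs": float(hs)}


def fowlkes_mallows(true_labels, pred_labels) -> float:
    """Geometric mean of pairwise precision and recall, in [0, 1]."""
    t = _contingency(true_labels, pred_labels)
    tp = _comb2(t).sum()
    pairs_true = _comb2(t.sum(axis=1)).sum()
    pairs_pred = _comb2(t.sum(axis=0)).sum()
    if pairs_true == 0 or pairs_pred == 0:
        return 0.0
    return float(tp / np.sqrt(pairs_true * pairs_pred))


# ---------------------------------------------------------------------------
# geometry scores


def geometry_scores(x: np.ndarray, labels) -> dict[str, float]:
    """Mean silhouette coefficient and Davies–Bouldin score (Euclidean).

    Silhouette per object: s = (b − a)/max(a, b) with a the mean distance
    to its own cluster (excluding itself) and b the smallest mean distance
    to another cluster; singletons (and a = b = 0 ties) score 0.
    Davies–Bouldin: mean over clusters of the worst (S_i + S_j)/M_ij ratio,
    S the mean member–centroid distance, M the centroid distance.
    """
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels).ravel()
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("geometry scores need at least 2 clusters")
    d = cdist(x, x)
    n = x.shape[0]
    members = {c: np.nonzero(labels == c)[0] for c in uniq}

    sil = np.zeros(n)
    for i in range(n):
        own = members[labels[i]]
        if own.size <= 1:
            sil[i] = 0.0
            continue
        a = d[i, own[own != i]].mean()
        b = min(d[i, members[c]].mean() for c in uniq if c != labels[i])
        m = max(a, b)
        sil[i] = 0.0 if m == 0 else (b - a) / m

    centroids = np.vstack([x[members[c]].mean(axis=0) for c in uniq])
    scatter = np.array([
        np.linalg.norm(x[members[c]] - centroids[k], axis=1).mean()
        for k, c in enumerate(uniq)
    ])
    cd = cdist(centroids, centroids)
    k = uniq.size
    ratios = np.zeros(k)
    for i in range(k):
        cand = [
            (scatter[i] + scatter[j]) / cd[i, j]
            for j in range(k)
            if j != i and cd[i, j] > 0
        ]
        ratios[i] = max(cand) if cand else 0.0  # coincident centroids, zero scatter
    return {"silhouette": float(sil.mean()), "dbs": float(ratios.mean())}


def clustering_report(true_labels, pred_labels, embedding: np.ndarray | None = None) -> dict[str, float]:
    """All clustering scores in one dict (geometry scores need an embedding)."""
    out = {"ari": ari(true_labels, pred_labels),
           "fms": fowlkes_mallows(true_labels, pred_labels)}
    out.update(information_scores(true_labels, pred_labels))
    if embedding is not None and np.unique(pred_labels).size >= 2:
        out.update(geometry_scores(embedding, pred_labels))
    return out
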