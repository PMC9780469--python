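"""Left-truncated mixed Gaussian (LTMG) model for per-gene expression.

Each gene's log-normalized expression across cells is modeled as a k-component
Gaussian mixture in which observations at or below a truncation threshold
(``zcut``, by default 0, i.e. zeros in log space) are treated as left-censored:
their likelihood contribution is the mixture mass below the threshold rather
than a density value. EM with truncated-normal conditional moments maximizes
the censored-data likelihood; BIC selects the component count. The discrete
component label of each observation is its transcriptional regulatory signal
(TRS), which downstream losses use as a per-entry weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import log_ndtr, ndtr

from .preprocess import ExpressionMatrix

SIGMA_FLOOR = 1e-3

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def _norm_pdf(x, mu, sd):
    z = (x - mu) / sd
    return np.exp(-0.5 * z * z) / (sd * np.sqrt(2.0 * np.pi))


def _norm_logpdf(x, mu, sd):
    z = (x - mu) / sd
    return -0.5 * z * z - np.log(sd) - _LOG_SQRT_2PI


@dataclass
class LTMGFit:
    """Fitted truncated-mixture parameters for one gene.

    Components are sorted by ascending mean. ``degenerate`` marks fits where
    no (or almost no) uncensored data was available and the parameters are
    a fallback rather than a maximum-likelihood estimate.
    """

    n_components: int
    mixing_probs: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    trunc_threshold: float
    loglik: float
    bic: float = np.nan
    n_iter: int = 0
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.mixing_probs = np.asarray(self.mixing_probs, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if not np.isclose(self.mixing_probs.sum(), 1.0, atol=1e-8):
            raise ValueError("mixing probabilities must sum to 1")
        if np.any(self.sds <= 0):
            raise ValueError("component sds must be positive")


@dataclass
class TRSMatrix:
    """Per-entry mixture-component labels (1..k per gene), cells × genes."""

    labels: np.ndarray  # int matrix, N × G

    def weight_matrix(self, mode: str = "binary") -> np.ndarray:
        """Turn labels into a loss weight matrix.

        mode="binary": weight 1 where the entry sits above the lowest
        (censored/low-expression) component, else 0. mode="label": the raw
        integer label. The binary reading treats the regularizer as "count
        the error only where the gene is actually on".
        """
        if mode == "binary":
            return (self.labels > 1).astype(float)
        if mode == "label":
            return self.labels.astype(float)
        raise ValueError(f"unknown TRS weight mode {mode!r}")


def _censored_moments(zcut: float, mu: np.ndarray, sd: np.ndarray):
    """First/second moments of N(mu, sd^2) conditioned on X <= zcut."""
    beta = (zcut - mu) / sd
    logphi = _norm_logpdf(beta, 0.0, 1.0)
    logPhi = log_ndtr(beta)
    lam = np.exp(logphi - logPhi)  # hazard-like ratio phi/Phi
    m1 = mu - sd * lam
    var = sd**2 * (1.0 - beta * lam - lam**2)
    var = np.maximum(var, 0.0)
    m2 = var + m1**2
    return m1, m2


def fit_ltmg_gene(
    x: np.ndarray,
    k: int,
    trunc_threshold: float = 0.0,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> LTMGFit:
    """Fit a k-component left-censored Gaussian mixture to one gene by EM.

    Values at or below ``trunc_threshold`` contribute the mixture CDF mass
    below the threshold to the likelihood; observed values contribute the
    mixture density. Convergence on relative log-likelihood change < tol.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 observations per gene")
    if k < 1:
        raise ValueError("k must be >= 1")
    zcut = float(trunc_threshold)
    censored = x <= zcut
    obs = x[~censored]
    n_cens = int(censored.sum())

    if obs.size == 0:
        # no uncensored data: fall back to a unit component below the cut
        fit = LTMGFit(
            n_components=1,
            mixing_probs=np.array([1.0]),
            means=np.array([zcut - 1.0]),
            sds=np.array([1.0]),
            trunc_threshold=zcut,
            loglik=0.0,
            degenerate=True,
        )
        return fit

    if k > np.unique(obs).size:
        raise ValueError(
            f"k={k} exceeds the {np.unique(obs).size} distinct uncensored values"
        )

    # deterministic init: quantile-spaced means, pooled sd, uniform weights
    qs = (np.arange(k) + 0.5) / k
    mu = np.quantile(obs, qs)
    sd = np.full(k, max(obs.std(ddof=0), SIGMA_FLOOR))
    alpha = np.full(k, 1.0 / k)

    def loglik_fn(alpha, mu, sd):
        ll = 0.0
        if obs.size:
            dens = alpha[None, :] * _norm_pdf(obs[:, None], mu[None, :], sd[None, :])
            ll += np.log(np.maximum(dens.sum(axis=1), 1e-300)).sum()
        if n_cens:
            mass = (alpha * ndtr((zcut - mu) / sd)).sum()
            ll += n_cens * np.log(max(mass, 1e-300))
        return ll

    trace = [loglik_fn(alpha, mu, sd)]
    for it in range(1, max_iter + 1):
        # E-step
        dens = alpha[None, :] * _norm_pdf(obs[:, None], mu[None, :], sd[None, :])
        dens_sum = np.maximum(dens.sum(axis=1, keepdims=True), 1e-300)
        r_obs = dens / dens_sum  # M × k
        if n_cens:
            mass_k = alpha * ndtr((zcut - mu) / sd)
            mass_k = np.maximum(mass_k, 1e-300)
            r_cens = mass_k / mass_k.sum()  # shared by all censored entries
            m1, m2 = _censored_moments(zcut, mu, sd)
        else:
            r_cens = np.zeros(k)
            m1 = m2 = np.zeros(k)

        # M-step (censored entries enter via their truncated moments)
        nk = r_obs.sum(axis=0) + n_cens * r_cens
        nk = np.maximum(nk, 1e-12)
        mu_new = (r_obs.T @ obs + n_cens * r_cens * m1) / nk
        sq_obs = r_obs.T @ obs**2
        sq_cens = n_cens * r_cens * m2
        ex2 = (sq_obs + sq_cens) / nk
        var = ex2 - 2 * mu_new * ((r_obs.T @ obs + n_cens * r_cens * m1) / nk) + mu_new**2
        sd_new = np.sqrt(np.maximum(var, SIGMA_FLOOR**2))
        alpha_new = nk / n

        alpha, mu, sd = alpha_new, mu_new, sd_new
        trace.append(loglik_fn(alpha, mu, sd))
        denom = max(abs(trace[-2]), 1.0)
        if abs(trace[-1] - trace[-2]) / denom < tol:
            break

    order = np.argsort(mu, kind="stable")
    return LTMGFit(
        n_components=k,
        mixing_probs=alpha[order] / alpha.sum(),
        means=mu[order],
        sds=sd[order],
        trunc_threshold=zcut,
        loglik=trace[-1],
        n_iter=it,
        loglik_trace=np.asarray(trace),
    )


def select_components(
    x: np.ndarray,
    k_max: int = 5,
    trunc_threshold: float = 0.0,
    **fit_kwargs,
) -> LTMGFit:
    """Fit k = 1..k_max and return the fit minimizing BIC.

    BIC = -2 loglik + p log(M), with p = 3k - 1 free parameters and M the
    number of uncensored observations.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    x = np.asarray(x, dtype=float).ravel()
    m_uncens = int((x > trunc_threshold).sum())
    best: LTMGFit | None = None
    last_err: Exception | None = None
    for k in range(1, k_max + 1):
        try:
            fit = fit_ltmg_gene(x, k, trunc_threshold, **fit_kwargs)
        except ValueError as exc:
            last_err = exc
            continue
        p = 3 * k - 1
        fit.bic = -2.0 * fit.loglik + p * np.log(max(m_uncens, 1))
        if fit.degenerate:
            return fit
        if best is None or fit.bic < best.bic:
            best = fit
    if best is None:
        raise ValueError(f"no component count in 1..{k_max} could be fitted: {last_err}")
    return best


def assign_trs(m: ExpressionMatrix, fits: list[LTMGFit]) -> TRSMatrix:
    """Label every entry with its most likely mixture component (1..k).

    The label maximizes the component posterior α_i φ(x; μ_i, σ_i); ties go
    to the lower-mean component (components are mean-sorted, argmax takes
    the first maximum).
    """
    if len(fits) != m.n_genes:
        raise ValueError(f"{len(fits)} fits for {m.n_genes} genes")
    labels = np.ones(m.values.shape, dtype=int)
    for g, fit in enumerate(fits):
        if fit is None:
            raise ValueError(f"missing LTMG fit for gene {m.gene_ids[g]!r}")
        if fit.n_components == 1:
            continue
        x = m.values[:, g][:, None]
        # log-domain scores avoid underflow far in the tails
        score = np.log(fit.mixing_probs)[None, :] + _norm_logpdf(
            x, fit.means[None, :], fit.sds[None, :]
        )
        labels[:, g] = np.argmax(score, axis=1) + 1
    return TRSMatrix(labels=labels)


def fit_all_genes(
    m: ExpressionMatrix,
    k_max: int = 5,
    trunc_threshold: float = 0.0,
    **fit_kwargs,
) -> list[LTMGFit]:
    """BIC-select and fit the censored mixture for every gene of ``m``."""
    return [
        select_components(m.values[:, g], k_max, trunc_threshold, **fit_kwargs)
        for g in range(m.n_genes)
    ]
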