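"""Stochastic EM for the zero-censored Gaussian mixture (mass cytometry).

CyTOF intensities are zero-inflated: the model reads an observed zero as a
latent Gaussian intensity z_{nk} <= 0 censored at the detection floor,
y = max(z, 0) coordinate-wise.  The stochastic E-step replaces conditional
expectations by Monte Carlo draws:

* labels  w~_n ~ Categorical(eta_n), eta_{nl} ∝ phi_{nl} N(z~_n | mu_l, Sigma_l);
* latents z~_{nk}: observed coordinates are copied through; each censored
  coordinate is drawn from its Gaussian full conditional (given the row's
  other coordinates) truncated to (-inf, 0], by inverse-CDF — one Gibbs
  sweep over coordinates per iteration by default.

The M-step then reuses the flow-model updates on (z~, w~).  A point estimate
is the average of the post-burn-in M-step outputs, and the modal sampled
label over kept iterations gives the hard assignment used for SSE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import log_ndtr, ndtri
from scipy.stats import norm

from . import flow
from .types import (
    DesignMatrix,
    FitResult,
    Hyperparams,
    LatentState,
    MarkerMatrix,
    MixtureWeights,
    ModelParams,
    ValidationError,
    compute_phi,
    ensure_spd,
)

logger = logging.getLogger(__name__)


@dataclass
class SEMOptions:
    """Stochastic-EM run length: burn-in iterations discarded, kept
    iterations averaged, and Gibbs sweeps per E-step."""

    burn_in: int = 100
    n_keep: int = 100
    n_gibbs: int = 1


def sample_labels(
    z: np.ndarray,
    phi: MixtureWeights,
    params: ModelParams,
    rng: np.random.Generator,
) -> LatentState:
    """Draw one-hot labels w~_n ~ Categorical(eta_n) with
    eta_{nl} ∝ phi_{nl} N(z_n | mu_l, Sigma_l), computed in log-space.

    A row whose eta underflows to all-zero falls back to sampling from phi_n.
    """
    logdens = flow._log_gauss_densities(z, params.mu, params.sigma)
    with np.errstate(divide="ignore"):
        logeta = logdens + np.log(phi.phi)
    logeta -= logeta.max(axis=1, keepdims=True)
    eta = np.exp(logeta)
    sums = eta.sum(axis=1)
    bad = ~np.isfinite(sums) | (sums <= 0)
    if np.any(bad):
        eta[bad] = phi.phi[bad]
        sums[bad] = eta[bad].sum(axis=1)
    eta /= sums[:, None]
    # inverse-CDF categorical draw, vectorised over cells
    u = rng.random(eta.shape[0])
    labels = (eta.cumsum(axis=1) < u[:, None]).sum(axis=1)
    labels = np.minimum(labels, eta.shape[1] - 1)
    w = np.zeros_like(eta)
    w[np.arange(eta.shape[0]), labels] = 1.0
    return LatentState(w=w, z=z)


def conditional_params(
    mu_row: np.ndarray, sigma: np.ndarray, z_row: np.ndarray, k: int
) -> tuple[float, float]:
    """Gaussian full conditional of coordinate k given the others:

    mean = mu_k + Sigma_{k,-k} Sigma_{-k,-k}^{-1} (z_{-k} - mu_{-k}),
    var  = Sigma_{kk} - Sigma_{k,-k} Sigma_{-k,-k}^{-1} Sigma_{-k,k}.
    """
    mu_row = np.asarray(mu_row, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    z_row = np.asarray(z_row, dtype=float)
    K = mu_row.shape[0]
    if K == 1:
        return float(mu_row[0]), float(sigma[0, 0])
    idx = np.delete(np.arange(K), k)
    s_kk = sigma[k, k]
    s_ko = sigma[k, idx]
    s_oo = sigma[np.ix_(idx, idx)]
    try:
        coef = np.linalg.solve(s_oo, s_ko)
    except np.linalg.LinAlgError:
        coef = np.linalg.solve(ensure_spd(s_oo, 1e-8), s_ko)
    mean = mu_row[k] + coef @ (z_row[idx] - mu_row[idx])
    var = s_kk - coef @ s_ko
    return float(mean), float(max(var, 1e-12))


def _conditional_coefs(sigma: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-coordinate regression coefficients and conditional variances for
    one cluster covariance; used to vectorise the Gibbs sweep over cells."""
    K = sigma.shape[0]
    coefs = np.zeros((K, K))  # row k: weights on z_{-k}-mu_{-k} (0 at k)
    cvars = np.empty(K)
    for k in range(K):
        if K == 1:
            cvars[0] = sigma[0, 0]
            continue
        idx = np.delete(np.arange(K), k)
        s_oo = sigma[np.ix_(idx, idx)]
        s_ko = sigma[k, idx]
        try:
            c = np.linalg.solve(s_oo, s_ko)
        except np.linalg.LinAlgError:
            c = np.linalg.solve(ensure_spd(s_oo, 1e-8), s_ko)
        coefs[k, idx] = c
        cvars[k] = max(sigma[k, k] - c @ s_ko, 1e-12)
    return coefs, cvars


def truncated_normal_below(
    mean: np.ndarray, sd: np.ndarray, bound: float, rng: np.random.Generator
) -> np.ndarray:
    """Inverse-CDF draws from N(mean, sd^2) truncated to (-inf, bound].

    Uses z = mean + sd * Phi^{-1}(u * b) with b = Phi((bound-mean)/sd).
    When b underflows (essentially no mass below the bound) the draw is
    clamped to just below the bound.
    """
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    alpha = (bound - mean) / sd
    # log-space u*b = exp(log u + log Phi(alpha)) survives b underflow
    logu = np.log(rng.random(mean.shape))
    logub = logu + log_ndtr(alpha)
    with np.errstate(over="ignore"):
        draws = mean + sd * ndtri(np.exp(logub))
    bad = ~np.isfinite(draws)
    if np.any(bad):
        draws[bad] = bound - 1e-10
    over = draws > bound
    if np.any(over):
        draws[over] = bound - 1e-10
    return draws


def sample_latents(
    Y: MarkerMatrix,
    w_onehot: np.ndarray,
    params: ModelParams,
    z_prev: np.ndarray,
    rng: np.random.Generator,
    n_sweeps: int = 1,
) -> np.ndarray:
    """One (or more) Gibbs sweep over coordinates refreshing censored latents.

    Observed coordinates (y > 0) pass through unchanged.  Each censored
    coordinate is redrawn from its truncated full conditional given the
    row's current other coordinates; coordinates are visited in index order.
    """
    yv = Y.values
    z = z_prev.copy()
    z[yv > 0] = yv[yv > 0]
    labels = np.argmax(w_onehot, axis=1)
    K = yv.shape[1]
    L = params.n_clusters
    censored = yv <= 0
    for _ in range(n_sweeps):
        for l in range(L):
            rows = np.nonzero(labels == l)[0]
            if rows.size == 0:
                continue
            coefs, cvars = _conditional_coefs(params.sigma[l])
            mu = params.mu[:, l]
            sds = np.sqrt(cvars)
            for k in range(K):
                cells = rows[censored[rows, k]]
                if cells.size == 0:
                    continue
                centered = z[cells] - mu  # uses current sweep state
                means = mu[k] + centered @ coefs[k]
                z[cells, k] = truncated_normal_below(means, sds[k], 0.0, rng)
    return z


def fit_mass(
    Y: MarkerMatrix,
    X: DesignMatrix,
    L: int,
    hyper: Hyperparams | None = None,
    opts: SEMOptions | None = None,
    seed: int = 0,
) -> FitResult:
    """Fit the censored-Gaussian model by stochastic EM.

    Iterates {sample labels -> Gibbs-refresh latents -> M-step}; after
    ``burn_in`` iterations the M-step outputs are averaged over ``n_keep``
    further iterations (a Rao-Blackwellised point estimate).  The returned
    latent state carries post-burn-in label frequencies (modal label =
    hard assignment) and the final latent draw.  ``loglik`` is the Gaussian
    log-likelihood of the final latent draw under the averaged parameters —
    the exact censored observed-data likelihood is integrals over orthants
    and is intentionally not computed.
    """
    if not Y.is_censored:
        raise ValidationError("fit_mass requires a censored MarkerMatrix")
    if X.n_rows != Y.n_cells:
        raise ValidationError("design matrix row count does not match cells")
    hyper = hyper or Hyperparams.default(Y.n_markers)
    opts = opts or SEMOptions()
    rng = np.random.default_rng(seed)

    w = flow.kmeans_init(Y, L, seed)
    z = Y.values.copy()
    z[z <= 0] = -0.1
    beta = np.zeros((X.n_covariates, L))
    zM = MarkerMatrix(z, Y.marker_names, is_censored=False)
    mu = flow.update_means(zM, w, hyper.tau)
    sigma = flow.update_covariances(zM, w, mu, hyper)
    beta = flow.optimize_beta(beta, w, X)
    params = ModelParams(mu, sigma, beta)

    n_total = opts.burn_in + opts.n_keep
    mu_acc = np.zeros_like(mu)
    sigma_acc = np.zeros_like(sigma)
    beta_acc = np.zeros_like(beta)
    label_counts = np.zeros((Y.n_cells, L))
    trace: list[float] = []
    kept = 0
    for it in range(n_total):
        phi = compute_phi(X, params.beta)
        state = sample_labels(z, phi, params, rng)
        z = sample_latents(Y, state.w, params, z, rng, n_sweeps=opts.n_gibbs)
        zM = MarkerMatrix(z, Y.marker_names, is_censored=False)
        mu = flow.update_means(zM, state.w, hyper.tau)
        sigma = flow.update_covariances(zM, state.w, mu, hyper)
        beta = flow.optimize_beta(params.beta, state.w, X)
        params = ModelParams(mu, sigma, beta)
        trace.append(flow.map_objective(zM, X, params, hyper))
        if it >= opts.burn_in:
            mu_acc += mu
            sigma_acc += sigma
            beta_acc += beta
            label_counts += state.w
            kept += 1

    avg = ModelParams(mu_acc / kept, sigma_acc / kept, beta_acc / kept)
    freq = label_counts / kept
    latent = LatentState(w=freq, z=z)
    zM = MarkerMatrix(z, Y.marker_names, is_censored=False)
    return FitResult(
        params=avg,
        latent=latent,
        weights=compute_phi(X, avg.beta),
        objective_trace=trace,
        loglik=flow.log_likelihood(zM, X, avg),
        n_iter=n_total,
        converged=True,
        seed=seed,
    )


def fitted_cell_means(fit: FitResult) -> np.ndarray:
    """Per-cell fitted intensities: the assigned (modal) cluster's mean,
    rectified at zero — the ingredient of the SSE elbow criterion."""
    labels = fit.latent.hard_labels
    return np.maximum(0.0, fit.params.mu[:, labels].T)
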