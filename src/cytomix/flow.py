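"""MAP EM for the covariate-dependent Gaussian mixture (flow cytometry).

The observed-data model is y_n | w_n=l ~ N(mu_l, Sigma_l) with
P(w_n = l | x_n) = softmax(x_n beta)_l.  Maximum-a-posteriori estimation
under the conjugate priors mu_l ~ N(0, Sigma_l/tau),
Sigma_l^{-1} ~ Wishart(nu, Lambda) alternates:

* E-step: responsibilities w_{nl} proportional to phi_{nl} N(y_n|mu_l,Sigma_l),
  evaluated in log-space;
* M-step: closed-form shrinkage updates for mu_l and Sigma_l, and a damped
  Newton ascent on the multinomial-logit objective Q(beta) for beta.

The mu update mu_l = sum_n w_{nl} y_n / (sum_n w_{nl} + tau) is optimal for
every Sigma (the prior and likelihood Sigma factors cancel), so the
coordinate updates jointly maximise the expected complete-data posterior and
the MAP objective is nondecreasing across iterations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import logsumexp
from sklearn.cluster import KMeans

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
class EMOptions:
    """Knobs for the EM loop: relative-change tolerance on the MAP objective,
    iteration cap, and Newton step-halving depth."""

    tol: float = 1e-6
    max_iter: int = 500
    newton_max_iter: int = 25
    newton_tol: float = 1e-8
    max_halvings: int = 20


def _log_gauss_densities(Y: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """N x L matrix of log N(y_n | mu_l, Sigma_l), via Cholesky factors."""
    n, k = Y.shape
    L = mu.shape[1]
    out = np.empty((n, L))
    for l in range(L):
        sig = ensure_spd(sigma[l])
        chol, lower = cho_factor(sig, lower=True)
        diff = Y - mu[:, l]
        solved = cho_solve((chol, lower), diff.T)
        maha = np.einsum("kn,kn->n", diff.T, solved)
        logdet = 2.0 * np.sum(np.log(np.diag(chol)))
        out[:, l] = -0.5 * (k * np.log(2.0 * np.pi) + logdet + maha)
    return out


def e_step(Y: MarkerMatrix, params: ModelParams, phi: MixtureWeights) -> LatentState:
    """Posterior responsibilities w_{nl} ∝ phi_{nl} N(y_n | mu_l, Sigma_l).

    Computed as log phi + log density followed by log-sum-exp normalisation.
    """
    logdens = _log_gauss_densities(Y.values, params.mu, params.sigma)
    with np.errstate(divide="ignore"):
        logpost = logdens + np.log(phi.phi)
    logpost -= logsumexp(logpost, axis=1, keepdims=True)
    return LatentState(w=np.exp(logpost))


def update_means(Y: MarkerMatrix, w: np.ndarray, tau: float) -> np.ndarray:
    """Shrinkage mean update: mu_{k,l} = sum_n w_{nl} y_{nk} / (sum_n w_{nl} + tau)."""
    num = Y.values.T @ w  # K x L
    den = w.sum(axis=0) + tau
    return num / den


def update_covariances(
    Y: MarkerMatrix, w: np.ndarray, mu: np.ndarray, hyper: Hyperparams
) -> np.ndarray:
    """Regularised covariance update.

    Sigma_l = (S_l + tau mu_l mu_l^T + Lambda) / (sum_n w_{nl} + nu - K),
    with S_l the responsibility-weighted scatter about mu_l.  The prior term
    tau mu mu^T + Lambda keeps the update well-defined for empty clusters.
    """
    K, L = mu.shape
    denoms = w.sum(axis=0) + hyper.nu - K
    if np.any(denoms <= 0):
        raise ValidationError(
            f"covariance denominator nonpositive; nu={hyper.nu} too small for K={K}"
        )
    sigma = np.empty((L, K, K))
    for l in range(L):
        diff = Y.values - mu[:, l]
        scatter = (diff * w[:, l][:, None]).T @ diff
        prior = hyper.tau * np.outer(mu[:, l], mu[:, l]) + hyper.lambda_mat
        sigma[l] = ensure_spd((scatter + prior) / denoms[l])
    return sigma


# ---------------------------------------------------------------------------
# Multinomial-logit (softmax) regression of responsibilities on covariates.
# Column 1 of beta is pinned at zero; gradient/curvature are restricted to
# the free columns 2..L when solving.
# ---------------------------------------------------------------------------


def q_beta(beta: np.ndarray, w: np.ndarray, X: DesignMatrix) -> float:
    """Expected complete-data log-probability of the allocation model,

    Q(beta) = sum_n sum_l w_{nl} (x_n beta_l - log sum_l' exp(x_n beta_l')).
    Concave in beta.
    """
    logits = X.values @ beta
    lse = logsumexp(logits, axis=1)
    return float(np.sum(w * (logits - lse[:, None])))


def grad_q(beta: np.ndarray, w: np.ndarray, X: DesignMatrix) -> np.ndarray:
    """Gradient of Q as a (D*L)-vector (column-major blocks of length D);
    the first cluster's block is projected to zero."""
    phi = compute_phi(X, beta).phi
    G = X.values.T @ (w - phi)  # D x L
    G[:, 0] = 0.0
    return G.flatten(order="F")


def hess_q(beta: np.ndarray, X: DesignMatrix) -> np.ndarray:
    """Curvature of Q: the positive-semidefinite matrix

    C = sum_n (diag(phi_n) - phi_n phi_n^T) (x) x_n x_n^T,

    i.e. the negation of the true Hessian of the concave Q.  newton_step
    absorbs the sign by ascending along C^{-1} grad."""
    phi = compute_phi(X, beta).phi
    Xv = X.values
    n, d = Xv.shape
    L = beta.shape[1]
    C = np.empty((d * L, d * L))
    for l in range(L):
        for m in range(l, L):
            coef = phi[:, l] * ((l == m) - phi[:, m])
            block = (Xv * coef[:, None]).T @ Xv
            C[l * d : (l + 1) * d, m * d : (m + 1) * d] = block
            C[m * d : (m + 1) * d, l * d : (l + 1) * d] = block.T
    return C


def _free_index(d: int, L: int) -> np.ndarray:
    """vec indices of the free beta entries (columns 2..L, column-major)."""
    return np.arange(d, d * L)


def newton_step(beta: np.ndarray, w: np.ndarray, X: DesignMatrix) -> np.ndarray:
    """One damped Newton ascent step on Q restricted to the free columns.

    Solves C delta = grad on columns 2..L, then halves the step until
    Q(beta + delta) >= Q(beta).  A singular curvature gets a small ridge;
    if factorisation still fails, falls back to a gradient step.
    """
    d, L = beta.shape
    if L == 1:
        return beta.copy()
    free = _free_index(d, L)
    g = grad_q(beta, w, X)[free]
    C = hess_q(beta, X)[np.ix_(free, free)]
    try:
        delta = np.linalg.solve(C, g)
    except np.linalg.LinAlgError:
        try:
            delta = np.linalg.solve(C + 1e-8 * np.eye(C.shape[0]), g)
        except np.linalg.LinAlgError:
            logger.warning("curvature not invertible; using gradient step")
            delta = g
    q0 = q_beta(beta, w, X)
    step = 1.0
    for _ in range(20):
        cand = beta.copy()
        cand[:, 1:] += step * delta.reshape((d, L - 1), order="F")
        if q_beta(cand, w, X) >= q0:
            return cand
        step *= 0.5
    return beta.copy()


def optimize_beta(
    beta: np.ndarray, w: np.ndarray, X: DesignMatrix, opts: EMOptions | None = None
) -> np.ndarray:
    """Iterate newton_step to convergence of Q (used inside each M-step)."""
    opts = opts or EMOptions()
    q_prev = q_beta(beta, w, X)
    for _ in range(opts.newton_max_iter):
        beta = newton_step(beta, w, X)
        q_new = q_beta(beta, w, X)
        if q_new - q_prev <= opts.newton_tol * (abs(q_prev) + 1.0):
            break
        q_prev = q_new
    return beta


def log_likelihood(Y: MarkerMatrix, X: DesignMatrix, params: ModelParams) -> float:
    """Observed-data log-likelihood sum_n log sum_l phi_{nl} N(y_n|mu_l,Sigma_l),
    priors excluded, evaluated by log-sum-exp."""
    phi = compute_phi(X, params.beta).phi
    logdens = _log_gauss_densities(Y.values, params.mu, params.sigma)
    with np.errstate(divide="ignore"):
        return float(np.sum(logsumexp(logdens + np.log(phi), axis=1)))


def _log_prior(params: ModelParams, hyper: Hyperparams) -> float:
    """Log density (up to additive constants) of the mu and Sigma priors.

    mu_l ~ N(0, Sigma_l/tau); Sigma_l^{-1} ~ Wishart(nu, rate Lambda), i.e.
    log p(Sigma^{-1}) ∝ -((nu-K-1)/2) log|Sigma| - tr(Lambda Sigma^{-1})/2.
    """
    K, L = params.mu.shape
    total = 0.0
    for l in range(L):
        sig = ensure_spd(params.sigma[l])
        chol, lower = cho_factor(sig, lower=True)
        logdet = 2.0 * np.sum(np.log(np.diag(chol)))
        mu = params.mu[:, l]
        quad = float(mu @ cho_solve((chol, lower), mu))
        inv = cho_solve((chol, lower), np.eye(K))
        total += -0.5 * logdet - 0.5 * hyper.tau * quad  # mean prior
        total += -0.5 * (hyper.nu - K - 1) * logdet - 0.5 * float(
            np.trace(hyper.lambda_mat @ inv)
        )
    return total


def map_objective(
    Y: MarkerMatrix, X: DesignMatrix, params: ModelParams, hyper: Hyperparams
) -> float:
    """The quantity EM ascends: observed log-likelihood plus log priors."""
    return log_likelihood(Y, X, params) + _log_prior(params, hyper)


def kmeans_init(Y: MarkerMatrix, L: int, seed: int) -> np.ndarray:
    """One-hot initial responsibilities from a seeded k-means++ clustering."""
    km = KMeans(n_clusters=L, n_init=3, random_state=seed)
    labels = km.fit_predict(Y.values)
    w = np.zeros((Y.n_cells, L))
    w[np.arange(Y.n_cells), labels] = 1.0
    return w


def fit_flow(
    Y: MarkerMatrix,
    X: DesignMatrix,
    L: int,
    hyper: Hyperparams | None = None,
    opts: EMOptions | None = None,
    seed: int = 0,
) -> FitResult:
    """Fit the flow-cytometry model by MAP EM.

    Initialisation is k-means++ on Y (seeded) for the labels and beta = 0.
    Convergence is declared when the relative change of the MAP objective
    falls below ``opts.tol``; non-convergence returns ``converged=False``
    rather than raising.
    """
    if L < 1:
        raise ValidationError("L must be >= 1")
    if Y.n_cells <= L:
        raise ValidationError("need more cells than clusters")
    if X.n_rows != Y.n_cells:
        raise ValidationError("design matrix row count does not match cells")
    hyper = hyper or Hyperparams.default(Y.n_markers)
    opts = opts or EMOptions()

    w = kmeans_init(Y, L, seed)
    beta = np.zeros((X.n_covariates, L))

    mu = update_means(Y, w, hyper.tau)
    sigma = update_covariances(Y, w, mu, hyper)
    beta = optimize_beta(beta, w, X, opts)
    params = ModelParams(mu, sigma, beta)

    trace: list[float] = []
    converged = False
    obj_prev = -np.inf
    latent = LatentState(w=w)
    for it in range(opts.max_iter):
        phi = compute_phi(X, params.beta)
        latent = e_step(Y, params, phi)
        w = latent.w
        counts = w.sum(axis=0)
        if np.any(counts < 1.0):
            logger.warning(
                "cluster(s) %s hold < 1 cell of total responsibility",
                np.nonzero(counts < 1.0)[0] + 1,
            )
        mu = update_means(Y, w, hyper.tau)
        sigma = update_covariances(Y, w, mu, hyper)
        beta = optimize_beta(params.beta, w, X, opts)
        params = ModelParams(mu, sigma, beta)
        obj = map_objective(Y, X, params, hyper)
        trace.append(obj)
        if obj_prev > -np.inf and abs(obj - obj_prev) <= opts.tol * (abs(obj_prev) + 1.0):
            converged = True
            break
        obj_prev = obj

    return FitResult(
        params=params,
        latent=latent,
        weights=compute_phi(X, params.beta),
        objective_trace=trace,
        loglik=log_likelihood(Y, X, params),
        n_iter=len(trace),
        converged=converged,
        seed=seed,
    )
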