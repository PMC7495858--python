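"""Shared model containers and the softmax link.

The model clusters N cells with K marker intensities into L populations whose
mixture proportions depend on per-cell covariates through a multinomial-logit
(softmax) link: ``phi_n = softmax(x_n @ beta)``.  Cluster emission is
multivariate Gaussian; for mass cytometry the Gaussian is left-censored at
zero.  Conjugate priors ``mu_l ~ N(0, Sigma_l / tau)`` and
``Sigma_l^{-1} ~ Wishart(nu, Lambda)`` regularise the cluster parameters.

Everything downstream (the flow EM, the mass stochastic EM, model selection,
the simulator) speaks in terms of the containers defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np


class ValidationError(ValueError):
    """Raised when an input container violates a model invariant."""


def _as_2d_float(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise ValidationError(f"{name} must be 2-dimensional, got shape {arr.shape}")
    if arr.size == 0:
        raise ValidationError(f"{name} must be non-empty")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite entries")
    return arr


@dataclass
class MarkerMatrix:
    """N x K matrix of per-cell marker intensities.

    ``is_censored=True`` marks mass-cytometry semantics: every entry is
    nonnegative and zeros are read as left-censored latent intensities.
    """

    values: np.ndarray
    marker_names: Optional[Sequence[str]] = None
    is_censored: bool = False

    def __post_init__(self) -> None:
        self.values = _as_2d_float(self.values, "MarkerMatrix.values")
        n, k = self.values.shape
        if self.marker_names is None:
            self.marker_names = [f"marker{j + 1}" for j in range(k)]
        else:
            self.marker_names = list(self.marker_names)
            if len(self.marker_names) != k:
                raise ValidationError(
                    f"{len(self.marker_names)} marker names for {k} columns"
                )
        if self.is_censored and np.any(self.values < 0):
            raise ValidationError("censored marker matrix has negative entries")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]


@dataclass
class DesignMatrix:
    """N x D covariate matrix; the first column is an all-ones intercept."""

    values: np.ndarray
    column_names: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.values = _as_2d_float(self.values, "DesignMatrix.values")
        if not np.all(self.values[:, 0] == 1.0):
            raise ValidationError("first design column must be an intercept of ones")
        d = self.values.shape[1]
        if self.column_names is None:
            self.column_names = ["intercept"] + [f"x{j}" for j in range(1, d)]
        else:
            self.column_names = list(self.column_names)
            if len(self.column_names) != d:
                raise ValidationError(
                    f"{len(self.column_names)} column names for {d} columns"
                )

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.values.shape[1]


@dataclass
class Hyperparams:
    """Prior hyperparameters: mean precision scale tau, Wishart (nu, Lambda).

    Defaults follow the weakly-informative choice tau=0.01, nu=K+2, Lambda=I;
    ``Hyperparams.default(K)`` builds that.
    """

    tau: float
    nu: float
    lambda_mat: np.ndarray

    def __post_init__(self) -> None:
        self.tau = float(self.tau)
        self.nu = float(self.nu)
        self.lambda_mat = np.asarray(self.lambda_mat, dtype=float)
        if self.tau <= 0:
            raise ValidationError("tau must be positive")
        k = self.lambda_mat.shape[0]
        if self.lambda_mat.shape != (k, k):
            raise ValidationError("lambda_mat must be square")
        if not np.allclose(self.lambda_mat, self.lambda_mat.T):
            raise ValidationError("lambda_mat must be symmetric")
        if self.nu <= k - 1:
            raise ValidationError(f"nu must exceed K-1 = {k - 1}")
        try:
            np.linalg.cholesky(self.lambda_mat)
        except np.linalg.LinAlgError as exc:
            raise ValidationError("lambda_mat must be positive definite") from exc

    @classmethod
    def default(cls, n_markers: int, tau: float = 0.01) -> "Hyperparams":
        return cls(tau=tau, nu=n_markers + 2, lambda_mat=np.eye(n_markers))


def ensure_spd(sigma: np.ndarray, jitter: float = 1e-8) -> np.ndarray:
    """Symmetrise and, if Cholesky fails, add jitter until positive definite.

    EM round-off can break PD-ness of covariance updates; this repairs it.
    """
    sigma = np.asarray(sigma, dtype=float)
    sigma = 0.5 * (sigma + sigma.T)
    eps = jitter
    for _ in range(12):
        try:
            np.linalg.cholesky(sigma)
            return sigma
        except np.linalg.LinAlgError:
            sigma = sigma + eps * np.eye(sigma.shape[0])
            eps *= 10.0
    raise np.linalg.LinAlgError("covariance could not be repaired to positive definite")


@dataclass
class ModelParams:
    """Cluster means mu (K x L), covariances sigma (L x K x K), logit
    coefficients beta (D x L, first column pinned at zero for identifiability).
    """

    mu: np.ndarray
    sigma: np.ndarray
    beta: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        k, l = self.mu.shape
        if self.sigma.shape != (l, k, k):
            raise ValidationError(
                f"sigma shape {self.sigma.shape} inconsistent with mu {self.mu.shape}"
            )
        if self.beta.ndim != 2 or self.beta.shape[1] != l:
            raise ValidationError("beta must be D x L")
        if not np.allclose(self.beta[:, 0], 0.0):
            raise ValidationError("first column of beta must be zero (identifiability)")

    @property
    def n_markers(self) -> int:
        return self.mu.shape[0]

    @property
    def n_clusters(self) -> int:
        return self.mu.shape[1]

    @property
    def n_covariates(self) -> int:
        return self.beta.shape[0]

    def copy(self) -> "ModelParams":
        return ModelParams(self.mu.copy(), self.sigma.copy(), self.beta.copy())


@dataclass
class MixtureWeights:
    """N x L per-cell mixture proportions; each row lies on the simplex."""

    phi: np.ndarray

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        if self.phi.ndim != 2:
            raise ValidationError("phi must be 2-dimensional")
        if np.any(self.phi < 0):
            raise ValidationError("phi entries must be nonnegative")
        if not np.allclose(self.phi.sum(axis=1), 1.0, atol=1e-10):
            raise ValidationError("phi rows must sum to 1")


@dataclass
class LatentState:
    """Per-cell latent allocation.

    ``w`` holds soft responsibilities (flow EM) or one-hot sampled labels
    (mass stochastic EM).  ``z`` holds the latent intensities of the censored
    model: equal to y where y > 0 and nonpositive where y == 0.
    """

    w: np.ndarray
    z: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.w.ndim != 2 or np.any(self.w < 0):
            raise ValidationError("w must be a nonnegative N x L matrix")
        if not np.allclose(self.w.sum(axis=1), 1.0, atol=1e-8):
            raise ValidationError("w rows must sum to 1")
        if self.z is not None:
            self.z = np.asarray(self.z, dtype=float)
            if self.z.shape[0] != self.w.shape[0]:
                raise ValidationError("z and w row counts differ")

    @property
    def hard_labels(self) -> np.ndarray:
        """Modal cluster index per cell (0-based)."""
        return np.argmax(self.w, axis=1)


@dataclass
class FitResult:
    """Outcome of a fit: parameters, final latent state, per-cell weights,
    objective trace, observed-data log-likelihood, and bookkeeping."""

    params: ModelParams
    latent: LatentState
    weights: MixtureWeights
    objective_trace: list = field(default_factory=list)
    loglik: float = float("nan")
    n_iter: int = 0
    converged: bool = False
    seed: int = 0


def softmax_rows(logits: np.ndarray) -> MixtureWeights:
    """Row-wise softmax, computed with per-row max subtraction for stability.

    Shift-invariant: adding a constant to a row leaves its output unchanged.
    """
    logits = _as_2d_float(logits, "logits")
    shifted = logits - logits.max(axis=1, keepdims=True)
    expd = np.exp(shifted)
    return MixtureWeights(expd / expd.sum(axis=1, keepdims=True))


def compute_phi(X: DesignMatrix, beta: np.ndarray) -> MixtureWeights:
    """Per-cell mixture proportions phi_n = softmax(x_n @ beta)."""
    beta = np.asarray(beta, dtype=float)
    if beta.ndim != 2 or beta.shape[0] != X.n_covariates:
        raise ValidationError(
            f"beta shape {beta.shape} does not conform to design D={X.n_covariates}"
        )
    return softmax_rows(X.values @ beta)
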