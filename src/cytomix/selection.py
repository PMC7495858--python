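"""Choosing the number of clusters L.

Flow model: BIC = -2 log L + f log N on the observed-data likelihood at the
MAP parameters, with the free-parameter count
f = L*K + L*K(K+1)/2 + (L-1)*D (beta's pinned first column is not free).
Mass model: the exact censored likelihood is orthant integrals, so the fit
is scored by the sum of squared errors against rectified cluster means and
L is read off an elbow in the SSE-vs-L scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import flow, mass
from .types import DesignMatrix, Hyperparams, MarkerMatrix, ValidationError


def n_free_params(L: int, K: int, D: int) -> int:
    """Free parameters of an L-cluster fit: means, covariances, and the
    (L-1) free logit columns."""
    return L * K + L * K * (K + 1) // 2 + (L - 1) * D


def bic(loglik: float, n_params: int, n_cells: int) -> float:
    """Bayesian information criterion, -2 log(L) + f log(N)."""
    if n_cells < 1:
        raise ValidationError("n_cells must be >= 1")
    return -2.0 * loglik + n_params * np.log(n_cells)


def sse(Y: MarkerMatrix, fitted: np.ndarray) -> float:
    """Sum of squared errors sum_{n,k} (y_{nk} - max(0, fitted_{nk}))^2."""
    fitted = np.asarray(fitted, dtype=float)
    if fitted.shape != Y.values.shape:
        raise ValidationError(
            f"fitted shape {fitted.shape} does not match data {Y.values.shape}"
        )
    return float(np.sum((Y.values - np.maximum(0.0, fitted)) ** 2))


@dataclass
class ScanResult:
    """Per-L scores plus, for flow, the argmin-BIC choice.  For the mass
    model ``suggested_L`` is only the largest-second-difference heuristic
    applied to the SSE curve — an elbow should be confirmed by eye."""

    table: pd.DataFrame
    criterion: str
    best_L: int | None = None
    suggested_L: int | None = None
    fits: dict = field(default_factory=dict)


def _elbow_heuristic(Ls: Sequence[int], scores: Sequence[float]) -> int | None:
    """Largest second difference of the score curve; needs >= 3 points."""
    Ls = list(Ls)
    s = np.asarray(scores, dtype=float)
    if len(Ls) < 3 or not np.all(np.isfinite(s)):
        return None
    curvature = s[:-2] - 2 * s[1:-1] + s[2:]
    return Ls[1 + int(np.argmax(curvature))]


def scan_L(
    Y: MarkerMatrix,
    X: DesignMatrix,
    L_range: Sequence[int],
    model: Literal["flow", "mass"] = "flow",
    hyper: Hyperparams | None = None,
    opts=None,
    seed: int = 0,
    keep_fits: bool = False,
) -> ScanResult:
    """Fit every L in ``L_range`` (fresh seeded initialisation each) and
    score it: BIC for the flow model, SSE for the mass model.

    A failed fit is recorded in the table (NaN score) and the scan continues.
    """
    L_range = list(L_range)
    if not L_range or any(b <= a for a, b in zip(L_range, L_range[1:])):
        raise ValidationError("L_range must be nonempty and strictly increasing")
    rows = []
    fits = {}
    for L in L_range:
        row = {"L": L, "score": np.nan, "converged": False, "seed": seed}
        try:
            if model == "flow":
                fit = flow.fit_flow(Y, X, L, hyper=hyper, opts=opts, seed=seed)
                f = n_free_params(L, Y.n_markers, X.n_covariates)
                row["score"] = bic(fit.loglik, f, Y.n_cells)
            elif model == "mass":
                fit = mass.fit_mass(Y, X, L, hyper=hyper, opts=opts, seed=seed)
                row["score"] = sse(Y, mass.fitted_cell_means(fit))
            else:
                raise ValidationError(f"unknown model {model!r}")
            row["converged"] = fit.converged
            if keep_fits:
                fits[L] = fit
        except ValidationError:
            raise
        except Exception as exc:  # noqa: BLE001 - scan keeps going past a bad L
            row["error"] = str(exc)
        rows.append(row)
    table = pd.DataFrame(rows)
    criterion = "BIC" if model == "flow" else "SSE"
    best = None
    if model == "flow" and table["score"].notna().any():
        best = int(table.loc[table["score"].idxmin(), "L"])
    suggested = None
    if model == "mass":
        ok = table["score"].notna()
        suggested = _elbow_heuristic(table.loc[ok, "L"], table.loc[ok, "score"])
    return ScanResult(
        table=table, criterion=criterion, best_L=best, suggested_L=suggested, fits=fits
    )
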