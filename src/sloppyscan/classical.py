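"""Eigenvalue (Hessian/FIM) sloppiness and linear-predictor theory.

The classical sloppiness measure of a least-squares fit is the eigenvalue
ratio S = lambda_min / lambda_max of the cost Hessian; a model is
conventionally called sloppy at a working point when S <= 1e-6.  For the
self-referenced cost C(theta) = sum_t ||y(theta*, t) - y(theta, t)||^2 the
Hessian at theta* reduces to the Gauss-Newton form 2 J^T J built from output
sensitivities J = dy/dtheta, since the residual term vanishes at the
reference point.

For a linear predictor y = X theta everything is analytic: the Hessian is
2 X^T X, the squared prediction deviation induced by a parameter deviation
delta is ||X delta||^2, and the per-parameter standard errors follow the
diagonal-inversion convention sigma_i = 1 / sqrt(sum_obs x_i^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .models import (
    ExperimentCondition,
    ModelValidationError,
    ODEModelSpec,
    simulate,
)

__all__ = [
    "SLOPPY_CUTOFF",
    "CostHessian",
    "SpectrumSummary",
    "LinearDesign",
    "DegenerateSpectrumError",
    "linear_hessian",
    "ode_cost_hessian",
    "output_sensitivities",
    "spectrum",
    "grid_scan_S",
    "linear_standard_errors",
    "linear_epsilon",
    "norm_bound_check",
]

#: Conventional classical-sloppiness cutoff on S = lambda_min / lambda_max.
SLOPPY_CUTOFF = 1e-6


class DegenerateSpectrumError(ValueError):
    """Raised when the Hessian has no positive curvature (lambda_max <= 0)."""


@dataclass
class CostHessian:
    """Symmetric cost-curvature matrix evaluated at a reference point."""

    matrix: np.ndarray
    theta_ref: np.ndarray
    scale: str = "linear"  # parameterisation: "linear" or "log"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.theta_ref = np.atleast_1d(np.asarray(self.theta_ref, dtype=float))
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ModelValidationError("Hessian must be square")
        if not np.all(np.isfinite(self.matrix)):
            raise ModelValidationError("Hessian has non-finite entries")
        scale = np.abs(self.matrix).max()
        if scale > 0 and np.abs(self.matrix - self.matrix.T).max() > 1e-10 * scale:
            raise ModelValidationError("Hessian is not symmetric")
        # exact symmetrisation for eigh
        self.matrix = 0.5 * (self.matrix + self.matrix.T)


@dataclass
class SpectrumSummary:
    """Eigen-spectrum of a cost Hessian with the classical sloppiness flag."""

    eigenvalues: np.ndarray          # descending
    S: float                         # lambda_min / lambda_max
    stiff_direction: np.ndarray      # unit eigenvector of lambda_max
    sloppy_direction: np.ndarray     # unit eigenvector of lambda_min
    is_sloppy_classical: bool
    rank_deficient: bool = False     # flagged when a sensitivity column vanishes


@dataclass
class LinearDesign:
    """An m x n regression design matrix."""

    X: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim == 1:
            self.X = self.X[:, None]
        if self.X.ndim != 2 or self.X.shape[0] < 1 or self.X.shape[1] < 1:
            raise ModelValidationError("design matrix must be non-empty and 2-D")
        if not np.all(np.isfinite(self.X)):
            raise ModelValidationError("design matrix has non-finite entries")

    @property
    def m(self) -> int:
        return self.X.shape[0]

    @property
    def n(self) -> int:
        return self.X.shape[1]


def linear_hessian(design: LinearDesign) -> CostHessian:
    """Hessian 2 X^T X of the least-squares cost of a linear predictor."""
    X = design.X
    return CostHessian(matrix=2.0 * X.T @ X, theta_ref=np.zeros(design.n))


def output_sensitivities(
    model: ODEModelSpec,
    theta_ref: np.ndarray,
    experiment: ExperimentCondition,
    scale: str = "linear",
    rel_step: float = 1e-6,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> np.ndarray:
    """Output Jacobian dy/dtheta (or dy/dlog theta), shape (T * n_outputs, n_params).

    Central finite differences on simulated outputs with per-parameter step
    rel_step * max(|theta_i|, 1); in log scale the step is taken in log
    coordinates, which applies the chain rule d/dlog theta = theta d/dtheta.
    """
    theta_ref = np.atleast_1d(np.asarray(theta_ref, dtype=float))
    if scale == "log" and np.any(theta_ref <= 0):
        raise ModelValidationError("log scale requires strictly positive theta_ref")
    cols = []
    for i in range(model.n_params):
        if scale == "log":
            step = rel_step
            lo, hi = np.log(theta_ref.copy()), np.log(theta_ref.copy())
            lo[i] -= step
            hi[i] += step
            th_lo, th_hi = np.exp(lo), np.exp(hi)
        else:
            step = rel_step * max(abs(theta_ref[i]), 1.0)
            th_lo, th_hi = theta_ref.copy(), theta_ref.copy()
            th_lo[i] -= step
            th_hi[i] += step
        y_hi = simulate(model, th_hi, experiment, rtol=rtol, atol=atol).outputs
        y_lo = simulate(model, th_lo, experiment, rtol=rtol, atol=atol).outputs
        cols.append(((y_hi - y_lo) / (2.0 * step)).ravel())
    return np.column_stack(cols)


def _cost_at(model, theta, y_ref, experiment, rtol, atol) -> float:
    y = simulate(model, theta, experiment, rtol=rtol, atol=atol).outputs
    return float(np.sum((y_ref - y) ** 2))


def ode_cost_hessian(
    model: ODEModelSpec,
    theta_ref: np.ndarray,
    experiment: ExperimentCondition,
    scale: str = "linear",
    method: str = "gauss_newton",
    rel_step: float = 1e-6,
    fd_step: float = 1e-3,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> CostHessian:
    """Hessian of the self-referenced least-squares cost at theta_ref.

    ``gauss_newton`` builds 2 J^T J from output sensitivities (exact at the
    reference point, where residuals vanish); ``finite_difference``
    differentiates the cost C(theta) = sum (y(theta*) - y(theta))^2 directly
    with a central second-difference stencil (step ``fd_step`` relative).
    An all-zero sensitivity column is flagged (rank deficiency), not an error.
    """
    theta_ref = np.atleast_1d(np.asarray(theta_ref, dtype=float))
    if scale == "log" and np.any(theta_ref <= 0):
        raise ModelValidationError("log scale requires strictly positive theta_ref")

    if method == "gauss_newton":
        J = output_sensitivities(
            model, theta_ref, experiment, scale=scale, rel_step=rel_step,
            rtol=rtol, atol=atol,
        )
        H = CostHessian(matrix=2.0 * J.T @ J, theta_ref=theta_ref, scale=scale)
        H.rank_deficient = bool(np.any(np.linalg.norm(J, axis=0) == 0.0))
        return H

    if method != "finite_difference":
        raise ModelValidationError(f"unknown Hessian method {method!r}")

    y_ref = simulate(model, theta_ref, experiment, rtol=rtol, atol=atol).outputs
    p = model.n_params
    if scale == "log":
        z0 = np.log(theta_ref)
        to_theta = np.exp
        steps = np.full(p, fd_step)
    else:
        z0 = theta_ref.copy()
        to_theta = lambda z: z
        steps = fd_step * np.maximum(np.abs(theta_ref), 1.0)

    def C(z):
        return _cost_at(model, to_theta(z), y_ref, experiment, rtol, atol)

    H = np.empty((p, p))
    c0 = C(z0)
    for i in range(p):
        ei = np.zeros(p)
        ei[i] = steps[i]
        H[i, i] = (C(z0 + ei) - 2.0 * c0 + C(z0 - ei)) / steps[i] ** 2
        for j in range(i + 1, p):
            ej = np.zeros(p)
            ej[j] = steps[j]
            H[i, j] = H[j, i] = (
                C(z0 + ei + ej) - C(z0 + ei - ej) - C(z0 - ei + ej) + C(z0 - ei - ej)
            ) / (4.0 * steps[i] * steps[j])
    return CostHessian(matrix=H, theta_ref=theta_ref, scale=scale)


def spectrum(H: CostHessian, cutoff: float = SLOPPY_CUTOFF) -> SpectrumSummary:
    """Eigen-decomposition of a cost Hessian and the sloppiness ratio S."""
    vals, vecs = np.linalg.eigh(H.matrix)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    lam_max, lam_min = vals[0], vals[-1]
    if lam_max <= 0.0:
        raise DegenerateSpectrumError(
            "Hessian has no positive curvature; S is undefined"
        )
    S = float(lam_min / lam_max)
    return SpectrumSummary(
        eigenvalues=vals,
        S=S,
        stiff_direction=vecs[:, 0],
        sloppy_direction=vecs[:, -1],
        is_sloppy_classical=bool(S <= cutoff),
    )


def grid_scan_S(
    model: ODEModelSpec,
    grid: Iterable[tuple[np.ndarray, ExperimentCondition]],
    scale: str = "linear",
    method: str = "gauss_newton",
    cutoff: float = SLOPPY_CUTOFF,
    **hessian_kwargs,
) -> pd.DataFrame:
    """Classical sloppiness S over a grid of (theta, experiment) points.

    Per-point failures (integration errors, degenerate spectra) are recorded
    as NaN and the scan continues.  Columns: one per parameter, the initial
    conditions, S and the classical flag.
    """
    grid = list(grid)
    if not grid:
        raise ModelValidationError("grid must be non-empty")
    rows = []
    for theta, experiment in grid:
        theta = np.atleast_1d(np.asarray(theta, dtype=float))
        row = {f"theta{i + 1}": theta[i] for i in range(theta.size)}
        for j, v in enumerate(np.atleast_1d(experiment.x0_values)):
            row[f"x{j + 1}_0"] = v
        try:
            H = ode_cost_hessian(
                model, theta, experiment, scale=scale, method=method, **hessian_kwargs
            )
            row["S"] = spectrum(H, cutoff=cutoff).S
        except (Exception,) as err:  # per-point failure: record and continue
            warnings.warn(f"grid point {theta.tolist()} failed: {err}")
            row["S"] = np.nan
        rows.append(row)
    df = pd.DataFrame(rows)
    df["is_sloppy_classical"] = df["S"] <= cutoff
    return df


def linear_standard_errors(design: LinearDesign) -> np.ndarray:
    """Per-parameter standard errors sigma_i = 1/sqrt(sum_obs x_i^2).

    This is the diagonal-inversion convention (invert the Hessian diagonal,
    ignoring cross terms); it equals the exact inverse-Hessian diagonal for
    orthogonal designs.  A zero column yields an infinite standard error.
    """
    ss = np.sum(design.X**2, axis=0)
    with np.errstate(divide="ignore"):
        sig = 1.0 / np.sqrt(ss)
    if np.any(~np.isfinite(sig)):
        warnings.warn("zero design column: infinite standard error")
    return sig


def linear_epsilon(design: LinearDesign, delta_vec: Sequence[float]) -> float:
    """Squared prediction deviation ||X delta||^2 induced by a parameter deviation."""
    delta_vec = np.atleast_1d(np.asarray(delta_vec, dtype=float))
    if delta_vec.shape != (design.n,):
        raise ModelValidationError(
            f"delta_vec has shape {delta_vec.shape}, expected ({design.n},)"
        )
    return float(np.sum((design.X @ delta_vec) ** 2))


def norm_bound_check(
    design: LinearDesign, epsilon: float, delta: float
) -> tuple[bool, float]:
    """Check an (epsilon, delta) pair against the design's spectral geometry.

    ``epsilon`` is a squared output deviation, ``delta`` a parameter-space
    distance.  Returns ``(achievable, implied_norm)`` where ``implied_norm``
    is sqrt(epsilon)/delta — the spectral norm a design would need for the
    matrix-norm bound ||X theta_d|| <= ||X|| ||theta_d|| to allow the pair —
    and ``achievable`` reports whether some deviation of length delta
    actually attains an output deviation <= epsilon, i.e.
    (sigma_min * delta)^2 <= epsilon.  A (near-)zero smallest singular value
    therefore makes epsilon = 0 achievable at delta > 0: loss of
    identifiability.
    """
    if delta <= 0:
        raise ModelValidationError("delta must be positive")
    if epsilon < 0:
        raise ModelValidationError("epsilon must be non-negative")
    svals = np.linalg.svd(design.X, compute_uv=False)
    sigma_min = svals[-1] if design.n <= design.m else 0.0
    if sigma_min <= 1e-12 * svals[0]:
        sigma_min = 0.0  # numerically singular: identifiability lost
    implied_norm = float(np.sqrt(epsilon) / delta)
    need = (sigma_min * delta) ** 2
    achievable = bool(need <= epsilon + 1e-9 * (need + epsilon) + 1e-300)
    return achievable, implied_norm
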