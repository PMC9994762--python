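"""Monte-Carlo (epsilon, delta)-sloppiness scanning of a Euclidean ball.

The scanner probes model behaviour around a reference parameter vector
theta* by sampling a ball of radius delta, divided into l equally spaced
shells.  Per shell it records the minimum and maximum sum-squared output
deviation from the reference trajectory,

    gamma(theta) = sum_t || y(theta*, t) - y(theta, t) ||^2,

and the per-shell sensitivity index psi = 1 - gamma_min / gamma_max.
A gamma_min that returns to numerically zero at a non-zero radius exposes
local structural unidentifiability; a gamma_min that stays positive but far
below a chosen prediction tolerance epsilon while the radius delta is large
exposes (epsilon, delta)-sloppiness; psi near one signals strong anisotropy
(coexisting near-invisible and highly visible parameter directions).

Shell semantics: samples are drawn per annulus (delta_{k-1}, delta_k], so
the per-shell statistics describe behaviour *at* distance ~delta_k rather
than anywhere inside the ball; this is what makes the gamma_min-vs-delta
curve rise for identifiable models and dip at an unidentifiability radius.

By default each shell's sampled minimum is polished by a deterministic
constrained local minimisation within its annulus, so the reported
gamma_min is the annulus minimum rather than a Monte-Carlo estimate of it;
this makes unidentifiability detection independent of the sampling seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import NonlinearConstraint, minimize
from scipy.special import ndtr

from .models import (
    ExperimentCondition,
    IntegrationFailure,
    ModelValidationError,
    ODEModelSpec,
    Trajectory,
    simulate,
    simulate_batch,
)

__all__ = [
    "ShellScanConfig",
    "ShellScanResult",
    "SloppinessVerdict",
    "shell_radii",
    "sample_ball",
    "update_sample_size",
    "gamma",
    "sensitivity_index",
    "scan",
    "classify",
    "per_parameter_profiles",
    "rank_parameters",
    "direction_cosine_matrix",
]


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------


def shell_radii(delta_total: float, n_shells: int) -> np.ndarray:
    """l equally spaced shell radii ending exactly at delta_total."""
    if delta_total <= 0:
        raise ModelValidationError("delta_total must be positive")
    if n_shells < 1:
        raise ModelValidationError("n_shells must be >= 1")
    return np.linspace(delta_total / n_shells, delta_total, n_shells)


def _annulus_samples(
    center: np.ndarray, lo: float, hi: float, N: int, rng: np.random.Generator
) -> np.ndarray:
    """N points uniform in the annulus lo < ||x - center|| <= hi.

    Directions are normalised independent Gaussians (uniform on the sphere);
    radii follow the n-volume law r = (lo^n + u (hi^n - lo^n))^(1/n).  All
    random draws for sample i occupy one contiguous row, so the first N
    samples of a larger draw from the same generator state are identical
    (superset sampling under nested sample sizes).
    """
    n = center.size
    Z = rng.standard_normal((N, n + 1))
    D = Z[:, :n]
    norms = np.linalg.norm(D, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    D = D / norms
    u = ndtr(Z[:, n])  # uniform(0, 1) via the normal CDF
    r = (lo**n + u * (hi**n - lo**n)) ** (1.0 / n)
    return center + D * r[:, None]


def sample_ball(
    theta_ref: np.ndarray, radius: float, N: int, seed
) -> np.ndarray:
    """N parameter vectors uniform in the Euclidean ball of given radius.

    ``seed`` may be an int or an ``np.random.Generator``.  Deterministic
    under a fixed seed; every point satisfies ||theta - theta*|| <= radius.
    """
    if radius <= 0:
        raise ModelValidationError("radius must be positive")
    if N < 1:
        raise ModelValidationError("N must be >= 1")
    theta_ref = np.atleast_1d(np.asarray(theta_ref, dtype=float))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _annulus_samples(theta_ref, 0.0, radius, N, rng)


def update_sample_size(N_current: int, alpha: float, radius_ratio: float, n: int) -> int:
    """Sample-size growth N(k+1) = N(k) + ceil(alpha * (delta_{k+1}/delta_k)^n)."""
    if radius_ratio < 1:
        raise ModelValidationError("radius_ratio must be >= 1")
    return int(N_current + np.ceil(alpha * radius_ratio**n))


def gamma(y_ref: Trajectory, y: Trajectory) -> float:
    """Sum over time points and outputs of the squared deviation."""
    if y_ref.outputs.shape != y.outputs.shape or not np.allclose(
        y_ref.time_grid, y.time_grid
    ):
        raise ModelValidationError("trajectories have mismatched grids or dimensions")
    return float(np.sum((y_ref.outputs - y.outputs) ** 2))


def sensitivity_index(gamma_min: float, gamma_max: float) -> float:
    """psi = 1 - gamma_min / gamma_max; 0 when gamma_max = 0 (no output variation)."""
    if gamma_min < 0 or gamma_max < gamma_min:
        raise ModelValidationError("need 0 <= gamma_min <= gamma_max")
    if gamma_max == 0.0:
        return 0.0
    return 1.0 - gamma_min / gamma_max


# ---------------------------------------------------------------------------
# Scan configuration and result containers
# ---------------------------------------------------------------------------


@dataclass
class ShellScanConfig:
    """Settings for a shell scan around theta*.

    delta_total is the ball radius in parameter units (scale="linear") or in
    log-parameter units (scale="log", in which case sampling, distances and
    profiles all live in log space and theta must be strictly positive).
    zero_tol is the relative "numerically zero" tolerance on gamma_min,
    taken relative to the global gamma_max of the scan.
    """

    theta_ref: np.ndarray
    delta_total: float
    n_shells: int = 30
    N0: int = 20000
    alpha: float = 1000.0
    seed: int = 0
    scale: str = "linear"
    zero_tol: float = 1e-8
    refine: bool = True            # polish per-shell minima within each annulus
    refine_maxiter: int = 100
    keep_samples: bool = True      # retain (theta, gamma) records for profiles
    rtol: float = 1e-8             # integrator tolerances for sampled simulations
    atol: float = 1e-10

    def __post_init__(self) -> None:
        self.theta_ref = np.atleast_1d(np.asarray(self.theta_ref, dtype=float))
        if self.delta_total <= 0:
            raise ModelValidationError("delta_total must be positive")
        if self.n_shells < 2:
            raise ModelValidationError("n_shells must be >= 2")
        if self.N0 < 1:
            raise ModelValidationError("N0 must be >= 1")
        if self.alpha < 0:
            raise ModelValidationError("alpha must be >= 0")
        if self.scale not in ("linear", "log"):
            raise ModelValidationError("scale must be 'linear' or 'log'")
        if self.scale == "log" and np.any(self.theta_ref <= 0):
            raise ModelValidationError("log scale requires strictly positive theta_ref")


@dataclass
class ShellScanResult:
    """Per-shell gamma statistics of a completed scan."""

    shell_radii: np.ndarray
    gamma_min: np.ndarray
    gamma_max: np.ndarray
    psi: np.ndarray
    argmin_params: np.ndarray      # (l, n) parameter vectors, model units
    argmax_params: np.ndarray
    samples_per_shell: np.ndarray
    config: ShellScanConfig
    param_names: Sequence[str]
    n_failed: int = 0
    all_samples: Optional[np.ndarray] = None   # (N_total, n) sampling-scale coords
    all_gamma: Optional[np.ndarray] = None
    all_shell_index: Optional[np.ndarray] = None

    @property
    def gamma_max_global(self) -> float:
        return float(self.gamma_max.max())

    def shell_centers(self) -> np.ndarray:
        edges = np.concatenate([[0.0], self.shell_radii])
        return 0.5 * (edges[:-1] + edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "delta_k": self.shell_radii,
                "gamma_min": self.gamma_min,
                "gamma_max": self.gamma_max,
                "psi": self.psi,
                "N_k": self.samples_per_shell,
            }
        )

    def to_json(self) -> str:
        payload = {
            "shell_radii": self.shell_radii.tolist(),
            "gamma_min": self.gamma_min.tolist(),
            "gamma_max": self.gamma_max.tolist(),
            "psi": self.psi.tolist(),
            "argmin_params": self.argmin_params.tolist(),
            "argmax_params": self.argmax_params.tolist(),
            "samples_per_shell": self.samples_per_shell.tolist(),
            "param_names": list(self.param_names),
            "scale": self.config.scale,
            "theta_ref": self.config.theta_ref.tolist(),
            "delta_total": self.config.delta_total,
            "seed": self.config.seed,
            "zero_tol": self.config.zero_tol,
            "n_failed": self.n_failed,
        }
        return json.dumps(payload, indent=2)


@dataclass
class SloppinessVerdict:
    """Classification of the scanned region around theta*."""

    locally_identifiable: bool
    unidentifiability_radius: Optional[float]
    eps_delta_sloppy: bool
    eps: float
    delta: float
    scale: str
    sensitive_params: list = field(default_factory=list)
    insensitive_params: list = field(default_factory=list)

    def summary(self) -> str:
        lines = []
        if self.locally_identifiable:
            lines.append("locally structurally identifiable in the scanned ball")
            state = "(eps, delta)-sloppy" if self.eps_delta_sloppy else "not sloppy"
            lines.append(
                f"{state} at eps={self.eps:.3g}, delta={self.delta:.3g} "
                f"({self.scale} scale)"
            )
        else:
            lines.append(
                "locally structurally unidentifiable: gamma_min numerically zero "
                f"at radius ~{self.unidentifiability_radius:.4g} ({self.scale} scale)"
            )
        if self.sensitive_params:
            lines.append("most sensitive parameters: " + ", ".join(self.sensitive_params))
        if self.insensitive_params:
            lines.append("insensitive parameters: " + ", ".join(self.insensitive_params))
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# The scan
# ---------------------------------------------------------------------------


def _to_model_space(points: np.ndarray, scale: str) -> np.ndarray:
    return np.exp(points) if scale == "log" else points


def _batch_gamma(
    model: ODEModelSpec,
    thetas: np.ndarray,
    y_ref: np.ndarray,
    experiment: ExperimentCondition,
    config: ShellScanConfig,
) -> tuple[np.ndarray, int]:
    """gamma for each row of thetas (model space); NaN where simulation fails."""
    Y = simulate_batch(
        model, thetas, experiment, rtol=config.rtol, atol=config.atol
    )
    g = np.sum((Y - y_ref[None, :, :]) ** 2, axis=(1, 2))
    bad = ~np.isfinite(g)
    g[bad] = np.nan
    return g, int(bad.sum())


def _refine_minimum(
    model: ODEModelSpec,
    experiment: ExperimentCondition,
    config: ShellScanConfig,
    center: np.ndarray,
    lo: float,
    hi: float,
    start: np.ndarray,
    start_gamma: float,
    y_ref: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Polish a sampled minimum by constrained minimisation within the annulus."""

    def objective(z):
        theta = _to_model_space(z, config.scale)
        try:
            y = simulate(model, theta, experiment, rtol=config.rtol, atol=config.atol)
        except (IntegrationFailure, ModelValidationError):
            return 1e12
        return float(np.sum((y.outputs - y_ref) ** 2))

    con = NonlinearConstraint(lambda z: np.linalg.norm(z - center), lo, hi)
    try:
        res = minimize(
            objective,
            start,
            method="SLSQP",
            constraints=[con],
            options={"maxiter": config.refine_maxiter, "ftol": 1e-18},
        )
    except Exception:
        return start, start_gamma
    if res.success:
        d = np.linalg.norm(res.x - center)
        if lo - 1e-9 * hi <= d <= hi * (1 + 1e-9) and res.fun < start_gamma:
            return res.x, float(max(res.fun, 0.0))
    return start, start_gamma


def scan(
    model: ODEModelSpec,
    experiment: ExperimentCondition,
    config: ShellScanConfig,
) -> ShellScanResult:
    """Run the shell-scan procedure around theta*.

    Per shell k: draw N(k) samples uniform in the annulus
    (delta_{k-1}, delta_k] (in log-parameter coordinates when
    scale="log"), simulate each, record gamma_min / gamma_max and the
    attaining parameter vectors, update N by the growth rule, and compute
    psi.  Failed simulations are excluded, with a warning when more than 1%
    of a shell fails.  With ``refine`` on, each shell's minimum (beyond the
    innermost) is polished by a deterministic local search in the annulus.
    """
    theta_ref = config.theta_ref
    if theta_ref.shape != (model.n_params,):
        raise ModelValidationError(
            f"theta_ref has shape {theta_ref.shape}, model expects ({model.n_params},)"
        )
    n = model.n_params
    y_ref = simulate(model, theta_ref, experiment, rtol=config.rtol, atol=config.atol).outputs

    center = np.log(theta_ref) if config.scale == "log" else theta_ref
    radii = shell_radii(config.delta_total, config.n_shells)

    g_min = np.empty(config.n_shells)
    g_max = np.empty(config.n_shells)
    arg_min = np.empty((config.n_shells, n))
    arg_max = np.empty((config.n_shells, n))
    n_samples = np.empty(config.n_shells, dtype=int)
    kept_pts, kept_g, kept_k = [], [], []
    total_failed = 0

    N = int(config.N0)
    for k in range(config.n_shells):
        lo = 0.0 if k == 0 else radii[k - 1]
        hi = radii[k]
        rng = np.random.default_rng([config.seed, k])
        pts = _annulus_samples(center, lo, hi, N, rng)
        thetas = _to_model_space(pts, config.scale)
        g, failed = _batch_gamma(model, thetas, y_ref, experiment, config)
        total_failed += failed
        if failed > 0.01 * N:
            warnings.warn(
                f"shell {k + 1}: {failed}/{N} simulations failed", RuntimeWarning
            )
        valid = np.isfinite(g)
        if not valid.any():
            raise IntegrationFailure(f"shell {k + 1}: all simulations failed")
        gv = np.where(valid, g, np.inf)
        i_min = int(np.argmin(gv))
        gv = np.where(valid, g, -np.inf)
        i_max = int(np.argmax(gv))
        g_min[k], g_max[k] = g[i_min], g[i_max]
        min_pt = pts[i_min].copy()
        if config.refine and k > 0:
            min_pt, g_min[k] = _refine_minimum(
                model, experiment, config, center, lo, hi, min_pt, g_min[k], y_ref
            )
        arg_min[k] = _to_model_space(min_pt, config.scale)
        arg_max[k] = thetas[i_max]
        n_samples[k] = N
        if config.keep_samples:
            kept_pts.append(pts[valid])
            kept_g.append(g[valid])
            kept_k.append(np.full(int(valid.sum()), k))
        if k < config.n_shells - 1:
            N = update_sample_size(N, config.alpha, radii[k + 1] / radii[k], n)

    psi = np.array(
        [sensitivity_index(min(lo_, hi_), max(lo_, hi_)) for lo_, hi_ in zip(g_min, g_max)]
    )
    return ShellScanResult(
        shell_radii=radii,
        gamma_min=g_min,
        gamma_max=g_max,
        psi=psi,
        argmin_params=arg_min,
        argmax_params=arg_max,
        samples_per_shell=n_samples,
        config=config,
        param_names=list(model.param_names),
        n_failed=total_failed,
        all_samples=np.concatenate(kept_pts) if kept_pts else None,
        all_gamma=np.concatenate(kept_g) if kept_g else None,
        all_shell_index=np.concatenate(kept_k) if kept_k else None,
    )


# ---------------------------------------------------------------------------
# Verdicts
# ---------------------------------------------------------------------------


def classify(
    result: ShellScanResult,
    eps: Optional[float] = None,
    delta: Optional[float] = None,
    zero_tol: Optional[float] = None,
    min_separation: float = 10.0,
    insensitive_frac: float = 0.01,
) -> SloppinessVerdict:
    """Turn per-shell gamma statistics into an identifiability/sloppiness verdict.

    Local structural unidentifiability: some shell beyond the innermost has
    gamma_min <= zero_tol * global gamma_max.  The innermost shell is
    excluded because its annulus touches theta*, where gamma vanishes by
    continuity regardless of identifiability.  (epsilon, delta)-sloppiness:
    the region is identifiable yet gamma_min at the shell containing delta
    is below eps, with delta/eps at least ``min_separation``.

    Defaults: eps = 1e-3 * gamma_max at the outermost shell; delta = the
    total scan radius; zero_tol from the scan config.
    """
    radii = result.shell_radii
    gmax_global = result.gamma_max_global
    if delta is None:
        delta = float(radii[-1])
    if zero_tol is None:
        zero_tol = result.config.zero_tol
    if delta > radii[-1] + 1e-12:
        raise ModelValidationError("delta exceeds the scanned radius")
    if eps is None:
        eps = 1e-3 * float(result.gamma_max[-1])
    elif eps > 0 and delta / eps < min_separation:
        # the separation contract is enforced for user-chosen pairs only;
        # the defaulted eps lives in output^2 units and carries its own scale
        raise ModelValidationError(
            f"(eps, delta) contract violated: delta/eps = {delta / eps:.3g} "
            f"< {min_separation}"
        )

    tol_abs = zero_tol * gmax_global
    centers = result.shell_centers()
    unident_radius = None
    for k in range(1, radii.size):  # innermost shell excluded (continuity)
        if result.gamma_min[k] <= tol_abs:
            unident_radius = float(centers[k])
            break
    identifiable = unident_radius is None

    sloppy = False
    if identifiable:
        k_delta = int(np.searchsorted(radii, delta - 1e-12))
        k_delta = min(k_delta, radii.size - 1)
        sloppy = bool(result.gamma_min[k_delta] < eps)

    sensitive, insensitive = [], []
    if result.all_samples is not None:
        profiles = per_parameter_profiles(result)
        sensitive, insensitive = rank_parameters(
            profiles, gmax_global, insensitive_frac=insensitive_frac
        )

    return SloppinessVerdict(
        locally_identifiable=identifiable,
        unidentifiability_radius=unident_radius,
        eps_delta_sloppy=sloppy,
        eps=float(eps),
        delta=float(delta),
        scale=result.config.scale,
        sensitive_params=sensitive,
        insensitive_params=insensitive,
    )


# ---------------------------------------------------------------------------
# Per-parameter profiles and direction analysis
# ---------------------------------------------------------------------------


def per_parameter_profiles(
    result: ShellScanResult, n_bins: int = 20
) -> dict[str, pd.DataFrame]:
    """Bin retained samples by each parameter's absolute coordinate deviation.

    For parameter i the samples are binned by |theta_i - theta*_i| (in
    sampling-scale coordinates, so log-deviations under a log scan); per bin
    the min and max gamma are reported.  Empty bins appear with NaN, never
    interpolated.
    """
    if result.all_samples is None:
        raise ModelValidationError("scan was run without keep_samples")
    cfg = result.config
    center = np.log(cfg.theta_ref) if cfg.scale == "log" else cfg.theta_ref
    dev = np.abs(result.all_samples - center)
    g = result.all_gamma
    edges = np.linspace(0.0, cfg.delta_total, n_bins + 1)
    profiles = {}
    for i, name in enumerate(result.param_names):
        idx = np.clip(np.digitize(dev[:, i], edges) - 1, 0, n_bins - 1)
        gmin = np.full(n_bins, np.nan)
        gmax = np.full(n_bins, np.nan)
        count = np.zeros(n_bins, dtype=int)
        for b in range(n_bins):
            mask = idx == b
            if mask.any():
                gmin[b] = g[mask].min()
                gmax[b] = g[mask].max()
                count[b] = int(mask.sum())
        profiles[name] = pd.DataFrame(
            {
                "bin_lo": edges[:-1],
                "bin_hi": edges[1:],
                "bin_center": 0.5 * (edges[:-1] + edges[1:]),
                "gamma_min": gmin,
                "gamma_max": gmax,
                "count": count,
            }
        )
    return profiles


def rank_parameters(
    profiles: dict[str, pd.DataFrame],
    gamma_max_global: float,
    insensitive_frac: float = 0.01,
) -> tuple[list[str], list[str]]:
    """Rank parameters sensitive/insensitive from their gamma profiles.

    A parameter is insensitive when its gamma_min profile stays below
    ``insensitive_frac`` of the global gamma_max across the scanned range:
    even large moves of that coordinate admit directions the output cannot
    see.  The remaining parameters are ranked sensitive by how steeply their
    gamma_max profile rises from small coordinate deviations (the rise of
    the upper envelope over the first half of the range, normalised by the
    global gamma_max): a steep early rise means small moves of that
    coordinate already produce the largest visible output changes.
    """
    insensitive: list[tuple[str, float]] = []
    sensitive: list[tuple[str, float]] = []
    for name, df in profiles.items():
        pop = df.dropna(subset=["gamma_min"])
        if pop.empty:
            insensitive.append((name, 0.0))
            continue
        flat = float(pop["gamma_min"].max()) / gamma_max_global
        # early-rise steepness of the max envelope
        envelope = pop["gamma_max"].to_numpy()
        centers = pop["bin_center"].to_numpy()
        half = max(2, len(envelope) // 2)
        x, y = centers[:half], envelope[:half]
        if len(x) >= 2 and x[-1] > x[0]:
            slope = float(np.polyfit(x, y, 1)[0]) * (x[-1] - x[0]) / gamma_max_global
        else:
            slope = 0.0
        if flat < insensitive_frac:
            insensitive.append((name, flat))
        else:
            sensitive.append((name, slope))
    sensitive.sort(key=lambda kv: -kv[1])
    insensitive.sort(key=lambda kv: kv[1])
    return [k for k, _ in sensitive], [k for k, _ in insensitive]


def direction_cosine_matrix(vectors: np.ndarray) -> np.ndarray:
    """Pairwise cosine matrix of per-shell deviation vectors.

    Rows are (argmin or argmax minus theta*) vectors, one per shell; entry
    (j, k) is the cosine of the angle between the unit-normalised vectors of
    shells j and k.  A zero vector yields NaN in its row and column.
    """
    V = np.atleast_2d(np.asarray(vectors, dtype=float))
    if V.shape[0] < 2:
        raise ModelValidationError("need at least 2 deviation vectors")
    norms = np.linalg.norm(V, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        U = V / norms[:, None]
    C = U @ U.T
    C[norms == 0, :] = np.nan
    C[:, norms == 0] = np.nan
    return np.clip(C, -1.0, 1.0)  # NaN rows/cols pass through unchanged


def deviation_vectors(result: ShellScanResult, which: str = "argmin") -> np.ndarray:
    """Per-shell deviation vectors (sampling-scale) for direction analysis."""
    cfg = result.config
    params = result.argmin_params if which == "argmin" else result.argmax_params
    pts = np.log(params) if cfg.scale == "log" else params
    center = np.log(cfg.theta_ref) if cfg.scale == "log" else cfg.theta_ref
    return pts - center
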