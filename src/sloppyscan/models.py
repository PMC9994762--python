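"""Parametric ODE models and benchmark systems.

A model is a triple (f, h, x0): a state derivative map, an observation map
and a (possibly parameter-dependent) initial-state map,

    dx/dt = f(x, theta, u(t), t),   y(t) = h(x(t), theta),   x(t0) = x0,

with dimensions n_states, n_outputs and n_params.  Models with a known
analytic solution carry a ``closed_form`` map so that scans over many
thousands of parameter vectors avoid numerical integration entirely.

The zoo ships four benchmarks used throughout the package:

``biexp``
    The two-parameter bi-exponential y(t) = exp(-th1 t) + exp(-th2 t),
    the canonical sloppy toy model.
``lti_diag``
    A two-state diagonal linear system with summed output
    y(t) = x1(0) exp(-th1 t) + x2(0) exp(-th2 t).  With equal initial
    conditions it is symmetric under th1 <-> th2, which makes it an exact
    oracle for local structural unidentifiability.
``mitotic_oscillator``
    Goldbeter's minimal cascade model of the mitotic oscillator
    (cyclin C, active cdc2 kinase fraction M, active protease fraction X);
    3 states, 10 scanned parameters.
``hiv``
    The Perelson-Kirschner-De Boer model of HIV infection of CD4+ T cells
    (uninfected T, latently infected T*, actively infected T**, free
    virus V); 4 states, 8 parameters, output = free virus.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "ODEModelSpec",
    "ExperimentCondition",
    "Trajectory",
    "ModelValidationError",
    "IntegrationFailure",
    "simulate",
    "simulate_batch",
    "make_benchmark",
    "linear_predictor",
    "default_experiment",
    "load_fixture_parameters",
    "BENCHMARK_NAMES",
]

BENCHMARK_NAMES = ("biexp", "lti_diag", "mitotic_oscillator", "hiv")


#: States beyond this magnitude are treated as divergent (integration failure).
_STATE_BOUND = 1e12


class ModelValidationError(ValueError):
    """Raised on dimension mismatches or malformed model inputs."""


class IntegrationFailure(RuntimeError):
    """Raised when numerical integration fails or produces non-finite states."""


def _zero_input(t: float) -> float:
    return 0.0


@dataclass
class ODEModelSpec:
    """A parametric dynamical model (f, h, x0) with known dimensions.

    ``closed_form(theta, t_grid) -> (T, n_outputs)`` bypasses integration;
    ``closed_form_batch(thetas, t_grid) -> (N, T, n_outputs)`` vectorises it
    over many parameter vectors at once (used by the shell scanner).
    ``x0`` maps (theta, experiment) to the initial state; by default it
    returns the experiment's initial conditions unchanged.
    """

    name: str
    n_params: int
    n_states: int
    n_outputs: int
    f: Optional[Callable] = None
    h: Optional[Callable] = None
    x0: Optional[Callable] = None
    closed_form: Optional[Callable] = None
    closed_form_batch: Optional[Callable] = None
    f_batch: Optional[Callable] = None   # (states (n_x, B), thetas (B, n_p), u, t) -> (n_x, B)
    param_names: Sequence[str] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.n_params < 1 or self.n_states < 0 or self.n_outputs < 1:
            raise ModelValidationError(
                f"model {self.name!r}: dimensions must be positive"
            )
        if not self.param_names:
            self.param_names = tuple(f"theta{i + 1}" for i in range(self.n_params))
        if len(self.param_names) != self.n_params:
            raise ModelValidationError(
                f"model {self.name!r}: {len(self.param_names)} parameter names "
                f"for {self.n_params} parameters"
            )
        if self.closed_form is None and (self.f is None or self.h is None):
            raise ModelValidationError(
                f"model {self.name!r}: need either closed_form or (f, h)"
            )

    def initial_state(self, theta: np.ndarray, experiment: "ExperimentCondition") -> np.ndarray:
        if self.x0 is not None:
            x = np.asarray(self.x0(theta, experiment), dtype=float)
        else:
            x = np.asarray(experiment.x0_values, dtype=float)
        if x.shape != (self.n_states,):
            raise ModelValidationError(
                f"model {self.name!r}: initial state has shape {x.shape}, "
                f"expected ({self.n_states},)"
            )
        return x


@dataclass
class ExperimentCondition:
    """One point of the experiment space: initial conditions, input, time grid."""

    x0_values: np.ndarray
    time_grid: np.ndarray
    input: Callable = _zero_input

    def __post_init__(self) -> None:
        self.x0_values = np.atleast_1d(np.asarray(self.x0_values, dtype=float))
        self.time_grid = np.asarray(self.time_grid, dtype=float)
        if self.time_grid.ndim != 1 or self.time_grid.size < 2:
            raise ModelValidationError("time_grid must be 1-D with at least 2 points")
        if np.any(np.diff(self.time_grid) <= 0):
            raise ModelValidationError("time_grid must be strictly increasing")

    def validate_for(self, model: ODEModelSpec) -> None:
        if model.n_states and self.x0_values.shape != (model.n_states,):
            raise ModelValidationError(
                f"experiment has {self.x0_values.size} initial conditions, "
                f"model {model.name!r} has {model.n_states} states"
            )


@dataclass
class Trajectory:
    """Model outputs sampled on a time grid (rows = time points)."""

    time_grid: np.ndarray
    outputs: np.ndarray

    def __post_init__(self) -> None:
        self.time_grid = np.asarray(self.time_grid, dtype=float)
        self.outputs = np.asarray(self.outputs, dtype=float)
        if self.outputs.ndim == 1:
            self.outputs = self.outputs[:, None]
        if self.outputs.shape[0] != self.time_grid.size:
            raise ModelValidationError(
                f"trajectory has {self.outputs.shape[0]} rows for "
                f"{self.time_grid.size} time points"
            )
        if not np.all(np.isfinite(self.outputs)):
            raise IntegrationFailure("trajectory contains non-finite outputs")

    def to_frame(self):
        import pandas as pd

        cols = {f"y{i + 1}": self.outputs[:, i] for i in range(self.outputs.shape[1])}
        return pd.DataFrame({"time": self.time_grid, **cols})


def simulate(
    model: ODEModelSpec,
    theta: np.ndarray,
    experiment: ExperimentCondition,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> Trajectory:
    """Simulate the model output at the experiment's sampling times.

    Uses the analytic solution when the model provides one, otherwise a
    stiff-capable adaptive integrator at the given tolerances.  Raises
    :class:`IntegrationFailure` (naming the offending parameter vector) when
    the state leaves the finite range, and :class:`ModelValidationError` on
    dimension mismatch.
    """
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    if theta.shape != (model.n_params,):
        raise ModelValidationError(
            f"theta has shape {theta.shape}, model {model.name!r} expects "
            f"({model.n_params},)"
        )
    experiment.validate_for(model)
    t = experiment.time_grid

    if model.closed_form is not None:
        y = np.asarray(model.closed_form(theta, t, experiment), dtype=float)
        return Trajectory(t, y)

    x_init = model.initial_state(theta, experiment)
    u = experiment.input
    blown = False

    def rhs(ti, x):
        # freeze runaway states so a divergent trajectory fails fast instead
        # of grinding the step-size control toward the singularity
        nonlocal blown
        if not np.all(np.isfinite(x)) or np.abs(x).max() > _STATE_BOUND:
            blown = True
            return np.zeros_like(x)
        return model.f(x, theta, u(ti), ti)

    with np.errstate(over="ignore", invalid="ignore"):
        sol = solve_ivp(
            rhs,
            (t[0], t[-1]),
            x_init,
            t_eval=t,
            method=method,
            rtol=rtol,
            atol=atol,
        )
    if blown or not sol.success or not np.all(np.isfinite(sol.y)):
        raise IntegrationFailure(
            f"integration failed for model {model.name!r} at theta={theta.tolist()}: "
            f"{'state diverged' if blown else sol.message}"
        )
    y = _observe(model, sol.y, theta, t.size)
    if y.shape[1] != model.n_outputs:
        raise ModelValidationError(
            f"observation map of {model.name!r} returned {y.shape[1]} outputs, "
            f"expected {model.n_outputs}"
        )
    return Trajectory(t, y)


def simulate_batch(
    model: ODEModelSpec,
    thetas: np.ndarray,
    experiment: ExperimentCondition,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    chunk: int = 2000,
) -> np.ndarray:
    """Simulate many parameter vectors at once; returns (N, T, n_outputs).

    Rows whose simulation fails are NaN.  Uses, in order of preference, the
    model's vectorised analytic solution, its batched state derivative
    (integrating ``chunk`` parameter sets as one stacked system with a
    non-stiff adaptive integrator), or a per-sample fallback loop.  The
    stacked route shares step-size control across the chunk, which is
    accurate (the error norm covers every sample) but couples the step to
    the worst-behaved sample; chunking bounds that coupling.
    """
    thetas = np.asarray(thetas, dtype=float)
    if thetas.ndim != 2 or thetas.shape[1] != model.n_params:
        raise ModelValidationError(
            f"thetas must be (N, {model.n_params}), got {thetas.shape}"
        )
    experiment.validate_for(model)
    t = experiment.time_grid
    N = thetas.shape[0]

    if model.closed_form_batch is not None:
        return np.asarray(model.closed_form_batch(thetas, t, experiment), dtype=float)

    if model.f_batch is None:
        out = np.full((N, t.size, model.n_outputs), np.nan)
        for i in range(N):
            try:
                out[i] = simulate(model, thetas[i], experiment, rtol=rtol, atol=atol).outputs
            except (IntegrationFailure, ModelValidationError):
                pass
        return out

    u = experiment.input
    out = np.full((N, t.size, model.n_outputs), np.nan)
    for start in range(0, N, chunk):
        P = thetas[start : start + chunk]
        B = P.shape[0]
        x0 = np.stack([model.initial_state(P[i], experiment) for i in range(B)], axis=1)
        blown = np.zeros(B, dtype=bool)

        def rhs(ti, xf):
            x = xf.reshape(model.n_states, B)
            bad = ~np.all(np.isfinite(x), axis=0) | (
                np.max(np.abs(np.where(np.isfinite(x), x, 0.0)), axis=0) > _STATE_BOUND
            )
            blown[bad] = True
            with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
                d = model.f_batch(x, P, u(ti), ti)
            d[:, blown] = 0.0  # freeze diverged samples; flagged NaN afterwards
            return d.ravel()

        sol = solve_ivp(
            rhs, (t[0], t[-1]), x0.ravel(), t_eval=t, method="RK45", rtol=rtol, atol=atol
        )
        if sol.success:
            states = sol.y.reshape(model.n_states, B, t.size)
            for i in range(B):
                if blown[i] or not np.all(np.isfinite(states[:, i, :])):
                    continue
                out[start + i] = _observe(model, states[:, i, :], P[i], t.size)
        else:  # a pathological chunk can sink the stacked solve: per-sample fallback
            for i in range(B):
                try:
                    out[start + i] = simulate(
                        model, P[i], experiment, rtol=rtol, atol=atol
                    ).outputs
                except (IntegrationFailure, ModelValidationError):
                    pass
    return out


def _observe(model: ODEModelSpec, states: np.ndarray, theta: np.ndarray, T: int) -> np.ndarray:
    """Apply the observation map to an (n_states, T) state matrix.

    Tries one vectorised call first (valid when h is built from elementwise
    array operations, as all packaged benchmarks are) and falls back to a
    per-time-point loop when the result shape does not check out.
    """
    try:
        y = np.asarray(model.h(states, theta), dtype=float)
        if y.shape == (T,) and model.n_outputs == 1:
            return y[:, None]
        if y.shape == (model.n_outputs, T):
            return y.T
    except Exception:
        pass
    y = np.stack(
        [np.asarray(model.h(states[:, i], theta), dtype=float) for i in range(T)]
    )
    if y.ndim == 1:
        y = y[:, None]
    return y


# ---------------------------------------------------------------------------
# Benchmarks
# ---------------------------------------------------------------------------


def _biexp() -> ODEModelSpec:
    def closed_form(theta, t, experiment=None):
        return (np.exp(-theta[0] * t) + np.exp(-theta[1] * t))[:, None]

    def closed_form_batch(thetas, t, experiment=None):
        y = np.exp(-np.multiply.outer(thetas[:, 0], t)) + np.exp(
            -np.multiply.outer(thetas[:, 1], t)
        )
        return y[:, :, None]

    def f(x, theta, u, t):
        return np.array([-theta[0] * x[0], -theta[1] * x[1]])

    def h(x, theta):
        return np.array([x[0] + x[1]])

    return ODEModelSpec(
        name="biexp",
        n_params=2,
        n_states=2,
        n_outputs=1,
        f=f,
        h=h,
        x0=lambda theta, exp: np.array([1.0, 1.0]),
        closed_form=closed_form,
        closed_form_batch=closed_form_batch,
        param_names=("theta1", "theta2"),
    )


def _lti_diag() -> ODEModelSpec:
    """Two-state diagonal linear system, y = x1(0) e^{-th1 t} + x2(0) e^{-th2 t}."""

    def closed_form(theta, t, experiment):
        a, b = experiment.x0_values
        return (a * np.exp(-theta[0] * t) + b * np.exp(-theta[1] * t))[:, None]

    def closed_form_batch(thetas, t, experiment):
        a, b = experiment.x0_values
        y = a * np.exp(-np.multiply.outer(thetas[:, 0], t)) + b * np.exp(
            -np.multiply.outer(thetas[:, 1], t)
        )
        return y[:, :, None]

    def f(x, theta, u, t):
        return np.array([-theta[0] * x[0], -theta[1] * x[1]])

    def h(x, theta):
        return np.array([x[0] + x[1]])

    return ODEModelSpec(
        name="lti_diag",
        n_params=2,
        n_states=2,
        n_outputs=1,
        f=f,
        h=h,
        closed_form=closed_form,
        closed_form_batch=closed_form_batch,
        param_names=("theta1", "theta2"),
    )


# Michaelis constants folded into the cascade kinetics (fixed, not scanned).
_MITOTIC_VM1 = 3.0   # 1/min, max cdc2 activation rate
_MITOTIC_VM3 = 1.0   # 1/min, max protease activation rate
_MITOTIC_KC = 0.5    # uM, cyclin activation threshold

_MITOTIC_PARAMS = ("v_i", "v_d", "k_d", "K_d", "K_1", "K_2", "K_3", "K_4", "V_2", "V_4")
_HIV_PARAMS = ("s", "mu_T", "r", "k_1", "k_2", "mu_b", "N_v", "mu_v")
_HIV_TMAX = 1500.0   # cells/mm^3, T-cell carrying capacity (fixed)


def _mitotic() -> ODEModelSpec:
    def f(x, theta, u, t):
        v_i, v_d, k_d, K_d, K_1, K_2, K_3, K_4, V_2, V_4 = theta
        C, M, X = x
        V_1 = _MITOTIC_VM1 * C / (_MITOTIC_KC + C)
        V_3 = _MITOTIC_VM3 * M
        return np.array(
            [
                v_i - v_d * X * C / (K_d + C) - k_d * C,
                V_1 * (1.0 - M) / (K_1 + 1.0 - M) - V_2 * M / (K_2 + M),
                V_3 * (1.0 - X) / (K_3 + 1.0 - X) - V_4 * X / (K_4 + X),
            ]
        )

    def h(x, theta):
        return np.asarray(x)

    def f_batch(x, thetas, u, t):
        C, M, X = x
        v_i, v_d, k_d, K_d, K_1, K_2, K_3, K_4, V_2, V_4 = thetas.T
        V_1 = _MITOTIC_VM1 * C / (_MITOTIC_KC + C)
        V_3 = _MITOTIC_VM3 * M
        d = np.empty_like(x)
        d[0] = v_i - v_d * X * C / (K_d + C) - k_d * C
        d[1] = V_1 * (1.0 - M) / (K_1 + 1.0 - M) - V_2 * M / (K_2 + M)
        d[2] = V_3 * (1.0 - X) / (K_3 + 1.0 - X) - V_4 * X / (K_4 + X)
        return d

    return ODEModelSpec(
        name="mitotic_oscillator",
        n_params=10,
        n_states=3,
        n_outputs=3,
        f=f,
        h=h,
        f_batch=f_batch,
        param_names=_MITOTIC_PARAMS,
    )


def _hiv() -> ODEModelSpec:
    def f(x, theta, u, t):
        s, mu_T, r, k_1, k_2, mu_b, N_v, mu_v = theta
        T, Tl, Ta, V = x
        total = T + Tl + Ta
        return np.array(
            [
                s - mu_T * T + r * T * (1.0 - total / _HIV_TMAX) - k_1 * V * T,
                k_1 * V * T - mu_T * Tl - k_2 * Tl,
                k_2 * Tl - mu_b * Ta,
                N_v * mu_b * Ta - k_1 * V * T - mu_v * V,
            ]
        )

    def h(x, theta):
        return np.asarray(x[3])[None] if np.ndim(x[3]) == 0 else np.asarray(x[3])[None, :]

    def f_batch(x, thetas, u, t):
        T, Tl, Ta, V = x
        s, mu_T, r, k_1, k_2, mu_b, N_v, mu_v = thetas.T
        total = T + Tl + Ta
        d = np.empty_like(x)
        d[0] = s - mu_T * T + r * T * (1.0 - total / _HIV_TMAX) - k_1 * V * T
        d[1] = k_1 * V * T - mu_T * Tl - k_2 * Tl
        d[2] = k_2 * Tl - mu_b * Ta
        d[3] = N_v * mu_b * Ta - k_1 * V * T - mu_v * V
        return d

    return ODEModelSpec(
        name="hiv",
        n_params=8,
        n_states=4,
        n_outputs=1,
        f=f,
        h=h,
        f_batch=f_batch,
        param_names=_HIV_PARAMS,
    )


_FACTORIES = {
    "biexp": _biexp,
    "lti_diag": _lti_diag,
    "mitotic_oscillator": _mitotic,
    "hiv": _hiv,
}


def make_benchmark(name: str) -> ODEModelSpec:
    """Return one of the packaged benchmark models by name."""
    try:
        return _FACTORIES[name]()
    except KeyError:
        raise ModelValidationError(
            f"unknown benchmark {name!r}; choose from {sorted(_FACTORIES)}"
        ) from None


def load_fixture_parameters(name: str) -> dict:
    """Load the documented nominal parameter values for a benchmark.

    Fixtures are plain-text files of ``key = value`` lines with citation
    comments; returned as an ordered name -> value mapping.
    """
    fname = {"mitotic_oscillator": "mitotic_oscillator.txt", "hiv": "hiv.txt"}.get(name)
    if fname is None:
        raise ModelValidationError(f"no parameter fixture for {name!r}")
    text = (
        importlib.resources.files("sloppyscan").joinpath("fixtures", fname).read_text()
    )
    params = {}
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, val = line.partition("=")
        params[key.strip()] = float(val)
    return params


def default_experiment(name: str) -> ExperimentCondition:
    """A sensible default experiment (initial conditions + time grid) per benchmark."""
    if name in ("biexp", "lti_diag"):
        # 0-20 s sampled every 0.5 s, the standard grid for the two-parameter toys
        return ExperimentCondition(
            x0_values=np.array([1.0, 1.0]), time_grid=np.arange(0.0, 20.0 + 1e-9, 0.5)
        )
    if name == "mitotic_oscillator":
        # ~4 oscillation periods at 1 min sampling; small positive start
        return ExperimentCondition(
            x0_values=np.array([0.01, 0.01, 0.01]),
            time_grid=np.arange(0.0, 100.0 + 1e-9, 1.0),
        )
    if name == "hiv":
        # primary-infection transient through the viral peak, days
        return ExperimentCondition(
            x0_values=np.array([1000.0, 0.0, 0.0, 1e-3]),
            time_grid=np.arange(0.0, 1200.0 + 1e-9, 10.0),
        )
    raise ModelValidationError(f"unknown benchmark {name!r}")


def nominal_theta(name: str) -> np.ndarray:
    """Nominal (reference) parameter vector for a benchmark."""
    if name == "biexp":
        return np.array([1.0, 10.0])
    if name == "lti_diag":
        return np.array([1.0, 10.0])
    params = load_fixture_parameters(name)
    model = make_benchmark(name)
    return np.array([params[p] for p in model.param_names])


def linear_predictor(X: np.ndarray) -> ODEModelSpec:
    """A degenerate (no-dynamics) model whose trajectory is y = X theta.

    The "time grid" is the observation index 0..m-1; each observation is one
    output sample.  Used to connect the shell scanner and the linear theory.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.size == 0:
        raise ModelValidationError("design matrix must be 2-D and non-empty")
    m, n = X.shape

    def closed_form(theta, t, experiment=None):
        return (X @ theta)[:, None]

    def closed_form_batch(thetas, t, experiment=None):
        return (thetas @ X.T)[:, :, None]

    model = ODEModelSpec(
        name="linear_predictor",
        n_params=n,
        n_states=0,
        n_outputs=1,
        closed_form=closed_form,
        closed_form_batch=closed_form_batch,
        param_names=tuple(f"a{i + 1}" for i in range(n)),
    )
    model.design = X  # attach for the linear theory helpers
    return model


def predictor_experiment(model: ODEModelSpec) -> ExperimentCondition:
    """Experiment for a linear predictor: the observation index grid."""
    m = model.design.shape[0]
    return ExperimentCondition(x0_values=np.zeros(0), time_grid=np.arange(float(m)))
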