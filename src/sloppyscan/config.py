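"""Run configuration: a lossless, serialisable description of one analysis.

A RunConfig holds everything needed to reproduce a scan bit-identically:
the model name, reference parameters, experiment, scan settings and verdict
overrides.  It round-trips through YAML, and every run writes it (with the
seed made explicit) into the output manifest before any computation.
"""

from __future__ import annotations

import secrets
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml

from . import models as _models
from .ballscan import ShellScanConfig
from .models import ExperimentCondition, ModelValidationError, ODEModelSpec

__all__ = ["RunConfig", "build_model", "build_experiment", "auto_scale"]


@dataclass
class RunConfig:
    """Plain-data description of one scan or classical analysis."""

    model: str
    theta_ref: list
    delta_total: float = 0.3
    n_shells: int = 30
    N0: int = 20000
    alpha: float = 1000.0
    seed: Optional[int] = None
    scale: Optional[str] = None       # None -> auto (log when theta spans >2 decades)
    zero_tol: float = 1e-8
    refine: bool = True
    rtol: float = 1e-8
    atol: float = 1e-10
    x0: Optional[list] = None         # None -> benchmark default experiment
    t_start: Optional[float] = None
    t_stop: Optional[float] = None
    t_step: Optional[float] = None
    eps: Optional[float] = None       # verdict overrides
    delta: Optional[float] = None
    outputs: str = "results"

    def resolved_seed(self) -> int:
        """The seed actually used; drawn once and recorded when unset."""
        if self.seed is None:
            self.seed = secrets.randbelow(2**31)
        return int(self.seed)

    def resolved_scale(self) -> str:
        if self.scale in ("linear", "log"):
            return self.scale
        return auto_scale(np.asarray(self.theta_ref, dtype=float))

    def to_yaml(self, path: Union[str, Path, None] = None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: Union[str, Path]) -> "RunConfig":
        path = Path(source)
        text = path.read_text() if path.exists() else str(source)
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ModelValidationError("config file must be a key-value mapping")
        return cls(**data)

    def scan_config(self) -> ShellScanConfig:
        return ShellScanConfig(
            theta_ref=np.asarray(self.theta_ref, dtype=float),
            delta_total=self.delta_total,
            n_shells=self.n_shells,
            N0=self.N0,
            alpha=self.alpha,
            seed=self.resolved_seed(),
            scale=self.resolved_scale(),
            zero_tol=self.zero_tol,
            refine=self.refine,
            rtol=self.rtol,
            atol=self.atol,
        )

    def manifest(self) -> dict:
        self.resolved_seed()
        data = asdict(self)
        data["scale"] = self.resolved_scale()
        return data


def auto_scale(theta: np.ndarray) -> str:
    """'log' when parameters span more than two decades, else 'linear'."""
    theta = np.asarray(theta, dtype=float)
    if np.any(theta <= 0):
        return "linear"
    lg = np.log10(theta)
    return "log" if (lg.max() - lg.min()) > 2.0 else "linear"


def build_model(name: str) -> ODEModelSpec:
    if name not in _models.BENCHMARK_NAMES:
        raise ModelValidationError(
            f"unknown model {name!r}; choose from {list(_models.BENCHMARK_NAMES)}"
        )
    return _models.make_benchmark(name)


def build_experiment(config: RunConfig, model: ODEModelSpec) -> ExperimentCondition:
    base = _models.default_experiment(config.model)
    x0 = np.asarray(config.x0, dtype=float) if config.x0 is not None else base.x0_values
    if config.t_stop is not None:
        start = config.t_start if config.t_start is not None else 0.0
        step = config.t_step if config.t_step is not None else (config.t_stop - start) / 40
        grid = np.arange(start, config.t_stop + 1e-9, step)
    else:
        grid = base.time_grid
    return ExperimentCondition(x0_values=x0, time_grid=grid)
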