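"""Figures and tables for the visual sloppiness-assessment tool.

Renders psi-vs-delta and gamma_min-vs-delta curves, per-parameter profile
panels, direction-cosine heat maps and classical grid-scan maps, and bundles
them with their tables and a manifest sufficient to re-run the scan.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .ballscan import ShellScanResult
from .models import ModelValidationError

__all__ = [
    "ReportBundle",
    "plot_sensitivity",
    "plot_gamma_min",
    "plot_profiles",
    "plot_cosine_heatmap",
    "plot_grid_scan",
]

ResultOrResults = Union[ShellScanResult, Sequence[ShellScanResult]]


def _as_list(results: ResultOrResults) -> list[ShellScanResult]:
    if isinstance(results, ShellScanResult):
        return [results]
    return list(results)


def plot_sensitivity(
    results: ResultOrResults, labels: Optional[Sequence[str]] = None
):
    """Model sensitivity index psi against shell radius, reference line at 1."""
    results = _as_list(results)
    fig, ax = plt.subplots(figsize=(6, 4))
    for i, res in enumerate(results):
        label = labels[i] if labels else None
        ax.plot(res.shell_radii, res.psi, marker="o", ms=3, label=label)
    ax.axhline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_ylim(0.0, 1.05)
    scale = results[0].config.scale
    ax.set_xlabel(rf"shell radius $\delta_k$ ({scale}-parameter units)")
    ax.set_ylabel(r"sensitivity index $\psi$")
    if labels:
        ax.legend()
    fig.tight_layout()
    return fig


def plot_gamma_min(
    results: ResultOrResults,
    labels: Optional[Sequence[str]] = None,
    log_y: bool = False,
    zero_tol_band: bool = True,
):
    """gamma_min against shell radius with the numerically-zero band drawn."""
    results = _as_list(results)
    fig, ax = plt.subplots(figsize=(6, 4))
    for i, res in enumerate(results):
        label = labels[i] if labels else None
        ax.plot(res.shell_radii, res.gamma_min, marker="o", ms=3, label=label)
    if zero_tol_band:
        tol = max(
            res.config.zero_tol * res.gamma_max_global for res in results
        )
        if tol > 0:
            ax.axhspan(0.0, tol, color="red", alpha=0.15, lw=0)
    if log_y:
        ax.set_yscale("log")
    scale = results[0].config.scale
    ax.set_xlabel(rf"shell radius $\delta_k$ ({scale}-parameter units)")
    ax.set_ylabel(r"$\gamma_{\min}$")
    if labels:
        ax.legend()
    fig.tight_layout()
    return fig


def plot_profiles(profiles: Mapping[str, pd.DataFrame], log_y: bool = False):
    """One panel per parameter: binned gamma_min (left) and gamma_max (right axis)."""
    if not profiles:
        raise ModelValidationError("no profiles to plot")
    names = list(profiles)
    ncols = min(5, len(names))
    nrows = int(np.ceil(len(names) / ncols))
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(3.2 * ncols, 2.6 * nrows), squeeze=False
    )
    for ax in axes.ravel()[len(names):]:
        ax.set_visible(False)
    for ax, name in zip(axes.ravel(), names):
        df = profiles[name]
        ax.plot(df["bin_center"], df["gamma_min"], color="tab:blue", marker=".", ms=3)
        ax.set_ylabel(r"$\gamma_{\min}$", color="tab:blue", fontsize=8)
        twin = ax.twinx()
        twin.plot(df["bin_center"], df["gamma_max"], color="tab:red", marker=".", ms=3)
        twin.set_ylabel(r"$\gamma_{\max}$", color="tab:red", fontsize=8)
        if log_y:
            ax.set_yscale("log")
            twin.set_yscale("log")
        ax.set_title(name, fontsize=9)
        ax.set_xlabel(r"$|\theta_i - \theta_i^*|$", fontsize=8)
        ax.tick_params(labelsize=7)
        twin.tick_params(labelsize=7)
    fig.tight_layout()
    return fig


def plot_cosine_heatmap(matrix: np.ndarray, title: str = "direction cosines"):
    """Heat map of a symmetric cosine matrix, diverging palette centred at 0."""
    M = np.asarray(matrix, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ModelValidationError("cosine matrix must be square")
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(M, cmap="RdBu_r", vmin=-1.0, vmax=1.0, origin="lower")
    fig.colorbar(im, ax=ax, label=r"$\cos\angle$")
    ax.set_xlabel("shell index")
    ax.set_ylabel("shell index")
    ax.set_title(title)
    fig.tight_layout()
    return fig


def plot_grid_scan(table: pd.DataFrame, x: str, y: str, value: str = "S"):
    """Map of classical sloppiness S over a 2-D grid (log10 colour scale)."""
    pivot = table.pivot_table(index=y, columns=x, values=value)
    fig, ax = plt.subplots(figsize=(5.5, 4))
    with np.errstate(divide="ignore"):
        Z = np.log10(pivot.to_numpy())
    im = ax.pcolormesh(pivot.columns, pivot.index, Z, shading="auto", cmap="viridis")
    fig.colorbar(im, ax=ax, label=rf"$\log_{{10}}$ {value}")
    ax.set_xlabel(x)
    ax.set_ylabel(y)
    fig.tight_layout()
    return fig


@dataclass
class ReportBundle:
    """Figures, tables and the manifest of one run; saveable to a directory."""

    figures: dict = field(default_factory=dict)
    tables: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    def save(self, outdir: Union[str, Path], formats: Sequence[str] = ("png", "svg")) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "manifest.json").write_text(json.dumps(self.manifest, indent=2))
        for name, table in self.tables.items():
            if isinstance(table, pd.DataFrame):
                table.to_csv(outdir / f"{name}.csv", index=False)
            else:
                (outdir / f"{name}.json").write_text(json.dumps(table, indent=2))
        for name, fig in self.figures.items():
            for fmt in formats:
                fig.savefig(outdir / f"{name}.{fmt}", dpi=150)
            plt.close(fig)
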