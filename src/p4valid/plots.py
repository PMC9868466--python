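"""Diagnostic plots for the validation report bundle."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .comparison import BlandAltmanResult, PassingBablokFit
from .core_io import PairedComparison
from .linearity import LinearityFit
from .precision import PrecisionProfile


def plot_linearity(
    spiked: Sequence[float],
    measured: Sequence[float],
    fit: LinearityFit,
    path: str | Path,
) -> Path:
    """Measured-versus-spiked scatter with the fit and the identity line."""
    x = np.asarray(spiked, dtype=float)
    y = np.asarray(measured, dtype=float)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(x, y, zorder=3)
    grid = np.linspace(0, x.max() * 1.05, 50)
    ax.plot(grid, grid, ls="--", color="orange", label="identity")
    ax.plot(grid, fit.intercept + fit.slope * grid, color="tab:blue",
            label=f"fit: y = {fit.intercept:.2f} + {fit.slope:.3f}x")
    ax.set_xlabel("spiked [P4] (ng/mL)")
    ax.set_ylabel("measured mean [P4] (ng/mL)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_cv_profile(profile: PrecisionProfile, path: str | Path) -> Path:
    """Within/between-run CV% against spiked concentration, with trendline."""
    rows = [r for r in profile.levels if r.spiked > 0]
    conc = np.array([r.spiked for r in rows])
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(conc, [r.within_cv_pct for r in rows], "o-", label="within-run")
    if all(r.between_cv_pct is not None for r in rows):
        ax.plot(conc, [r.between_cv_pct for r in rows], "s--", label="between-run")
    if profile.trendline is not None:
        grid = np.geomspace(conc.min(), conc.max(), 100)
        ax.plot(grid, [profile.trendline.predict(c) for c in grid],
                color="gray", lw=1, label=f"trend ({profile.trendline.form})")
    ax.set_xscale("log")
    ax.set_xlabel("spiked [P4] (ng/mL)")
    ax.set_ylabel("CV (%)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_passing_bablok(
    pairs: PairedComparison, fit: PassingBablokFit, path: str | Path
) -> Path:
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(pairs.a, pairs.b, zorder=3)
    grid = np.linspace(0, pairs.a.max() * 1.05, 50)
    ax.plot(grid, grid, ls="--", color="orange", label="identity")
    ax.plot(grid, fit.intercept + fit.slope * grid, color="tab:blue",
            label=f"PB: y = {fit.intercept:.2f} + {fit.slope:.3f}x")
    ax.set_xlabel(f"{pairs.label_a} [P4] (ng/mL)")
    ax.set_ylabel(f"{pairs.label_b} [P4] (ng/mL)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_bland_altman(
    pairs: PairedComparison, ba: BlandAltmanResult, path: str | Path
) -> Path:
    a, b = pairs.a, pairs.b
    means = (a + b) / 2.0
    d = 100.0 * (a - b) / means if ba.mode == "percent" else a - b
    unit = "%" if ba.mode == "percent" else "ng/mL"
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(means, d, zorder=3)
    ax.axhline(0, color="tab:blue", lw=1, ls="--")
    ax.axhline(ba.mean_bias, color="black", label=f"bias {ba.mean_bias:.1f}{unit}")
    for loa in (ba.loa_lower, ba.loa_upper):
        ax.axhline(loa, color="maroon", ls="--")
    ax.set_xlabel("pair mean [P4] (ng/mL)")
    ax.set_ylabel(f"difference {pairs.label_a} - {pairs.label_b} ({unit})")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
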