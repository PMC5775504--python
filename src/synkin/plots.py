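"""Optional figures: survival ln-curve, PSI dot plots, overlap contour."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np

from .shape_metrics import ContourSummary
from .spot_survival import SurvivalFit

__all__ = ["plot_survival", "plot_psi_dots", "plot_overlap_contour"]


def plot_survival(fit: SurvivalFit, path: str | Path, title: str = "") -> None:
    """Percent-remaining curve with its ln-linear fit."""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(8, 3.2))
    valid = np.isfinite(fit.percent_remaining)
    ax1.plot(fit.times[valid], fit.percent_remaining[valid], "o-")
    ax1.set(xlabel="time (h)", ylabel="% remaining", ylim=(0, 105))
    usable = np.isfinite(fit.ln_percent)
    ax2.plot(fit.times[usable], fit.ln_percent[usable], "o")
    ax2.plot(fit.times[usable], fit.intercept + fit.slope * fit.times[usable], "-")
    ax2.set(xlabel="time (h)", ylabel="ln(% remaining)")
    label = f"t1/2 = {fit.half_life:.2f} h, r² = {fit.r_squared:.3f}"
    fig.suptitle(f"{title} {label}".strip())
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_psi_dots(groups: Mapping[str, Sequence[float]], path: str | Path) -> None:
    """Dot plot of positional stability indices per group with mean bars."""
    fig, ax = plt.subplots(figsize=(1.6 * max(len(groups), 2), 3.2))
    rng = np.random.default_rng(0)  # fixed jitter for reproducible figures
    for i, (name, values) in enumerate(groups.items()):
        values = np.asarray(list(values), dtype=float)
        x = i + rng.uniform(-0.12, 0.12, size=len(values))
        ax.plot(x, values, "o", alpha=0.7)
        ax.hlines(values.mean(), i - 0.25, i + 0.25, color="red")
    ax.set_xticks(range(len(groups)), list(groups))
    ax.set_ylabel("positional stability index")
    ax.set_ylim(-0.05, 1.05)
    ax.axhline(0.5, color="grey", lw=0.5, ls="--")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_overlap_contour(summary: ContourSummary, path: str | Path) -> None:
    """2D density of (area ratio, fractional overlap) with the m boundary trace."""
    fig, ax = plt.subplots(figsize=(4.2, 3.4))
    ax.contourf(
        0.5 * (summary.ratio_edges[:-1] + summary.ratio_edges[1:]),
        0.5 * (summary.overlap_edges[:-1] + summary.overlap_edges[1:]),
        summary.hist.T,
        levels=8,
        cmap="Reds",
    )
    ax.plot(summary.trace_ratio, summary.trace_m, color="orange", lw=2,
            label="max possible overlap")
    ax.set(xlabel="cell area / spot area", ylabel="fractional overlap",
           ylim=(0, 1.02))
    ax.legend(loc="lower left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
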