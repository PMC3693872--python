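"""Plot helpers: the median-effect plot and the fa-CI curve."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from ctsynergy.assay import DoseResponseTable
from ctsynergy.combination import CombinationAnalysis, ci_curve
from ctsynergy.median_effect import MedianEffectFit

__all__ = ["median_effect_plot", "fa_ci_plot"]


def median_effect_plot(
    items: Sequence[tuple[DoseResponseTable, MedianEffectFit]],
    path: str | Path,
) -> None:
    """log10(D) vs log10(fa/fu) with the fitted lines, one series per pair."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for table, fit in items:
        doses, fas = table.fit_points("replicate-means")
        x = np.log10(doses)
        y = np.log10(np.array(fas) / (1.0 - np.array(fas)))
        (line,) = ax.plot(x, y, "o", label=f"{table.condition} (m={fit.m:.2f}, Dm={fit.dm:.3g})")
        xs = np.linspace(x.min(), x.max(), 50)
        ax.plot(xs, fit.m * (xs - np.log10(fit.dm)), "-", color=line.get_color(), alpha=0.7)
    ax.set_xlabel("log10 dose (uM)")
    ax.set_ylabel("log10(fa / fu)")
    ax.axhline(0.0, color="grey", lw=0.5)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def fa_ci_plot(analysis: CombinationAnalysis, path: str | Path, n_grid: int = 60) -> None:
    """Combination index across effect levels fa in [0.05, 0.95]."""
    grid = np.linspace(0.05, 0.95, n_grid)
    curve = ci_curve(analysis.fit1, analysis.fit2, analysis.fit_combo, analysis.design, grid)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(curve["fa"], curve["ci"], "-")
    ax.axhline(1.0, color="grey", ls="--", lw=0.8, label="additivity (CI = 1)")
    ax.plot([analysis.reference_fa], [analysis.ci], "ro", label=f"CI({analysis.reference_fa:g}) = {analysis.ci:.3f}")
    ax.set_xlabel("fraction affected (fa)")
    ax.set_ylabel("combination index (CI)")
    ax.set_yscale("log")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
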