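"""Optional figures for the agreement analysis (matplotlib, Agg-safe).

All numerical results live in the CSV/JSON reports; these plots are
presentation-only and are never produced unless explicitly requested.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .agreement import (
    BlandAltmanResult,
    PairedMeasurements,
    RegressionResult,
    pair_means,
)

__all__ = ["plot_method_scatter", "plot_bland_altman"]


def plot_method_scatter(
    pairs: PairedMeasurements,
    regression: RegressionResult,
    path: str | Path,
    label_a: str = "method A",
    label_b: str = "method B",
) -> None:
    """Scatter of method-A versus method-B values with the fitted OLS line."""
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(pairs.values_b, pairs.values_a, s=18, alpha=0.8)
    grid = np.linspace(pairs.values_b.min(), pairs.values_b.max(), 50)
    ax.plot(
        grid,
        regression.intercept + regression.slope * grid,
        "r--",
        label=f"fit: a = {regression.intercept:.3f} + {regression.slope:.3f} b  "
        f"(R² = {regression.r_squared:.3f})",
    )
    ax.set_xlabel(f"normalized max slope, {label_b} (s⁻¹)")
    ax.set_ylabel(f"normalized max slope, {label_a} (s⁻¹)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_bland_altman(
    pairs: PairedMeasurements,
    result: BlandAltmanResult,
    path: str | Path,
) -> None:
    """Difference-versus-mean plot with bias and limit-of-agreement lines."""
    means = pair_means(pairs)
    if result.mode == "relative_percent":
        diffs = 100.0 * (pairs.values_a - pairs.values_b) / means
        ylabel = "relative difference (%)"
    else:
        diffs = pairs.values_a - pairs.values_b
        ylabel = "difference (s⁻¹)"
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(means, diffs, s=18, alpha=0.8)
    ax.axhline(result.mean_difference_d, color="red", label=f"d = {result.mean_difference_d:.3g}")
    for limit in (result.loa_lower, result.loa_upper):
        ax.axhline(limit, color="green", linestyle="--")
    ax.axhline(0.0, color="gray", linewidth=0.6)
    ax.set_xlabel("mean of the two methods (s⁻¹)")
    ax.set_ylabel(ylabel)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
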