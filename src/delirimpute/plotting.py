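"""Panel figures for grid results: bias, mean SE and coverage.

Layout mirrors the simulation report: one panel per mechanism
configuration (MCAR, MAR weak/moderate/strong, MNAR weak/moderate/strong),
missingness proportion on the x axis, one line per strategy.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_metric", "save_report"]

METRICS = {
    "bias": "Bias of the duration slope",
    "mean_se": "Mean standard error",
    "coverage": "Coverage of the nominal 95% CI",
}

_STRATEGY_STYLE = {
    "complete_case": dict(color="#555555", marker="o"),
    "adhoc_worst": dict(color="#d62728", marker="v"),
    "adhoc_best": dict(color="#ff9896", marker="^"),
    "passive_mi": dict(color="#1f77b4", marker="s"),
    "active_mi": dict(color="#2ca02c", marker="D"),
}


def _panels(results: pd.DataFrame) -> list[tuple[str, pd.DataFrame]]:
    panels = []
    for (mech, strength), sub in results.groupby(["mechanism", "strength"]):
        title = mech if mech == "MCAR" else f"{mech} (b={strength:g})"
        panels.append((title, sub))
    return panels


def plot_metric(results: pd.DataFrame, metric: str) -> plt.Figure:
    """One figure of per-mechanism panels for a single performance metric."""
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {sorted(METRICS)}")
    panels = _panels(results)
    ncols = min(4, len(panels))
    nrows = -(-len(panels) // ncols)
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(3.2 * ncols, 2.8 * nrows), sharey=True, squeeze=False
    )
    for ax in axes.flat[len(panels):]:
        ax.set_visible(False)
    for ax, (title, sub) in zip(axes.flat, panels):
        for strategy, grp in sub.groupby("strategy"):
            grp = grp.sort_values("proportion")
            style = _STRATEGY_STYLE.get(strategy, {})
            ax.plot(
                grp["proportion"], grp[metric], label=strategy, lw=1.2, ms=4, **style
            )
        if metric == "coverage":
            ax.axhline(0.95, color="black", lw=0.8)
        elif metric == "bias":
            ax.axhline(0.0, color="black", lw=0.8)
        ax.set_title(title, fontsize=9)
        ax.set_xlabel("proportion missing")
    axes[0, 0].set_ylabel(METRICS[metric])
    handles, labels = axes[0, 0].get_legend_handles_labels()
    fig.legend(handles, labels, loc="lower center", ncol=5, fontsize=8, frameon=False)
    fig.suptitle(METRICS[metric], fontsize=11)
    fig.tight_layout(rect=(0, 0.06, 1, 0.96))
    return fig


def save_report(results: pd.DataFrame, outdir) -> list[Path]:
    """Write one PNG per metric; returns the created paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for metric in METRICS:
        fig = plot_metric(results, metric)
        path = outdir / f"{metric}.png"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        paths.append(path)
    return paths
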