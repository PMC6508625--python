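"""PDF report figures with sidecar TSVs of the plotted values.

Every figure writes the numbers it draws to a TSV next to the PDF, so
downstream checks (and users) can assert on data rather than rendered
pixels. Five per-run figures cover cumulative yield, the per-bin run
trend, the joint length-quality view with marginal histograms, the
flow-cell activity heatmaps, and the pass/fail/skip + GC overview; the
comparison stage adds a violin figure across runs.
"""

from __future__ import annotations

import os
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .compare import COMPARE_METRICS, ComparisonSet, group_values
from .flowcell import activity_matrix
from .stats import RunSummary, cumulative_yield, length_quality_fit

_METRIC_TITLES = {
    "n_reads": "Reads per bin",
    "n_bases": "Bases per bin",
    "len_mean": "Mean read length per bin",
    "q_mean": "Mean read quality per bin",
}


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".tsv")


def plot_yield(table: pd.DataFrame, out_pdf: str | os.PathLike) -> Path:
    """Cumulative reads and bases over run time."""
    out_pdf = Path(out_pdf)
    series = cumulative_yield(table)
    series.to_csv(_sidecar(out_pdf), sep="\t", index=False)
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    hours = series["time"] / 3600.0
    axes[0].plot(hours, series["cum_reads"], color="tab:blue")
    axes[0].set(xlabel="Run time (h)", ylabel="Cumulative reads")
    axes[1].plot(hours, series["cum_bases"], color="tab:orange")
    axes[1].set(xlabel="Run time (h)", ylabel="Cumulative bases")
    fig.tight_layout()
    fig.savefig(out_pdf)
    plt.close(fig)
    return out_pdf


def plot_binned(binned: pd.DataFrame, out_pdf: str | os.PathLike) -> Path:
    """Per-bin reads, bases, length (min/mean/max) and quality (min/mean/max)."""
    out_pdf = Path(out_pdf)
    binned.to_csv(_sidecar(out_pdf), sep="\t", index=False, na_rep="NA")
    fig, axes = plt.subplots(2, 2, figsize=(11, 7))
    hours = binned["bin_start"] / 3600.0
    axes[0, 0].bar(hours, binned["n_reads"], width=binned["bin_width"] / 3600.0 * 0.9)
    axes[0, 0].set(xlabel="Run time (h)", ylabel="Reads")
    axes[0, 1].bar(
        hours, binned["n_bases"], width=binned["bin_width"] / 3600.0 * 0.9,
        color="tab:orange",
    )
    axes[0, 1].set(xlabel="Run time (h)", ylabel="Bases")
    for stat, color in (("len_min", "tab:green"), ("len_mean", "tab:blue"),
                        ("len_max", "tab:red")):
        axes[1, 0].plot(hours, binned[stat], label=stat, color=color)
    axes[1, 0].set(xlabel="Run time (h)", ylabel="Read length (log10)", yscale="log")
    axes[1, 0].legend(fontsize=7)
    for stat, color in (("q_min", "tab:green"), ("q_mean", "tab:blue"),
                        ("q_max", "tab:red")):
        axes[1, 1].plot(hours, binned[stat], label=stat, color=color)
    axes[1, 1].set(xlabel="Run time (h)", ylabel="Mean q-score")
    axes[1, 1].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out_pdf)
    plt.close(fig)
    return out_pdf


def plot_length_quality(table: pd.DataFrame, out_pdf: str | os.PathLike) -> Path:
    """Joint length-quality scatter with OLS line and marginal histograms."""
    out_pdf = Path(out_pdf)
    sub = table[table["length"] > 0]
    data = sub[["read_id", "length", "quality"]].copy()
    try:
        slope, intercept = length_quality_fit(table)
    except Exception:
        slope = intercept = float("nan")
    data.attrs["slope"] = slope
    with open(_sidecar(out_pdf), "w") as handle:
        handle.write(f"# ols_slope\t{slope!r}\n# ols_intercept\t{intercept!r}\n")
        data.to_csv(handle, sep="\t", index=False)
    fig = plt.figure(figsize=(8, 8))
    grid = fig.add_gridspec(2, 2, width_ratios=(4, 1), height_ratios=(1, 4),
                            hspace=0.05, wspace=0.05)
    ax = fig.add_subplot(grid[1, 0])
    ax_top = fig.add_subplot(grid[0, 0], sharex=ax)
    ax_right = fig.add_subplot(grid[1, 1], sharey=ax)
    x = np.log10(sub["length"].to_numpy(dtype=float))
    y = sub["quality"].to_numpy(dtype=float)
    ax.scatter(x, y, s=4, alpha=0.4)
    if np.isfinite(slope) and x.size:
        xs = np.linspace(x.min(), x.max(), 50)
        ax.plot(xs, slope * xs + intercept, color="tab:red")
    ax.set(xlabel="log10 read length", ylabel="Mean q-score")
    if x.size:
        ax_top.hist(x, bins=40)
        ax_right.hist(y, bins=40, orientation="horizontal")
    ax_top.tick_params(labelbottom=False)
    ax_right.tick_params(labelleft=False)
    fig.savefig(out_pdf)
    plt.close(fig)
    return out_pdf


def plot_heatmaps(table: pd.DataFrame, out_pdf: str | os.PathLike) -> Path:
    """Channel and mux base-pair productivity on the physical grid."""
    out_pdf = Path(out_pdf)
    matrices = {
        per: activity_matrix(table, per=per, metric="bases")
        for per in ("channel", "mux")
    }
    with open(_sidecar(out_pdf), "w") as handle:
        handle.write("per\trow\tcol\tbases\tactive\n")
        for per, matrix in matrices.items():
            for (r, c), value in np.ndenumerate(matrix.grid):
                handle.write(
                    f"{per}\t{r}\t{c}\t{value:.0f}\t{int(not matrix.mask[r, c])}\n"
                )
    fig, axes = plt.subplots(2, 1, figsize=(10, 9))
    for ax, (per, matrix) in zip(axes, matrices.items()):
        shown = np.ma.masked_array(matrix.grid, matrix.mask)
        cmap = plt.get_cmap("viridis").copy()
        cmap.set_bad("lightgrey")  # inactive positions are grey
        im = ax.imshow(shown, cmap=cmap, aspect="auto")
        ax.set_title(f"Base pairs per {per}")
        fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(out_pdf)
    plt.close(fig)
    return out_pdf


def plot_passfail(
    summary: RunSummary, table: pd.DataFrame, out_pdf: str | os.PathLike
) -> Path:
    """Pass/fail/skip counts & percentages, plus GC histogram when computed."""
    out_pdf = Path(out_pdf)
    counts = pd.DataFrame(
        {
            "category": ["passed", "failed", "skipped"],
            "count": [summary.n_passed, summary.n_failed, summary.n_skipped],
            "percent": [summary.pct_passed, summary.pct_failed,
                        summary.pct_skipped],
        }
    )
    counts.to_csv(_sidecar(out_pdf), sep="\t", index=False)
    gc = table["gc_content"].dropna()
    fig, axes = plt.subplots(1, 3 if len(gc) else 2, figsize=(12, 4))
    axes[0].bar(counts["category"], counts["count"],
                color=["tab:green", "tab:red", "tab:grey"])
    axes[0].set(ylabel="Reads")
    axes[1].bar(counts["category"], counts["percent"],
                color=["tab:green", "tab:red", "tab:grey"])
    axes[1].set(ylabel="Percent", ylim=(0, 100))
    if len(gc):
        axes[2].hist(gc * 100.0, bins=40, color="tab:purple")
        axes[2].set(xlabel="GC content (%)", ylabel="Reads")
    fig.tight_layout()
    fig.savefig(out_pdf)
    plt.close(fig)
    return out_pdf


def plot_comparison(
    cs: ComparisonSet, out_pdf: str | os.PathLike, group_hours: float = 10.0
) -> Path:
    """Violin panels comparing runs per coarse time group, four metrics."""
    out_pdf = Path(out_pdf)
    values = group_values(cs, group_hours=group_hours)
    values.to_csv(_sidecar(out_pdf), sep="\t", index=False, na_rep="NA")
    groups = sorted(values["group"].unique()) if len(values) else []
    fig, axes = plt.subplots(
        len(COMPARE_METRICS), 1, figsize=(2.2 * max(len(groups), 1) * len(cs.labels) / 2 + 4, 12)
    )
    for ax, metric in zip(np.atleast_1d(axes), COMPARE_METRICS):
        positions, data, ticks, labels = [], [], [], []
        pos = 0
        for g in groups:
            for label in cs.labels:
                sel = values[
                    (values["group"] == g)
                    & (values["metric"] == metric)
                    & (values["label"] == label)
                ]["value"].dropna()
                if len(sel):
                    data.append(sel.to_numpy())
                    positions.append(pos)
                    ticks.append(pos)
                    labels.append(f"{label}\n{int(g * group_hours)}h")
                pos += 1
            pos += 1
        if data:
            ax.violinplot(data, positions=positions, showmedians=True)
            ax.set_xticks(ticks)
            ax.set_xticklabels(labels, fontsize=6)
        ax.set_title(_METRIC_TITLES[metric])
    fig.tight_layout()
    fig.savefig(out_pdf)
    plt.close(fig)
    return out_pdf
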