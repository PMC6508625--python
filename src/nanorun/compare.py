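"""Cross-run comparison of persisted binned statistics.

Comparison consumes only the per-run comparison folders written by
:func:`nanorun.stats.export_comparison_data` — never raw reads. Each
run's 30-minute bins are grouped into coarse intervals (default 10
hours) and, per group and run, the distribution over that group's bins
of four metrics (reads, bases, mean length, mean quality) is
summarized with five-number statistics plus sums, enough to render
violin panels and check conservation.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DomainError
from .stats import read_comparison_folder

DEFAULT_GROUP_HOURS = 10.0
COMPARE_METRICS = ("n_reads", "n_bases", "len_mean", "q_mean")
_QUANTILE_STATS = ("min", "q1", "median", "q3", "max")


@dataclass
class ComparisonSet:
    """Aligned binned statistics for two or more labelled runs."""

    labels: list[str]
    binned: list[pd.DataFrame]
    summaries: list[dict]


def load_comparison(
    dirs: list[str | os.PathLike], labels: list[str]
) -> ComparisonSet:
    """Load two or more exported comparison folders.

    Raises
    ------
    DomainError
        On fewer than two runs, mismatched arity or duplicate labels.
    FileNotFoundError
        If a folder (named in the message) is missing.
    """
    if len(dirs) != len(labels):
        raise DomainError(
            f"{len(dirs)} folders but {len(labels)} labels — one label per run"
        )
    if len(dirs) < 2:
        raise DomainError("comparison needs at least two runs")
    if len(set(labels)) != len(labels):
        raise DomainError(f"duplicate run labels: {labels}")
    binned, summaries = [], []
    for folder in dirs:
        if not Path(folder).is_dir():
            raise FileNotFoundError(f"comparison folder not found: {folder}")
        b, s = read_comparison_folder(folder)
        binned.append(b)
        summaries.append(s)
    return ComparisonSet(labels=list(labels), binned=binned, summaries=summaries)


def group_bins(
    cs: ComparisonSet, group_hours: float = DEFAULT_GROUP_HOURS
) -> pd.DataFrame:
    """Group each run's bins into coarse intervals and summarize.

    Bin ``b`` belongs to group ``floor(bin_start / group_width)``. Count
    metrics include empty bins (a silent half hour is a zero, not a
    gap); the mean-length/mean-quality distributions use defined bins
    only. Runs shorter than a group contribute only their existing bins.

    Returns a tidy frame: label, group, metric, statistic, value.
    """
    if group_hours <= 0:
        raise DomainError("group_hours must be positive")
    width = group_hours * 3600.0
    rows: list[tuple[str, int, str, str, float]] = []
    for label, binned in zip(cs.labels, cs.binned):
        if len(binned) == 0:
            continue
        groups = np.floor(binned["bin_start"].to_numpy() / width).astype(np.int64)
        for g in np.unique(groups):
            sub = binned[groups == g]
            for metric in COMPARE_METRICS:
                values = sub[metric].to_numpy(dtype=np.float64)
                if metric in ("len_mean", "q_mean"):
                    values = values[~np.isnan(values)]
                if values.size == 0:
                    continue
                quantiles = np.percentile(values, [0, 25, 50, 75, 100])
                for name, value in zip(_QUANTILE_STATS, quantiles):
                    rows.append((label, int(g), metric, name, float(value)))
                if metric in ("n_reads", "n_bases"):
                    rows.append((label, int(g), metric, "sum", float(values.sum())))
    return pd.DataFrame(
        rows, columns=["label", "group", "metric", "statistic", "value"]
    )


def group_values(
    cs: ComparisonSet, group_hours: float = DEFAULT_GROUP_HOURS
) -> pd.DataFrame:
    """Per-bin values tagged by group (tidy; raw material for violins)."""
    if group_hours <= 0:
        raise DomainError("group_hours must be positive")
    width = group_hours * 3600.0
    frames = []
    for label, binned in zip(cs.labels, cs.binned):
        if len(binned) == 0:
            continue
        melted = binned.melt(
            id_vars=["bin_start"],
            value_vars=list(COMPARE_METRICS),
            var_name="metric",
            value_name="value",
        )
        melted["label"] = label
        melted["group"] = np.floor(
            melted["bin_start"].to_numpy() / width
        ).astype(np.int64)
        frames.append(melted[["label", "group", "metric", "value"]])
    if not frames:
        return pd.DataFrame(columns=["label", "group", "metric", "value"])
    return pd.concat(frames, ignore_index=True)
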