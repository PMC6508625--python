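"""Run-level statistics: yield, time-binned aggregates, overview, export.

Reads are binned by start time into fixed-width bins (default 30
minutes, the interval the run trend plots use). Bins tile
``[0, run_end]`` with no gaps: empty bins are present with ``n_reads=0``
and undefined aggregates as NaN (serialized "NA"), which keeps the
tiling explicit for plotting. All statistics are computed on passed
reads only; failed and skipped units enter the overview counts alone.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .dataset import RunDataset
from .errors import DegenerateFitError, DomainError

DEFAULT_BIN_WIDTH = 1800.0  # seconds: the 30-minute trend interval

BINNED_COLUMNS = (
    "bin_index",
    "bin_start",
    "bin_width",
    "n_reads",
    "n_bases",
    "len_min",
    "len_mean",
    "len_max",
    "q_min",
    "q_mean",
    "q_max",
)


def bin_reads(table: pd.DataFrame, bin_width: float = DEFAULT_BIN_WIDTH) -> pd.DataFrame:
    """Aggregate the metadata table into fixed-width time bins.

    A read starting at ``t`` lands in bin ``floor(t / bin_width)``. The
    result covers bin 0 through the bin of the latest read, including
    empty bins. An empty table yields an empty frame.
    """
    if bin_width <= 0:
        raise DomainError("bin_width must be positive")
    if len(table) == 0:
        return pd.DataFrame(columns=list(BINNED_COLUMNS))
    idx = np.floor(table["start_time"].to_numpy() / bin_width).astype(np.int64)
    n_bins = int(idx.max()) + 1
    rows = []
    lengths = table["length"].to_numpy()
    quals = table["quality"].to_numpy()
    for b in range(n_bins):
        sel = idx == b
        n = int(sel.sum())
        if n:
            lens, qs = lengths[sel], quals[sel]
            agg = (
                int(lens.sum()),
                float(lens.min()), float(lens.mean()), float(lens.max()),
                float(qs.min()), float(qs.mean()), float(qs.max()),
            )
        else:
            agg = (0,) + (float("nan"),) * 6
        rows.append((b, b * bin_width, bin_width, n) + agg)
    return pd.DataFrame(rows, columns=list(BINNED_COLUMNS))


def cumulative_yield(table: pd.DataFrame) -> pd.DataFrame:
    """Running reads and bases over time (columns: time, cum_reads, cum_bases)."""
    ordered = table.sort_values(["start_time", "read_id"], kind="mergesort")
    return pd.DataFrame(
        {
            "time": ordered["start_time"].to_numpy(),
            "cum_reads": np.arange(1, len(ordered) + 1, dtype=np.int64),
            "cum_bases": np.cumsum(ordered["length"].to_numpy()),
        }
    )


def length_quality_fit(table: pd.DataFrame) -> tuple[float, float]:
    """OLS of quality on log10(length).

    Longer nanopore reads tend to carry higher mean quality; the slope
    quantifies that trend on the log-length scale used by the joint plot.
    Zero-length reads cannot enter the fit.

    Returns ``(slope, intercept)``.
    """
    sub = table[table["length"] > 0]
    x = np.log10(sub["length"].to_numpy(dtype=np.float64))
    y = sub["quality"].to_numpy(dtype=np.float64)
    if len(sub) < 2 or np.unique(sub["length"]).size < 2:
        raise DegenerateFitError("need >= 2 rows with distinct positive lengths")
    fit = sps.linregress(x, y)
    return float(fit.slope), float(fit.intercept)


@dataclass
class RunSummary:
    """Overview of one sequencing run (the ShortSummary record)."""

    label: str
    total_reads: int
    total_bases: int
    run_duration_hours: float
    len_min: float
    len_mean: float
    len_max: float
    q_min: float
    q_mean: float
    q_max: float
    n_passed: int
    n_failed: int
    n_skipped: int
    pct_passed: float
    pct_failed: float
    pct_skipped: float
    gc_mean: Optional[float]

    def as_items(self) -> list[tuple[str, object]]:
        return [
            ("label", self.label),
            ("total_reads", self.total_reads),
            ("total_bases", self.total_bases),
            ("run_duration_hours", self.run_duration_hours),
            ("length_min", self.len_min),
            ("length_mean", self.len_mean),
            ("length_max", self.len_max),
            ("quality_min", self.q_min),
            ("quality_mean", self.q_mean),
            ("quality_max", self.q_max),
            ("passed_reads", self.n_passed),
            ("failed_reads", self.n_failed),
            ("skipped_reads", self.n_skipped),
            ("passed_percent", self.pct_passed),
            ("failed_percent", self.pct_failed),
            ("skipped_percent", self.pct_skipped),
            ("gc_mean", "NA" if self.gc_mean is None else self.gc_mean),
        ]


def summarize_run(
    table: pd.DataFrame,
    dataset: RunDataset,
    out_path: str | os.PathLike | None = None,
) -> RunSummary:
    """Compute the run overview; optionally write ShortSummary.txt.

    Percentages are over passed + failed + skipped read units. An empty
    run reports zero totals with the passed share at 100 by convention.
    """
    n_passed = len(table)
    n_failed = dataset.n_failed_reads
    n_skipped = dataset.n_skipped
    total_units = n_passed + n_failed + n_skipped
    if total_units:
        pcts = (
            100.0 * n_passed / total_units,
            100.0 * n_failed / total_units,
            100.0 * n_skipped / total_units,
        )
    else:
        pcts = (100.0, 0.0, 0.0)
    if n_passed:
        lens = table["length"].to_numpy()
        quals = table["quality"].to_numpy()
        stats = (
            float(lens.min()), float(lens.mean()), float(lens.max()),
            float(quals.min()), float(quals.mean()), float(quals.max()),
        )
        duration = float(table["start_time"].max()) / 3600.0
        bases = int(lens.sum())
    else:
        stats = (0.0,) * 6
        duration = 0.0
        bases = 0
    gc = table["gc_content"].to_numpy() if n_passed else np.array([])
    gc_mean = float(np.nanmean(gc)) if gc.size and not np.all(np.isnan(gc)) else None

    summary = RunSummary(
        label=dataset.label,
        total_reads=n_passed,
        total_bases=bases,
        run_duration_hours=duration,
        len_min=stats[0], len_mean=stats[1], len_max=stats[2],
        q_min=stats[3], q_mean=stats[4], q_max=stats[5],
        n_passed=n_passed, n_failed=n_failed, n_skipped=n_skipped,
        pct_passed=pcts[0], pct_failed=pcts[1], pct_skipped=pcts[2],
        gc_mean=gc_mean,
    )
    if out_path is not None:
        lines = [f"{key}\t{value}" for key, value in summary.as_items()]
        Path(out_path).write_text("\n".join(lines) + "\n")
    return summary


def export_comparison_data(
    binned: pd.DataFrame, summary: RunSummary, out_dir: str | os.PathLike
) -> Path:
    """Persist the per-run comparison folder (binned_stats.tsv + summary.tsv).

    The folder is the sole input of the cross-run comparison stage and
    round-trips losslessly through :func:`nanorun.compare.load_comparison`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    binned.to_csv(out / "binned_stats.tsv", sep="\t", index=False, na_rep="NA")
    with open(out / "summary.tsv", "w") as handle:
        for key, value in summary.as_items():
            handle.write(f"{key}\t{value}\n")
    return out


def read_comparison_folder(path: str | os.PathLike) -> tuple[pd.DataFrame, dict]:
    """Load one folder written by :func:`export_comparison_data`."""
    folder = Path(path)
    binned = pd.read_csv(folder / "binned_stats.tsv", sep="\t", na_values=["NA"])
    summary: dict[str, str] = {}
    for line in (folder / "summary.tsv").read_text().splitlines():
        key, _, value = line.partition("\t")
        summary[key] = value
    return binned, summary
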