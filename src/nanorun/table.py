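"""The canonical per-read metadata table.

Every passed read contributes one row with exactly seven columns:
``read_id``, ``channel``, ``mux``, ``start_time`` (seconds since
experiment start), ``length`` (bases), ``quality`` (error-probability
mean Phred score) and ``gc_content`` (fraction, NaN when not computed —
the column is always present so the table shape never depends on
options).

Rows are sorted by ``(start_time, read_id)``; the lexicographic read-id
tie-break makes the table deterministic regardless of worker count.

Quality comes from the stored ``mean_qscore`` attribute when the input
carries one and is recomputed from the quality string otherwise, so the
fast5 path and the summary path agree on the same scale.
"""

from __future__ import annotations

import multiprocessing
import os
from typing import Optional

import numpy as np
import pandas as pd

from . import fast5 as f5
from .dataset import RunDataset
from .errors import (
    MalformedFileError,
    NanorunError,
    NotBasecalledError,
    UnknownLayoutError,
    UnreadableFileError,
)
from .qscore import gc_content, mean_qscore

TABLE_COLUMNS = (
    "read_id",
    "channel",
    "mux",
    "start_time",
    "length",
    "quality",
    "gc_content",
)

_Row = tuple[str, int, int, float, int, float, float]


def _row_from_read(
    attrs: f5.RawReadAttributes, payload: f5.BasecallPayload, want_gc: bool
) -> _Row:
    if payload.stored_mean_qscore is not None:
        quality = payload.stored_mean_qscore
    elif payload.quality_string is not None:
        quality = mean_qscore(payload.quality_string)
    else:
        raise MalformedFileError(f"read {attrs.read_id}: no quality available")
    if payload.stored_sequence_length is not None:
        length = payload.stored_sequence_length
    elif payload.sequence is not None:
        length = len(payload.sequence)
    else:
        raise MalformedFileError(f"read {attrs.read_id}: no length available")
    gc = gc_content(payload.sequence) if want_gc and payload.sequence else float("nan")
    return (
        attrs.read_id,
        attrs.channel,
        attrs.mux,
        attrs.start_time,
        length,
        quality,
        gc,
    )


def _parse_file(args: tuple[str, str, bool]) -> tuple[list[_Row], int]:
    """Worker: parse one passed fast5 file into (rows, n_skipped)."""
    path, flavor, want_gc = args
    try:
        if flavor == "fast5_single":
            # lazy first pass; fetch the sequence only when needed
            attrs, payload = f5.read_single(path, want_sequence=want_gc)
            if payload.stored_mean_qscore is None and payload.quality_string is None:
                attrs, payload = f5.read_single(path, want_sequence=True)
            return [_row_from_read(attrs, payload, want_gc)], 0
        records, n_skipped = f5.read_multi(path, want_sequence=want_gc)
        rows: list[_Row] = []
        for attrs, payload in records:
            try:
                if (
                    payload.stored_mean_qscore is None
                    and payload.quality_string is None
                ):
                    raise MalformedFileError("no stored q-score; need sequence")
                rows.append(_row_from_read(attrs, payload, want_gc))
            except NanorunError:
                n_skipped += 1
        return rows, n_skipped
    except (UnreadableFileError, UnknownLayoutError, NotBasecalledError,
            MalformedFileError, OSError):
        return [], 1


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "read_id": pd.Series(dtype=str),
            "channel": pd.Series(dtype=np.int64),
            "mux": pd.Series(dtype=np.int64),
            "start_time": pd.Series(dtype=np.float64),
            "length": pd.Series(dtype=np.int64),
            "quality": pd.Series(dtype=np.float64),
            "gc_content": pd.Series(dtype=np.float64),
        }
    )


def _finalize(rows: list[_Row]) -> pd.DataFrame:
    if not rows:
        return _empty_table()
    frame = pd.DataFrame(rows, columns=list(TABLE_COLUMNS))
    frame = frame.astype(
        {
            "channel": np.int64,
            "mux": np.int64,
            "start_time": np.float64,
            "length": np.int64,
            "quality": np.float64,
            "gc_content": np.float64,
        }
    )
    frame = frame.sort_values(["start_time", "read_id"], kind="mergesort")
    return frame.reset_index(drop=True)


def _build_from_fast5(dataset: RunDataset, workers: int, want_gc: bool):
    jobs = [(path, dataset.flavor, want_gc) for path in dataset.passed_files]
    if workers > 1 and len(jobs) > 1:
        with multiprocessing.Pool(workers) as pool:
            results = pool.map(_parse_file, jobs, chunksize=max(1, len(jobs) // (4 * workers)))
    else:
        results = [_parse_file(job) for job in jobs]
    rows: list[_Row] = []
    n_skipped = 0
    for file_rows, skipped in results:
        rows.extend(file_rows)
        n_skipped += skipped
    return _finalize(rows), n_skipped


def _build_from_summary(dataset: RunDataset, want_gc: bool):
    from .summary import parse_fastq, parse_summary

    records = [r for r in parse_summary(dataset.summary_path) if r.passes_filtering]
    gc_by_id: dict[str, float] = {}
    if want_gc and dataset.fastq_paths:
        for read_id, sequence, _ in parse_fastq(dataset.fastq_paths):
            if sequence:
                gc_by_id[read_id] = gc_content(sequence)
    rows = [
        (
            r.read_id,
            r.channel,
            r.mux,
            r.start_time,
            r.sequence_length,
            r.mean_qscore,
            gc_by_id.get(r.read_id, float("nan")),
        )
        for r in records
    ]
    return _finalize(rows), 0


def build_table(
    dataset: RunDataset, workers: int = 1, want_gc: bool = False
) -> pd.DataFrame:
    """Assemble the 7-column metadata table for a prepared run.

    Parameters
    ----------
    dataset : RunDataset
        Prepared run; ``dataset.n_skipped`` is incremented by the number
        of passed read units that could not be parsed.
    workers : int
        Processes for fast5 parsing. The result is identical for any
        value — parallelism never changes content or order.
    want_gc : bool
        Compute per-read GC fraction (requires reading sequences).

    Returns
    -------
    pandas.DataFrame
        One row per passed read, sorted by ``(start_time, read_id)``.
    """
    if workers < 1:
        raise ValueError("workers must be >= 1")
    if dataset.flavor in ("fast5_single", "fast5_multi"):
        table, n_skipped = _build_from_fast5(dataset, workers, want_gc)
    elif dataset.flavor == "summary_fastq":
        table, n_skipped = _build_from_summary(dataset, want_gc)
    else:
        raise ValueError(f"unknown flavor {dataset.flavor!r}")
    dataset.n_skipped += n_skipped
    if table.empty:
        import warnings

        warnings.warn(f"run {dataset.label!r}: no parsable passed reads", stacklevel=2)
    return table


def write_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Serialize the table as TSV with a header row (canonical interchange)."""
    table.to_csv(path, sep="\t", index=False)


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a table written by :func:`write_table`."""
    frame = pd.read_csv(path, sep="\t", dtype={"read_id": str})
    return frame.astype(
        {
            "channel": np.int64,
            "mux": np.int64,
            "start_time": np.float64,
            "length": np.int64,
            "quality": np.float64,
            "gc_content": np.float64,
        }
    )
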