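"""Sequencing-summary and FASTQ input (the summary-driven analysis path).

The device emits one tab-separated ``sequencing_summary.txt`` with a
header row and one row per read, alongside passed/failed FASTQ files.
Summary schemas drifted across device software releases, so required
columns are resolved by name through an alias list (e.g. read length and
mean q-score usually carry a ``_template`` suffix).
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import FastqParseError, RowParseError, SchemaError

#: Header aliases, in precedence order, for each required/optional field.
COLUMN_ALIASES: dict[str, tuple[str, ...]] = {
    "read_id": ("read_id",),
    "channel": ("channel", "channel_number"),
    "start_time": ("start_time",),
    "length": ("sequence_length_template", "sequence_length"),
    "quality": ("mean_qscore_template", "mean_qscore"),
    "passes_filtering": ("passes_filtering",),
    "mux": ("mux", "start_mux"),  # optional
}

_OPTIONAL = {"mux"}
_TRUTHY = {"true", "t", "1", "yes", "pass"}
_FALSY = {"false", "f", "0", "no", "fail"}


@dataclass(frozen=True)
class SummaryRecord:
    """One sequencing-summary row; ``mux == 0`` means unknown."""

    read_id: str
    channel: int
    mux: int
    start_time: float
    sequence_length: int
    mean_qscore: float
    passes_filtering: bool


def _parse_bool(value: str, line: int) -> bool:
    v = str(value).strip().lower()
    if v in _TRUTHY:
        return True
    if v in _FALSY:
        return False
    raise RowParseError(f"line {line}: unparseable passes_filtering value {value!r}")


def _numeric(series: pd.Series, column: str, caster) -> list:
    out = []
    for pos, value in enumerate(series):
        try:
            out.append(caster(value))
        except (TypeError, ValueError) as exc:
            # +2: one header line plus 1-based numbering
            raise RowParseError(
                f"line {pos + 2}: non-numeric value {value!r} in column {column!r}"
            ) from exc
    return out


def parse_summary(path: str | os.PathLike) -> list[SummaryRecord]:
    """Parse a sequencing summary TSV into one record per row.

    Required columns are resolved by alias; unknown extra columns are
    ignored; row order is preserved.

    Raises
    ------
    SchemaError
        If a required column is missing (the message names it).
    RowParseError
        On an unparseable cell (the message carries the line number).
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    resolved: dict[str, str] = {}
    for field, aliases in COLUMN_ALIASES.items():
        hit = next((a for a in aliases if a in frame.columns), None)
        if hit is None and field not in _OPTIONAL:
            raise SchemaError(
                f"summary file lacks required column {field!r} "
                f"(accepted headers: {', '.join(aliases)})"
            )
        if hit is not None:
            resolved[field] = hit

    channels = _numeric(frame[resolved["channel"]], "channel", lambda v: int(float(v)))
    starts = _numeric(frame[resolved["start_time"]], "start_time", float)
    lengths = _numeric(frame[resolved["length"]], "length", lambda v: int(float(v)))
    quals = _numeric(frame[resolved["quality"]], "quality", float)
    if "mux" in resolved:
        muxes = _numeric(frame[resolved["mux"]], "mux", lambda v: int(float(v)))
    else:
        muxes = [0] * len(frame)
    passes = [
        _parse_bool(v, pos + 2)
        for pos, v in enumerate(frame[resolved["passes_filtering"]])
    ]
    return [
        SummaryRecord(
            read_id=str(rid),
            channel=ch,
            mux=mx,
            start_time=st,
            sequence_length=ln,
            mean_qscore=q,
            passes_filtering=pf,
        )
        for rid, ch, mx, st, ln, q, pf in zip(
            frame[resolved["read_id"]], channels, muxes, starts, lengths, quals, passes
        )
    ]


def _open_maybe_gzip(path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def parse_fastq(
    paths: Iterable[str | os.PathLike],
) -> Iterator[tuple[str, str, str]]:
    """Stream ``(read_id, sequence, quality_string)`` from FASTQ files.

    Accepts plain or gzip-compressed Sanger FASTQ; files are read in the
    given order and records in file order. The read id is the first
    whitespace-delimited token of the header.

    Raises
    ------
    FastqParseError
        On a truncated record (the message carries the record index).
    """
    index = 0
    for path in paths:
        with _open_maybe_gzip(path) as handle:
            try:
                for record in SeqIO.parse(handle, "fastq"):
                    quality = "".join(
                        chr(q + 33)
                        for q in record.letter_annotations["phred_quality"]
                    )
                    yield record.id, str(record.seq), quality
                    index += 1
            except ValueError as exc:
                raise FastqParseError(
                    f"malformed FASTQ record at index {index} in {path}: {exc}"
                ) from exc


def summary_to_arrays(records: list[SummaryRecord]) -> pd.DataFrame:
    """Tabulate summary records (one row per read, original order)."""
    return pd.DataFrame(
        {
            "read_id": [r.read_id for r in records],
            "channel": np.array([r.channel for r in records], dtype=np.int64),
            "mux": np.array([r.mux for r in records], dtype=np.int64),
            "start_time": np.array([r.start_time for r in records], dtype=np.float64),
            "length": np.array([r.sequence_length for r in records], dtype=np.int64),
            "quality": np.array([r.mean_qscore for r in records], dtype=np.float64),
            "passes_filtering": [r.passes_filtering for r in records],
        }
    )
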