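"""FASTQ extraction, quality filtering and FASTA conversion.

The device classifies reads as passed when their mean q-score is at
least 7; user-supplied thresholds (meant to be stricter than the device
default) apply the same inclusive boundary rule. Filtering never
modifies record content, so filtering is idempotent at a fixed
threshold.
"""

from __future__ import annotations

import gzip
import multiprocessing
import os
from pathlib import Path
from typing import Iterable, Iterator

from . import fast5 as f5
from .dataset import RunDataset
from .errors import DomainError, NanorunError
from .qscore import mean_qscore

DEFAULT_PASS_THRESHOLD = 7.0

FastqRecord = tuple[str, str, str]  # (read_id, sequence, quality_string)


def classify_passed(q: float, threshold: float = DEFAULT_PASS_THRESHOLD) -> bool:
    """Device pass/fail rule: passed iff mean q-score >= threshold."""
    if threshold < 0:
        raise DomainError(f"threshold must be non-negative, got {threshold}")
    return q >= threshold


def filter_fastq(
    records: Iterable[FastqRecord], min_q: float
) -> tuple[list[FastqRecord], int, int]:
    """Keep records whose mean q-score is >= ``min_q`` (inclusive).

    Returns ``(kept, n_kept, n_discarded)``; record content is never
    modified, so ``n_kept + n_discarded`` equals the input count.
    """
    if min_q < 0:
        raise DomainError(f"min_q must be non-negative, got {min_q}")
    kept: list[FastqRecord] = []
    n_discarded = 0
    for record in records:
        if classify_passed(mean_qscore(record[2]), min_q):
            kept.append(record)
        else:
            n_discarded += 1
    return kept, len(kept), n_discarded


def fastq_to_fasta(records: Iterable[FastqRecord]) -> Iterator[str]:
    """Convert FASTQ records to FASTA entries (qualities dropped)."""
    for read_id, sequence, _ in records:
        yield f">{read_id}\n{sequence}"


def _open_out(path, compress: bool):
    if compress:
        return gzip.open(path, "wt")
    return open(path, "w")


def write_fastq(records: Iterable[FastqRecord], path: str | os.PathLike) -> int:
    """Write records as 4-line Sanger FASTQ; returns the record count."""
    n = 0
    with _open_out(path, str(path).endswith(".gz")) as handle:
        for read_id, sequence, quality in records:
            handle.write(f"@{read_id}\n{sequence}\n+\n{quality}\n")
            n += 1
    return n


def write_fasta(records: Iterable[FastqRecord], path: str | os.PathLike) -> int:
    n = 0
    with _open_out(path, str(path).endswith(".gz")) as handle:
        for entry in fastq_to_fasta(records):
            handle.write(entry + "\n")
            n += 1
    return n


def _extract_worker(args: tuple[str, str]) -> list[tuple[float, str, str, str, float]]:
    """Worker: pull (start_time, read_id, sequence, quality, q) from one file."""
    path, flavor = args
    out = []
    try:
        if flavor == "fast5_single":
            records = [f5.read_single(path, want_sequence=True)]
        else:
            records, _ = f5.read_multi(path, want_sequence=True)
    except NanorunError:
        return out
    for attrs, payload in records:
        if payload.sequence is None or payload.quality_string is None:
            continue
        q = (
            payload.stored_mean_qscore
            if payload.stored_mean_qscore is not None
            else mean_qscore(payload.quality_string)
        )
        out.append(
            (attrs.start_time, attrs.read_id, payload.sequence,
             payload.quality_string, q)
        )
    return out


def extract_fastq_from_fast5(
    dataset: RunDataset,
    min_q: float = DEFAULT_PASS_THRESHOLD,
    workers: int = 1,
    out: str | os.PathLike = "extracted.fastq",
    fasta: bool = False,
) -> tuple[int, int]:
    """Extract reads above ``min_q`` from passed fast5 into one FASTQ.

    Output order is (start_time, read_id) regardless of worker count.
    The filtering decision uses the same mean q-score the metadata table
    reports (stored attribute, else recomputed from the quality string).

    Returns ``(n_kept, n_discarded)``.
    """
    if min_q < 0:
        raise DomainError(f"min_q must be non-negative, got {min_q}")
    if dataset.flavor not in ("fast5_single", "fast5_multi"):
        raise DomainError("fast5 extraction requires a fast5-flavored run")
    jobs = [(path, dataset.flavor) for path in dataset.passed_files]
    if workers > 1 and len(jobs) > 1:
        with multiprocessing.Pool(workers) as pool:
            chunks = pool.map(_extract_worker, jobs,
                              chunksize=max(1, len(jobs) // (4 * workers)))
    else:
        chunks = [_extract_worker(job) for job in jobs]
    reads = sorted(
        (item for chunk in chunks for item in chunk), key=lambda r: (r[0], r[1])
    )
    kept = [(rid, seq, qual) for _, rid, seq, qual, q in reads if q >= min_q]
    n_discarded = len(reads) - len(kept)
    Path(out).parent.mkdir(parents=True, exist_ok=True)
    if fasta:
        write_fasta(kept, out)
    else:
        write_fastq(kept, out)
    return len(kept), n_discarded
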