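"""Run preparation: organize input files for the downstream stages.

A :class:`RunDataset` is the manifest of one sequencing run: where its
passed/failed inputs live, which input flavor they are, and the
pass/fail/skip accounting filled in as stages run. Failed inputs are
counted but never parsed for metadata — run statistics are computed on
passed reads only.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

from . import fast5 as f5
from .errors import DomainError, UnreadableFileError
from .summary import parse_summary

FLAVORS = ("fast5_single", "fast5_multi", "summary_fastq")


@dataclass
class RunDataset:
    """A prepared sequencing run.

    ``n_failed_reads`` is fixed at prepare time; ``n_skipped`` is updated
    by the metadata-table stage as unparsable passed units are found.
    """

    label: str
    flavor: str
    passed_files: list[str] = field(default_factory=list)
    failed_files: list[str] = field(default_factory=list)
    summary_path: Optional[str] = None
    fastq_paths: list[str] = field(default_factory=list)
    n_failed_reads: int = 0
    n_skipped: int = 0

    def to_json(self, path: str | os.PathLike) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "RunDataset":
        return cls(**json.loads(Path(path).read_text()))


def _discover_fast5(root: str | os.PathLike) -> list[str]:
    return sorted(str(p) for p in Path(root).rglob("*.fast5"))


def prepare_fast5(
    passed_dir: str | os.PathLike,
    label: str,
    failed_dir: str | os.PathLike | None = None,
    multi_read: bool = False,
) -> RunDataset:
    """Inventory a run of basecalled fast5 files.

    ``passed_dir`` (required) and ``failed_dir`` (optional) are searched
    recursively for ``*.fast5``. Failed files are only counted: one read
    unit per single-read file, one per read group in multi-read files.
    An unreadable failed container counts toward ``n_skipped``.
    """
    passed = _discover_fast5(passed_dir)
    if not passed:
        raise DomainError(f"no .fast5 files under {passed_dir}")
    flavor = "fast5_multi" if multi_read else "fast5_single"
    expected = f5.Fast5Flavor.MULTI_READ if multi_read else f5.Fast5Flavor.SINGLE_READ

    failed: list[str] = []
    n_failed = 0
    n_skipped = 0
    if failed_dir is not None:
        failed = _discover_fast5(failed_dir)
        for path in failed:
            try:
                n_failed += f5.count_reads(path, expected)
            except (OSError, UnreadableFileError):
                n_skipped += 1
    return RunDataset(
        label=label,
        flavor=flavor,
        passed_files=passed,
        failed_files=failed,
        n_failed_reads=n_failed,
        n_skipped=n_skipped,
    )


def prepare_summary(
    summary_path: str | os.PathLike,
    label: str,
    fastq_paths: list[str | os.PathLike] | None = None,
) -> RunDataset:
    """Organize a sequencing-summary + FASTQ run.

    The summary is parsed once here to validate its schema and fix the
    failed-read count (rows with ``passes_filtering`` false). FASTQ files
    are only needed when GC content will be requested downstream.
    """
    records = parse_summary(summary_path)
    n_failed = sum(1 for r in records if not r.passes_filtering)
    return RunDataset(
        label=label,
        flavor="summary_fastq",
        summary_path=str(summary_path),
        fastq_paths=[str(p) for p in (fastq_paths or [])],
        n_failed_reads=n_failed,
    )
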