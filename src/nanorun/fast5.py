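"""Reading basecalled fast5 (HDF5) containers.

Two on-disk dialects exist. Early devices wrote one read per file
(*single-read*): tracking and channel attributes live under
``UniqueGlobalKey``, the raw read group under ``Raw/Reads``, and the
basecall output under ``Analyses``. The *multi-read* dialect nests the
same structure once per read under top-level groups named
``read_<read_id>``.

Parsing is deliberately lazy: per-read metadata (id, channel, mux, start
time, stored length and mean q-score) is read from attribute nodes via
direct HDF5 pointer access, and the fastq payload dataset is only
materialised when the caller asks for sequences. This keeps metadata
extraction independent of read length.
"""

from __future__ import annotations

import enum
import os
from dataclasses import dataclass
from typing import Optional

import h5py

from .errors import (
    MalformedFileError,
    NotBasecalledError,
    UnknownLayoutError,
    UnreadableFileError,
)

# HDF5 node paths, single-read dialect. The multi-read dialect uses the
# same relative paths under each read_<id> group (with the raw group
# flattened to "Raw").
TRACKING_GROUP = "UniqueGlobalKey/tracking_id"
CHANNEL_GROUP = "UniqueGlobalKey/channel_id"
RAW_READS_GROUP = "Raw/Reads"
BASECALL_GROUP = "Analyses/Basecall_1D_000"
FASTQ_DATASET = BASECALL_GROUP + "/BaseCalled_template/Fastq"
BASECALL_SUMMARY = BASECALL_GROUP + "/Summary/basecall_1d_template"

MULTI_READ_PREFIX = "read_"


class Fast5Flavor(enum.Enum):
    """On-disk dialect of a fast5 container."""

    SINGLE_READ = "single_read"
    MULTI_READ = "multi_read"


@dataclass(frozen=True)
class RawReadAttributes:
    """Per-read metadata taken from HDF5 attribute nodes.

    ``raw_start_time`` is in samples since experiment start; divide by
    ``sampling_rate`` for seconds. ``mux == 0`` means unknown.
    """

    read_id: str
    raw_start_time: int
    mux: int
    channel: int
    sampling_rate: float
    exp_start_time: str

    @property
    def start_time(self) -> float:
        """Read start in seconds since experiment start."""
        return self.raw_start_time / self.sampling_rate


@dataclass(frozen=True)
class BasecallPayload:
    """Basecall output of one read.

    ``sequence``/``quality_string`` are ``None`` unless sequences were
    requested. The stored summary attributes are ``None`` when the file
    does not carry them.
    """

    sequence: Optional[str]
    quality_string: Optional[str]
    stored_mean_qscore: Optional[float]
    stored_sequence_length: Optional[int]


def _as_str(value) -> str:
    return value.decode() if isinstance(value, bytes) else str(value)


def detect_flavor(path: str | os.PathLike) -> Fast5Flavor:
    """Classify a fast5 file as single-read or multi-read.

    Raises
    ------
    UnreadableFileError
        If the file is not a readable HDF5 container.
    UnknownLayoutError
        If it is HDF5 but matches neither dialect.
    """
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise UnreadableFileError(f"not a readable HDF5 file: {path}") from exc
    with f:
        if RAW_READS_GROUP in f:
            reads = [k for k in f[RAW_READS_GROUP] ]
            if len(reads) == 1:
                return Fast5Flavor.SINGLE_READ
            raise UnknownLayoutError(
                f"single-read layout with {len(reads)} raw read groups: {path}"
            )
        keys = list(f.keys())
        if keys and all(
            k.startswith(MULTI_READ_PREFIX) and isinstance(f[k], h5py.Group)
            for k in keys
        ):
            return Fast5Flavor.MULTI_READ
    raise UnknownLayoutError(f"neither single- nor multi-read fast5 layout: {path}")


def _parse_fastq_payload(raw) -> tuple[str, str]:
    text = _as_str(raw[()] if isinstance(raw, h5py.Dataset) else raw)
    lines = text.strip("\n").split("\n")
    if len(lines) < 4:
        raise MalformedFileError("embedded fastq payload is truncated")
    return lines[1], lines[3]


def _read_one(group: h5py.Group, raw_group: h5py.Group, want_sequence: bool):
    """Extract one read from ``group`` whose raw attrs live on ``raw_group``."""
    if BASECALL_GROUP not in group:
        raise NotBasecalledError("missing basecall group")
    # single-read: tracking/channel under UniqueGlobalKey at file root;
    # multi-read: directly under the per-read group.
    tracking_path = TRACKING_GROUP if TRACKING_GROUP in group else "tracking_id"
    channel_path = CHANNEL_GROUP if CHANNEL_GROUP in group else "channel_id"
    try:
        channel_attrs = group[channel_path].attrs
        tracking_attrs = group[tracking_path].attrs
        raw_attrs = raw_group.attrs
        attrs = RawReadAttributes(
            read_id=_as_str(raw_attrs["read_id"]),
            raw_start_time=int(raw_attrs["start_time"]),
            mux=int(raw_attrs.get("start_mux", 0)),
            channel=int(_as_str(channel_attrs["channel_number"])),
            sampling_rate=float(channel_attrs["sampling_rate"]),
            exp_start_time=_as_str(tracking_attrs["exp_start_time"]),
        )
    except KeyError as exc:
        raise MalformedFileError(f"missing required attribute: {exc}") from exc

    stored_q = stored_len = None
    if BASECALL_SUMMARY in group:
        summary = group[BASECALL_SUMMARY].attrs
        if "mean_qscore" in summary:
            stored_q = float(summary["mean_qscore"])
        if "sequence_length" in summary:
            stored_len = int(summary["sequence_length"])

    sequence = quality = None
    if want_sequence:
        if FASTQ_DATASET not in group:
            raise NotBasecalledError("missing fastq dataset")
        sequence, quality = _parse_fastq_payload(group[FASTQ_DATASET])
    return attrs, BasecallPayload(sequence, quality, stored_q, stored_len)


def read_single(
    path: str | os.PathLike, want_sequence: bool = False
) -> tuple[RawReadAttributes, BasecallPayload]:
    """Parse a single-read fast5 file.

    With ``want_sequence=False`` the embedded fastq dataset is never
    touched; only attribute nodes are read.
    """
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise UnreadableFileError(f"not a readable HDF5 file: {path}") from exc
    with f:
        if RAW_READS_GROUP not in f:
            raise MalformedFileError(f"no raw read group in {path}")
        read_names = sorted(f[RAW_READS_GROUP].keys())
        if not read_names:
            raise MalformedFileError(f"empty raw read group in {path}")
        raw_group = f[RAW_READS_GROUP][read_names[0]]
        return _read_one(f["/"], raw_group, want_sequence)


def read_multi(
    path: str | os.PathLike, want_sequence: bool = False
) -> tuple[list[tuple[RawReadAttributes, BasecallPayload]], int]:
    """Parse every read of a multi-read fast5 file.

    Read groups are visited in lexicographic read-id order. A malformed
    or non-basecalled read group is skipped and counted, not fatal.

    Returns
    -------
    (records, n_skipped)
        ``records`` is a list of ``(RawReadAttributes, BasecallPayload)``.
    """
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise UnreadableFileError(f"not a readable HDF5 file: {path}") from exc
    records = []
    n_skipped = 0
    with f:
        for name in sorted(f.keys()):
            if not name.startswith(MULTI_READ_PREFIX):
                continue
            group = f[name]
            try:
                records.append(_read_one(group, group["Raw"], want_sequence))
            except (NotBasecalledError, MalformedFileError, KeyError):
                n_skipped += 1
    return records, n_skipped


def count_reads(path: str | os.PathLike, flavor: Fast5Flavor) -> int:
    """Number of read units a fast5 file holds (1 for single-read)."""
    if flavor is Fast5Flavor.SINGLE_READ:
        return 1
    with h5py.File(path, "r") as f:
        return sum(1 for k in f.keys() if k.startswith(MULTI_READ_PREFIX))
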