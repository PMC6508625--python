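"""Seeded synthetic sequencing runs with retained ground truth.

Emulates the outputs of a basecalled nanopore run in all three flavors
the readers consume — single-read fast5, multi-read fast5, and
sequencing summary + FASTQ — so the whole pipeline is testable offline.
Read lengths are log-normal, per-read mean q-scores truncated normal,
start times uniform or ramp-down (pore activity decaying linearly over
the run), channels drawn from the active set. Reads with q >= 7 go to
the passed tree, the rest to failed, and the generated pass fraction is
set exactly by drawing each class from the corresponding truncated
quality distribution.

Quality strings are synthesized from two adjacent integer Phred values
mixed so the error-probability-mean q-score of the string matches the
drawn per-read target to within 0.01; the drawn target itself is stored
as the ``mean_qscore`` attribute / summary column, so parser output can
be compared to ground truth exactly.

The same seed always produces a byte-identical file tree.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from . import fast5 as f5
from .errors import DomainError
from .qscore import gc_content

SAMPLING_RATE = 4000.0  # samples/s written into every generated file
EXP_START_TIME = "2019-01-01T00:00:00Z"
PASS_Q = 7.0
MIN_LENGTH = 100  # floor on drawn lengths; keeps q-string synthesis within 0.01

FLAVORS = ("fast5_single", "fast5_multi", "summary_fastq")


@dataclass
class RunSpec:
    """Parameters of one synthetic run.

    Defaults describe a modest but realistic flow cell: median read
    5 kb with log-sigma 0.6, mean read quality 10 +/- 1.5, 90% of reads
    passing, activity ramping down over an 8-hour run on all 512
    channels.
    """

    n_reads: int
    duration_hours: float = 8.0
    length_median: float = 5000.0
    length_sigma: float = 0.6
    quality_mean: float = 10.0
    quality_sd: float = 1.5
    pass_fraction: float = 0.9
    active_channels: list[int] | None = None
    start_time_model: str = "ramp"  # "uniform" | "ramp"
    seed: int = 0


GROUND_TRUTH_COLUMNS = (
    "read_id",
    "channel",
    "mux",
    "start_time",
    "length",
    "quality",
    "gc_content",
    "passed",
)


def quality_string_for_target(q_target: float, length: int) -> str:
    """A Phred+33 string whose error-probability mean q-score ~= target.

    Mixes floor(q) and floor(q)+1 characters in the proportion that
    matches the target mean error probability; the residual shrinks as
    1/length and stays below 0.01 for lengths >= 100.
    """
    if length <= 0:
        raise DomainError("length must be positive")
    if q_target < 0:
        raise DomainError("q_target must be non-negative")
    q_lo = int(np.floor(q_target))
    if q_lo == q_target:
        return chr(q_lo + 33) * length
    q_hi = q_lo + 1
    p_t = 10.0 ** (-q_target / 10.0)
    p_lo = 10.0 ** (-q_lo / 10.0)
    p_hi = 10.0 ** (-q_hi / 10.0)
    n_hi = int(round(length * (p_lo - p_t) / (p_lo - p_hi)))
    n_hi = min(max(n_hi, 0), length)
    return chr(q_hi + 33) * n_hi + chr(q_lo + 33) * (length - n_hi)


def _draw_reads(spec: RunSpec) -> pd.DataFrame:
    if spec.n_reads <= 0:
        raise DomainError("n_reads must be positive")
    if not 0.0 <= spec.pass_fraction <= 1.0:
        raise DomainError("pass_fraction must be in [0, 1]")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_reads
    n_pass = int(round(n * spec.pass_fraction))

    lengths = np.maximum(
        np.round(
            np.exp(rng.normal(np.log(spec.length_median), spec.length_sigma, n))
        ).astype(np.int64),
        MIN_LENGTH,
    )

    # passed reads: quality from N(mean, sd) truncated to [7, inf);
    # failed reads: truncated to [0, 7)
    loc, scale = spec.quality_mean, spec.quality_sd
    q_pass = truncnorm.rvs(
        (PASS_Q - loc) / scale, np.inf, loc=loc, scale=scale,
        size=n_pass, random_state=rng,
    )
    q_fail = truncnorm.rvs(
        (0.0 - loc) / scale, (PASS_Q - loc) / scale, loc=loc, scale=scale,
        size=n - n_pass, random_state=rng,
    )
    quality = np.round(np.concatenate([q_pass, q_fail]), 3)
    # rounding must not cross the pass boundary
    quality[:n_pass] = np.maximum(quality[:n_pass], PASS_Q)
    quality[n_pass:] = np.minimum(quality[n_pass:], PASS_Q - 0.001)
    passed = np.zeros(n, dtype=bool)
    passed[:n_pass] = True

    total = spec.duration_hours * 3600.0
    u = rng.random(n)
    if spec.start_time_model == "uniform":
        seconds = u * total
    elif spec.start_time_model == "ramp":
        # density decreasing linearly to zero at run end
        seconds = total * (1.0 - np.sqrt(1.0 - u))
    else:
        raise DomainError(f"unknown start_time_model {spec.start_time_model!r}")
    raw_start = np.round(seconds * SAMPLING_RATE).astype(np.int64)
    start_time = raw_start / SAMPLING_RATE

    channels = np.asarray(
        spec.active_channels
        if spec.active_channels is not None
        else np.arange(1, 513),
        dtype=np.int64,
    )
    channel = rng.choice(channels, size=n)
    mux = rng.integers(1, 5, size=n)

    read_ids = [
        "{}-{}-{}-{}-{}".format(h[:8], h[8:12], h[12:16], h[16:20], h[20:32])
        for h in (bytes(rng.integers(0, 256, 16, dtype=np.uint8)).hex() for _ in range(n))
    ]
    frame = pd.DataFrame(
        {
            "read_id": read_ids,
            "channel": channel,
            "mux": mux,
            "start_time": start_time,
            "raw_start": raw_start,
            "length": lengths,
            "quality": quality,
            "passed": passed,
        }
    )
    frame = frame.sort_values(["start_time", "read_id"], kind="mergesort")
    return frame.reset_index(drop=True)


def _sequences(frame: pd.DataFrame, seed: int) -> list[str]:
    rng = np.random.default_rng(seed + 1)
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    return [
        alphabet[rng.integers(0, 4, size=int(length))].tobytes().decode("ascii")
        for length in frame["length"]
    ]


def _fastq_text(read_id: str, sequence: str, quality: str) -> str:
    return f"@{read_id}\n{sequence}\n+\n{quality}\n"


def _write_read_group(group: h5py.Group, row, sequence: str, qual: str,
                      single: bool) -> None:
    prefix = "UniqueGlobalKey/" if single else ""
    tracking = group.create_group(prefix + "tracking_id")
    tracking.attrs["exp_start_time"] = EXP_START_TIME
    tracking.attrs["run_id"] = "synthetic-run"
    channel = group.create_group(prefix + "channel_id")
    channel.attrs["channel_number"] = str(int(row.channel))
    channel.attrs["sampling_rate"] = SAMPLING_RATE
    if single:
        raw = group.create_group(f"Raw/Reads/Read_{int(row.Index)}")
    else:
        raw = group.create_group("Raw")
    raw.attrs["read_id"] = row.read_id
    raw.attrs["start_time"] = int(row.raw_start)
    raw.attrs["start_mux"] = int(row.mux)
    group.create_dataset(
        f5.FASTQ_DATASET,
        data=_fastq_text(row.read_id, sequence, qual).encode("ascii"),
    )
    summary = group.create_group(f5.BASECALL_SUMMARY)
    summary.attrs["mean_qscore"] = float(row.quality)
    summary.attrs["sequence_length"] = int(row.length)


def _write_fast5_single(frame, sequences, qstrings, out: Path) -> None:
    for sub, dirname in ((frame[frame.passed], "passed"),
                         (frame[~frame.passed], "failed")):
        folder = out / dirname
        folder.mkdir(parents=True, exist_ok=True)
        for row in sub.itertuples():
            with h5py.File(folder / f"{row.read_id}.fast5", "w") as handle:
                _write_read_group(
                    handle["/"], row, sequences[row.Index], qstrings[row.Index],
                    single=True,
                )


def _write_fast5_multi(frame, sequences, qstrings, out: Path,
                       reads_per_file: int) -> None:
    for sub, dirname in ((frame[frame.passed], "passed"),
                         (frame[~frame.passed], "failed")):
        folder = out / dirname
        folder.mkdir(parents=True, exist_ok=True)
        rows = list(sub.itertuples())
        for k in range(0, max(len(rows), 1), reads_per_file):
            chunk = rows[k : k + reads_per_file]
            if not chunk:
                continue
            with h5py.File(folder / f"batch_{k // reads_per_file:04d}.fast5",
                           "w") as handle:
                for row in chunk:
                    group = handle.create_group(f"read_{row.read_id}")
                    _write_read_group(
                        group, row, sequences[row.Index], qstrings[row.Index],
                        single=False,
                    )


def _write_summary_fastq(frame, sequences, qstrings, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    header = (
        "filename\tread_id\trun_id\tchannel\tmux\tstart_time\tduration\t"
        "num_events\tpasses_filtering\tsequence_length_template\t"
        "mean_qscore_template\n"
    )
    with open(out / "sequencing_summary.txt", "w") as summary, \
         open(out / "passed.fastq", "w") as passed, \
         open(out / "failed.fastq", "w") as failed:
        summary.write(header)
        for row in frame.itertuples():
            summary.write(
                "\t".join(
                    [
                        f"{row.read_id}.fast5",
                        row.read_id,
                        "synthetic-run",
                        str(int(row.channel)),
                        str(int(row.mux)),
                        repr(float(row.start_time)),
                        "1.0",
                        str(int(row.length)),
                        "TRUE" if row.passed else "FALSE",
                        str(int(row.length)),
                        repr(float(row.quality)),
                    ]
                )
                + "\n"
            )
            target = passed if row.passed else failed
            target.write(
                _fastq_text(row.read_id, sequences[row.Index], qstrings[row.Index])
            )


def generate_run(
    spec: RunSpec,
    flavor: str,
    out: str | os.PathLike,
    reads_per_file: int = 1000,
) -> tuple[Path, pd.DataFrame]:
    """Write one synthetic run and its ground truth.

    Parameters
    ----------
    spec : RunSpec
        Study conditions; ``spec.seed`` fixes every output byte.
    flavor : str
        One of ``fast5_single``, ``fast5_multi``, ``summary_fastq``.
    out : path
        Output directory (created). Ground truth lands in
        ``ground_truth.tsv`` with one row per read, passed and failed.
    reads_per_file : int
        Reads per container for the multi-read flavor.

    Returns
    -------
    (out_path, ground_truth)
    """
    if flavor not in FLAVORS:
        raise DomainError(f"flavor must be one of {FLAVORS}, got {flavor!r}")
    out = Path(out)
    frame = _draw_reads(spec)
    sequences = _sequences(frame, spec.seed)
    qstrings = [
        quality_string_for_target(float(q), int(length))
        for q, length in zip(frame["quality"], frame["length"])
    ]
    truth = pd.DataFrame(
        {
            "read_id": frame["read_id"],
            "channel": frame["channel"],
            "mux": frame["mux"],
            "start_time": frame["start_time"],
            "length": frame["length"],
            "quality": frame["quality"],
            "gc_content": [gc_content(s) for s in sequences],
            "passed": frame["passed"],
        }
    )
    out.mkdir(parents=True, exist_ok=True)
    if flavor == "fast5_single":
        _write_fast5_single(frame, sequences, qstrings, out)
    elif flavor == "fast5_multi":
        _write_fast5_multi(frame, sequences, qstrings, out, reads_per_file)
    else:
        _write_summary_fastq(frame, sequences, qstrings, out)
    truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
    return out, truth


def corrupt(path: str | os.PathLike, mode: str) -> None:
    """Deterministically damage a fast5 file to exercise skip accounting.

    ``truncate`` keeps only the first third of the file's bytes (the
    parser must then classify it unreadable/skipped);
    ``drop_basecall_group`` deletes the basecall analysis group of the
    file (single-read) or of its lexicographically first read group
    (multi-read), producing a not-basecalled read.
    """
    path = Path(path)
    if mode == "truncate":
        data = path.read_bytes()
        path.write_bytes(data[: max(len(data) // 3, 1)])
    elif mode == "drop_basecall_group":
        with h5py.File(path, "r+") as handle:
            if "Analyses" in handle:
                del handle["Analyses"]
            else:
                name = sorted(
                    k for k in handle.keys()
                    if k.startswith(f5.MULTI_READ_PREFIX)
                )[0]
                del handle[name]["Analyses"]
    else:
        raise DomainError(f"unknown corruption mode {mode!r}")
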