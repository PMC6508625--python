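"""fast5 container parsing: flavor detection, round trips, laziness, damage."""

import h5py
import numpy as np
import pytest

from nanorun import fast5 as f5
from nanorun.errors import (
    NotBasecalledError,
    UnknownLayoutError,
    UnreadableFileError,
)
from nanorun.simulate import SAMPLING_RATE, corrupt

from conftest import passed_truth


def _passed_files(run_dir):
    return sorted((run_dir / "passed").glob("*.fast5"))


def test_detect_flavor_on_generated_files(run_factory):
    single, _ = run_factory("fast5_single", n_reads=10, seed=1)
    multi, _ = run_factory("fast5_multi", n_reads=10, seed=1)
    assert f5.detect_flavor(_passed_files(single)[0]) is f5.Fast5Flavor.SINGLE_READ
    assert (
        f5.detect_flavor(sorted((multi / "passed").glob("*.fast5"))[0])
        is f5.Fast5Flavor.MULTI_READ
    )


def test_detect_flavor_rejects_non_hdf5(tmp_path):
    empty = tmp_path / "empty.fast5"
    empty.write_bytes(b"")
    with pytest.raises(UnreadableFileError):
        f5.detect_flavor(empty)


def test_detect_flavor_rejects_unknown_layout(tmp_path):
    path = tmp_path / "odd.fast5"
    with h5py.File(path, "w") as handle:
        handle.create_group("something_else")
    with pytest.raises(UnknownLayoutError):
        f5.detect_flavor(path)


def test_read_single_round_trips_ground_truth(run_factory):
    run_dir, truth = run_factory("fast5_single", n_reads=10, seed=1)
    by_id = truth.set_index("read_id")
    for path in _passed_files(run_dir):
        attrs, payload = f5.read_single(path, want_sequence=True)
        row = by_id.loc[attrs.read_id]
        assert attrs.channel == row["channel"]
        assert attrs.mux == row["mux"]
        assert attrs.sampling_rate == SAMPLING_RATE
        assert attrs.start_time == pytest.approx(row["start_time"], abs=1e-9)
        assert payload.stored_sequence_length == row["length"]
        assert payload.stored_mean_qscore == pytest.approx(row["quality"], abs=1e-9)
        assert len(payload.sequence) == row["length"]
        assert len(payload.quality_string) == row["length"]


def test_start_time_is_samples_over_sampling_rate(run_factory):
    run_dir, truth = run_factory("fast5_single", n_reads=10, seed=1)
    attrs, _ = f5.read_single(_passed_files(run_dir)[0])
    assert attrs.start_time == attrs.raw_start_time / attrs.sampling_rate


def test_read_multi_round_trips_all_reads(run_factory):
    run_dir, truth = run_factory("fast5_multi", n_reads=10, seed=2)
    gt = passed_truth(truth)
    records = []
    for path in _passed_files(run_dir):
        recs, skipped = f5.read_multi(path, want_sequence=True)
        assert skipped == 0
        records.extend(recs)
    assert len(records) == len(gt)
    got = {a.read_id: (a.channel, a.mux, p.stored_sequence_length)
           for a, p in records}
    for row in gt.itertuples():
        assert got[row.read_id] == (row.channel, row.mux, row.length)


def test_read_multi_lexicographic_order(run_factory):
    run_dir, _ = run_factory("fast5_multi", n_reads=10, seed=2)
    records, _ = f5.read_multi(_passed_files(run_dir)[0])
    ids = [a.read_id for a, _ in records]
    assert ids == sorted(ids)


def test_read_multi_empty_container(tmp_path):
    path = tmp_path / "none.fast5"
    with h5py.File(path, "w") as handle:
        handle.attrs["file_version"] = "2.0"
    records, skipped = f5.read_multi(path)
    assert records == [] and skipped == 0


def test_lazy_parse_survives_unreadable_fastq_payload(run_factory, copy_run):
    """With want_sequence=False the fastq dataset must never be touched."""
    src, _ = run_factory("fast5_single", n_reads=10, seed=1)
    run_dir = copy_run(src)
    path = sorted((run_dir / "passed").glob("*.fast5"))[0]
    with h5py.File(path, "r+") as handle:
        del handle[f5.FASTQ_DATASET]
    attrs, payload = f5.read_single(path, want_sequence=False)
    assert payload.stored_mean_qscore is not None
    with pytest.raises(NotBasecalledError):
        f5.read_single(path, want_sequence=True)


def test_dropped_basecall_group_is_not_basecalled(run_factory, copy_run):
    src, _ = run_factory("fast5_single", n_reads=10, seed=1)
    run_dir = copy_run(src)
    path = sorted((run_dir / "passed").glob("*.fast5"))[0]
    corrupt(path, "drop_basecall_group")
    with pytest.raises(NotBasecalledError):
        f5.read_single(path)


def test_truncated_file_is_unreadable(run_factory, copy_run):
    src, _ = run_factory("fast5_single", n_reads=10, seed=1)
    run_dir = copy_run(src)
    path = sorted((run_dir / "passed").glob("*.fast5"))[0]
    corrupt(path, "truncate")
    with pytest.raises(UnreadableFileError):
        f5.read_single(path)


def test_corrupted_group_in_multi_is_skipped_not_fatal(run_factory, copy_run):
    src, truth = run_factory("fast5_multi", n_reads=10, seed=2)
    run_dir = copy_run(src)
    path = sorted((run_dir / "passed").glob("*.fast5"))[0]
    with h5py.File(path, "r") as handle:
        n_before = len(handle.keys())
    corrupt(path, "drop_basecall_group")
    records, skipped = f5.read_multi(path)
    assert skipped == 1
    assert len(records) == n_before - 1
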