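"""Cross-run comparison of persisted binned statistics."""

import numpy as np
import pandas as pd
import pytest

from nanorun.compare import group_bins, group_values, load_comparison
from nanorun.dataset import RunDataset
from nanorun.errors import DomainError
from nanorun.stats import bin_reads, export_comparison_data, summarize_run


def _make_folder(tmp_path, name, times, lengths, qualities):
    table = pd.DataFrame(
        {
            "read_id": [f"{name}{i}" for i in range(len(times))],
            "channel": np.ones(len(times), dtype=np.int64),
            "mux": np.ones(len(times), dtype=np.int64),
            "start_time": np.array(times, dtype=float),
            "length": np.array(lengths, dtype=np.int64),
            "quality": np.array(qualities, dtype=float),
            "gc_content": np.full(len(times), np.nan),
        }
    )
    binned = bin_reads(table)
    summary = summarize_run(table, RunDataset(label=name, flavor="fast5_single"))
    return export_comparison_data(binned, summary, tmp_path / name), binned


@pytest.fixture
def two_runs(tmp_path):
    rng = np.random.default_rng(23)
    folders, binned = [], []
    for name, hours in (("A", 20.0), ("B", 8.0)):
        n = 300
        times = rng.uniform(0, hours * 3600, n)
        f, b = _make_folder(tmp_path, name, times,
                            rng.integers(200, 8000, n), rng.normal(10, 1.5, n))
        folders.append(f)
        binned.append(b)
    return folders, binned


def test_load_round_trips_bins_exactly(two_runs):
    folders, binned = two_runs
    cs = load_comparison(folders, ["A", "B"])
    assert cs.labels == ["A", "B"]
    for loaded, original in zip(cs.binned, binned):
        pd.testing.assert_frame_equal(loaded, original)


def test_load_validations(two_runs, tmp_path):
    folders, _ = two_runs
    with pytest.raises(DomainError, match="duplicate"):
        load_comparison(folders, ["A", "A"])
    with pytest.raises(DomainError, match="two runs"):
        load_comparison(folders[:1], ["A"])
    with pytest.raises(DomainError):
        load_comparison(folders, ["A"])
    with pytest.raises(FileNotFoundError, match="missing_dir"):
        load_comparison([folders[0], tmp_path / "missing_dir"], ["A", "B"])


def test_twenty_hour_run_splits_into_two_groups_of_twenty_bins(two_runs):
    folders, _ = two_runs
    cs = load_comparison(folders, ["A", "B"])
    values = group_values(cs, group_hours=10.0)
    run_a = values[(values["label"] == "A") & (values["metric"] == "n_reads")]
    counts = run_a.groupby("group").size()
    assert set(counts.index) == {0, 1}
    assert counts[0] == 20  # 10 h of 30-min bins


def test_group_medians_match_brute_force_oracle(two_runs):
    folders, binned = two_runs
    cs = load_comparison(folders, ["A", "B"])
    grouped = group_bins(cs, group_hours=10.0)
    width = 10.0 * 3600.0
    for label, frame in zip(["A", "B"], binned):
        groups = np.floor(frame["bin_start"] / width).astype(int)
        for g in sorted(groups.unique()):
            oracle = float(np.median(frame.loc[groups == g, "n_reads"]))
            got = grouped[
                (grouped["label"] == label)
                & (grouped["group"] == g)
                & (grouped["metric"] == "n_reads")
                & (grouped["statistic"] == "median")
            ]["value"].iloc[0]
            assert got == pytest.approx(oracle)


def test_group_sums_conserve_total_reads(two_runs):
    folders, binned = two_runs
    cs = load_comparison(folders, ["A", "B"])
    grouped = group_bins(cs, group_hours=10.0)
    for label, frame in zip(["A", "B"], binned):
        sums = grouped[
            (grouped["label"] == label)
            & (grouped["metric"] == "n_reads")
            & (grouped["statistic"] == "sum")
        ]["value"].sum()
        assert sums == frame["n_reads"].sum()


def test_shorter_run_absent_from_later_groups(two_runs):
    folders, _ = two_runs
    cs = load_comparison(folders, ["A", "B"])
    grouped = group_bins(cs, group_hours=10.0)
    # B lasts 8 h, so only run A contributes bins to the 10-20 h group
    assert set(grouped[grouped["group"] == 1]["label"]) == {"A"}
    assert set(grouped[grouped["group"] == 0]["label"]) == {"A", "B"}


def test_grouping_then_summing_equals_summing_then_grouping(two_runs):
    folders, binned = two_runs
    cs = load_comparison(folders, ["A", "B"])
    values = group_values(cs, group_hours=10.0)
    for label, frame in zip(["A", "B"], binned):
        per_group = (
            values[(values["label"] == label) & (values["metric"] == "n_bases")]
            .groupby("group")["value"]
            .sum()
        )
        assert per_group.sum() == frame["n_bases"].sum()
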