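"""Binned statistics, yield, regression, overview, comparison export."""

import numpy as np
import pandas as pd
import pytest

from nanorun.dataset import RunDataset, prepare_fast5
from nanorun.errors import DegenerateFitError
from nanorun.stats import (
    bin_reads,
    cumulative_yield,
    export_comparison_data,
    length_quality_fit,
    read_comparison_folder,
    summarize_run,
)
from nanorun.table import build_table


def _table(times, lengths=None, qualities=None):
    n = len(times)
    return pd.DataFrame(
        {
            "read_id": [f"r{i}" for i in range(n)],
            "channel": np.ones(n, dtype=np.int64),
            "mux": np.ones(n, dtype=np.int64),
            "start_time": np.array(times, dtype=float),
            "length": np.array(lengths if lengths is not None else [100] * n,
                               dtype=np.int64),
            "quality": np.array(qualities if qualities is not None else [10.0] * n),
            "gc_content": np.full(n, np.nan),
        }
    )


def test_bin_assignment_uses_floor_of_time_over_width():
    binned = bin_reads(_table([300.0, 600.0, 2400.0]), bin_width=1800.0)
    assert list(binned["n_reads"]) == [2, 1]
    assert list(binned["bin_start"]) == [0.0, 1800.0]


def test_bin_aggregates_min_mean_max():
    binned = bin_reads(_table([10.0, 20.0], lengths=[100, 300],
                              qualities=[8.0, 12.0]), bin_width=1800.0)
    row = binned.iloc[0]
    assert (row["len_min"], row["len_mean"], row["len_max"]) == (100.0, 200.0, 300.0)
    assert (row["q_min"], row["q_mean"], row["q_max"]) == (8.0, 10.0, 12.0)
    assert row["n_bases"] == 400


def test_bins_tile_with_explicit_empty_bins():
    binned = bin_reads(_table([100.0, 4000.0]), bin_width=1800.0)
    assert len(binned) == 3
    middle = binned.iloc[1]
    assert middle["n_reads"] == 0
    assert np.isnan(middle["len_mean"])


def test_empty_table_gives_empty_binning():
    assert len(bin_reads(_table([]))) == 0


def test_merging_adjacent_bins_equals_double_width():
    rng = np.random.default_rng(5)
    times = rng.uniform(0, 20000, 200)
    lengths = rng.integers(100, 5000, 200)
    fine = bin_reads(_table(times, lengths=lengths), bin_width=1000.0)
    coarse = bin_reads(_table(times, lengths=lengths), bin_width=2000.0)
    for b in range(len(coarse)):
        pair = fine[fine["bin_index"] // 2 == b]
        assert coarse.iloc[b]["n_reads"] == pair["n_reads"].sum()
        assert coarse.iloc[b]["n_bases"] == pair["n_bases"].sum()


def test_cumulative_yield_runs_and_conserves():
    series = cumulative_yield(_table([1.0, 2.0, 3.0], lengths=[100, 200, 300]))
    assert list(series["cum_bases"]) == [100, 300, 600]
    assert list(series["cum_reads"]) == [1, 2, 3]
    assert (np.diff(series["cum_bases"]) >= 0).all()


def test_length_quality_fit_recovers_exact_line():
    lengths = np.array([100, 1000, 10000, 100000])
    qualities = 2.0 * np.log10(lengths) + 1.0
    slope, intercept = length_quality_fit(_table([0.0] * 4, lengths=lengths,
                                                 qualities=qualities))
    assert slope == pytest.approx(2.0, abs=1e-9)
    assert intercept == pytest.approx(1.0, abs=1e-9)


def test_length_quality_fit_constant_quality_gives_zero_slope():
    slope, _ = length_quality_fit(
        _table([0.0] * 3, lengths=[100, 200, 300], qualities=[9.0, 9.0, 9.0])
    )
    assert slope == pytest.approx(0.0, abs=1e-12)


def test_length_quality_fit_matches_normal_equations_oracle():
    rng = np.random.default_rng(11)
    lengths = rng.integers(100, 50000, 500)
    qualities = rng.normal(10, 2, 500)
    slope, intercept = length_quality_fit(
        _table(np.zeros(500), lengths=lengths, qualities=qualities)
    )
    x = np.log10(lengths.astype(float))
    design = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(design.T @ design, design.T @ qualities)
    assert slope == pytest.approx(beta[1], abs=1e-9)
    assert intercept == pytest.approx(beta[0], abs=1e-9)


def test_degenerate_fit_raises():
    with pytest.raises(DegenerateFitError):
        length_quality_fit(_table([0.0, 1.0], lengths=[500, 500]))


def test_summarize_run_matches_generator_truth(run_factory, tmp_path):
    run_dir, truth = run_factory("fast5_single", n_reads=50, seed=13)
    dataset = prepare_fast5(run_dir / "passed", "demo",
                            failed_dir=run_dir / "failed")
    table = build_table(dataset)
    out = tmp_path / "ShortSummary.txt"
    summary = summarize_run(table, dataset, out_path=out)
    gt = truth[truth["passed"]]
    assert summary.total_reads == len(gt)
    assert summary.total_bases == gt["length"].sum()
    assert summary.n_failed == (~truth["passed"]).sum()
    assert summary.pct_passed + summary.pct_failed + summary.pct_skipped == (
        pytest.approx(100.0, abs=1e-6)
    )
    text = out.read_text()
    assert f"total_reads\t{len(gt)}" in text


def test_all_passed_run_reports_hundred_percent():
    table = _table([0.0, 10.0])
    dataset = RunDataset(label="x", flavor="fast5_single")
    summary = summarize_run(table, dataset)
    assert summary.pct_passed == pytest.approx(100.0)


def test_empty_run_has_zero_totals():
    summary = summarize_run(_table([]), RunDataset(label="x", flavor="fast5_single"))
    assert summary.total_reads == 0
    assert summary.total_bases == 0
    assert summary.run_duration_hours == 0.0


def test_comparison_export_round_trip(tmp_path):
    table = _table([100.0, 2000.0, 4000.0], lengths=[100, 200, 300],
                   qualities=[8.0, 9.0, 10.0])
    binned = bin_reads(table)
    summary = summarize_run(table, RunDataset(label="rt", flavor="fast5_single"))
    folder = export_comparison_data(binned, summary, tmp_path / "DataForComparison")
    back, meta = read_comparison_folder(folder)
    pd.testing.assert_frame_equal(binned, back)
    assert meta["label"] == "rt"


def test_export_of_empty_run_writes_header_only_tables(tmp_path):
    table = _table([])
    binned = bin_reads(table)
    summary = summarize_run(table, RunDataset(label="e", flavor="fast5_single"))
    folder = export_comparison_data(binned, summary, tmp_path / "cmp")
    back, _ = read_comparison_folder(folder)
    assert len(back) == 0
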