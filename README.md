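# nanorun

Run-level quality control for Oxford Nanopore sequencing output — MinION
and GridION class flow cells — as a Python library with a matching
command-line tool.

After basecalling, a nanopore run leaves behind either a tree of fast5
(HDF5) containers split into `passed/` and `failed/` folders, or a
tab-separated `sequencing_summary.txt` plus passed/failed FASTQ files.
Sequencing teams need to judge, quickly and per run, how much the flow
cell yielded, how yield and read quality evolved over time, whether
particular regions of the flow cell went quiet, and how a run stacks up
against previous ones. `nanorun` answers those questions from either
input form, without re-reading the data for every question.

## What it computes

The pipeline centres on a canonical **metadata table** with one row per
passed read and seven columns: read id, channel (1–512), mux (1–4, 0 =
unknown), start time *t* in seconds since experiment start, length *L*
in bases, mean q-score *Q*, and GC fraction (optional; NaN when not
computed). The per-read quality is the error-probability-domain mean of
the per-base Phred scores *qᵢ*:

    Q = −10·log₁₀( (1/L) Σᵢ 10^(−qᵢ/10) )

which is the convention the basecaller's own stored `mean_qscore` uses;
the device classifies a read as *passed* when Q ≥ 7.

From the table, `nanorun` derives:

- cumulative reads and bases over run time (yield curves);
- per-time-bin statistics (default 30-minute bins): read and base
  counts, min/mean/max length and quality;
- an ordinary least-squares fit of quality on log₁₀(length), with
  marginal length and quality histograms (longer reads tend to score
  higher);
- channel and mux activity heatmaps on the physical 16×32 flow-cell
  grid (muxes split each cell 2×2, 2048 positions), inactive positions
  masked;
- a run overview (`ShortSummary.txt`) with pass/fail/skip counts and
  percentages;
- cross-run comparison: each run's 30-minute bins grouped into 10-hour
  intervals, with violin plots of reads, bases, mean length and mean
  quality per group.

Metadata extraction reads only HDF5 attribute nodes unless sequences
are explicitly needed (GC or fastq extraction), so its cost is
independent of read length, and it parallelises over files with a
deterministic, worker-count-independent result.

A seeded synthetic-run generator (`nanorun.simulate`) emits all three
input flavors together with a ground-truth table, so the entire
pipeline is testable without device data.

## Worked example

Generate a small synthetic run and push it through the five stages:

```python
from nanorun.simulate import RunSpec, generate_run
generate_run(RunSpec(n_reads=200, seed=11, duration_hours=24), "fast5_multi", "runA")
```

```sh
$ nanorun prepare --passed runA/passed --failed runA/failed --label A --multi-read --out A.json
prepared run 'A': flavor=fast5_multi passed_files=1 failed_reads=20
$ nanorun table --manifest A.json --out A_table.tsv --gc
wrote 180 reads x 7 columns to A_table.tsv
$ nanorun stats --manifest A.json --table A_table.tsv --out A_stats
run 'A': 180 reads, 1075425 bases over 21.54 h -> A_stats
$ nanorun fastq --manifest A.json --out A_filtered.fastq --min-q 9
kept 131, discarded 49 at min_q 9.0 -> A_filtered.fastq
```

The run held 200 reads, 20 of which fell below the device's Q ≥ 7 rule
and sit in `failed/` (counted, never parsed); the other 180 passed reads
produced ~1.08 Mb over 21.5 hours. `A_stats/` now contains
`ShortSummary.txt`, five PDF reports (yield, binned trend,
length-vs-quality, flow-cell heatmaps, pass/fail/GC) each with a TSV
sidecar of the plotted numbers, and a `DataForComparison/` folder.
Filtering at a user threshold of 9 — stricter than the device default —
kept 131 of the 180 passed reads. Given a second analyzed run:

```sh
$ nanorun compare --data A_stats/DataForComparison --data B_stats/DataForComparison --labels A,B --out cmp
compared 2 runs -> cmp
```

For summary-driven runs, use
`nanorun prepare --summary sequencing_summary.txt --fastq passed.fastq ...`
instead; everything downstream is identical.

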