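# Methods

## Inputs and the two analysis paths

`nanorun` accepts a basecalled nanopore run in either of the two forms
the devices emit:

- **fast5 path** — directories of basecalled fast5 (HDF5) containers,
  split into passed and failed trees, in the single-read dialect (one
  read per file) or the multi-read dialect (many `read_<id>` groups per
  file);
- **summary path** — the `sequencing_summary.txt` TSV plus passed and
  failed FASTQ files.

Both paths converge on the same 7-column per-read metadata table, and
everything downstream (statistics, plots, comparison) consumes only the
table. On a synthetic run emitted in both forms, the two tables agree
exactly on shared columns; the test suite asserts this at 1e-6.

### fast5 node layout

The vendor never standardized a documented schema, so the expected node
paths are fixed here and written identically by the synthetic
generator: tracking attributes (`exp_start_time`, `run_id`) and channel
attributes (`channel_number`, `sampling_rate`) under `UniqueGlobalKey`
(single-read) or per-read groups (multi-read); raw read attributes
(`read_id`, `start_time` in samples, `start_mux`) on the raw group; the
fastq payload and a summary attribute node (`mean_qscore`,
`sequence_length`) under `Analyses/Basecall_1D_000`. Start time in
seconds is `start_time / sampling_rate` — the only dimensionally
consistent reading of the samples-denominated attribute.

### Laziness

Metadata extraction touches attribute nodes only; the fastq payload
dataset is materialised solely when sequences are required (GC content
or fastq extraction). This makes table construction cost independent of
read length. The property is observable and tested: a file whose fastq
dataset has been deleted still parses fully with `want_sequence=False`.

### Error handling and "skipped"

A passed read unit that cannot be parsed (unreadable container, missing
basecall group, missing required attributes) is *skipped*: counted,
reported in the overview, never fatal. In a multi-read container a
damaged read group skips only that group. Failed inputs are counted
(one unit per single-read file, one per read group in multi-read files,
one row per `passes_filtering=false` summary row) and never parsed for
metadata — run statistics describe passed reads only.

## Per-read quality

The read-level quality is the error-probability-domain mean,
`Q = −10·log10(mean_i 10^(−q_i/10))`, not the arithmetic mean of the
per-base scores. This matches the convention of the stored
`mean_qscore` attribute and the summary column, keeping the two input
paths on one scale. When an input carries a stored mean q-score it
takes precedence (one attribute read instead of streaming the
sequence); the string-derived value is the fallback. Q is bounded by
the per-base min and max and is permutation-invariant; both properties
are tested, and equivalence with a brute-force per-base oracle is
asserted at 1e-9.

GC content is `(#G + #C) / length` with ambiguous IUPAC codes counting
in the denominator only; it is stored as a fraction (reports render
percentages). The table keeps its 7 columns whether or not GC was
computed — a NaN sentinel fills the column otherwise — so the table
shape is configuration-independent.

## Statistics

- **Binning.** A read starting at `t` belongs to bin
  `floor(t / width)`; the default width is 1800 s (the 30-minute trend
  interval). Bins tile `[0, run_end]` with empty bins present
  (`n_reads = 0`, aggregates NA) so plots show silence as silence.
  Binning at width `w` then merging adjacent pairs equals binning at
  `2w` for counts and base sums (tested).
- **Regression.** Ordinary least squares of quality on log10(length),
  via `scipy.stats.linregress`; log length is the scale the joint plot
  uses and keeps the fit from being dominated by the length tail.
  Zero-length reads are excluded; fewer than two distinct lengths is a
  degenerate-fit error. The test suite checks the fit against an
  explicit normal-equations solution at 1e-9.
- **Overview.** `ShortSummary.txt` is a key/value TSV of totals,
  min/mean/max length and quality, run duration, pass/fail/skip counts
  and percentages (summing to 100 over the three classes; an empty run
  reports zero totals with the passed share at 100 by convention), and
  mean GC when computed.
- **Comparison.** Consumes only the persisted `DataForComparison`
  folders (binned table + summary), never raw reads. Bins are grouped
  by `floor(bin_start / group_width)` with a 10-hour default. The
  violin distributions are over *per-bin* values within each group —
  per-read distributions within a window would answer a different
  question (read-length spread rather than throughput stability).
  Count metrics include empty bins; mean-length/quality distributions
  use defined bins only.

## Flow-cell geometry

512 channels on a 16×32 grid; each channel cell splits 2×2 for the four
muxes, giving 2048 pore positions. The packaged, version-stamped layout
table is generated by a deterministic block pattern (eight 64-channel
blocks of 16 rows × 4 columns, left to right). The vendor's physical
diagram is not publicly archived, so cell-for-cell physical fidelity is
explicitly not claimed; the guaranteed surface is the grid shape, the
injectivity of both coordinate maps (exhaustively tested over 512 and
2048 cases) and conservation of totals, which is what positional
diagnostics actually require. Reads with unknown mux (0) appear in
channel maps but are excluded from mux maps.

## Filtering and extraction

Pass/fail uses the inclusive rule `Q ≥ threshold`, with the device
default of 7; user thresholds are meant to be stricter. The filter
decision uses the same per-read Q the table reports, never a second
derivation. Extraction from fast5 writes reads sorted by
`(start_time, read_id)` — the same deterministic order the table uses —
so output is byte-identical for any worker count. Filtering is
conservative (`kept + discarded = input`) and idempotent.

## Parallelism and determinism

fast5 parsing and extraction fan out over files with
`multiprocessing.Pool`; results are re-sorted by `(start_time,
read_id)` with the lexicographic id as tie-break, so content and order
are worker-count-independent (asserted byte-for-byte on serialized
output). The table is assembled once at its final size rather than
grown incrementally.

## The synthetic generator

`nanorun.simulate` emits a seeded run in any of the three input flavors
plus a ground-truth table. Study conditions (defaults): log-normal read
lengths (median 5000 b, log-sigma 0.6, floor 100 b), per-read quality
from a truncated normal (mean 10, sd 1.5), pass fraction 0.9 — passed
reads drawn from the distribution truncated to `[7, ∞)`, failed from
`[0, 7)`, so the q ≥ 7 rule and the pass fraction hold exactly — start
times from a linearly decaying intensity over an 8-hour run (pore
activity ramps down as a run ages; a uniform model is available),
channels uniform over the active set, mux uniform on 1–4, sampling rate
fixed at 4000 samples/s with `raw_start = round(seconds × 4000)` so the
samples→seconds conversion is testable with known numbers.

Quality strings mix the two integer Phred values bracketing the drawn
target in the proportion that matches its mean error probability; the
residual shrinks as 1/length and stays below 0.01 q for lengths ≥ 100.
The drawn target itself is stored as the `mean_qscore` attribute and
summary column, which is what makes generator→parser round trips exact
rather than approximate. The same seed reproduces every output byte.

What the generator does **not** emulate: raw current signal, realistic
basecaller error profiles (qualities are two-valued per read, not
banded), within-read quality structure, channel-specific productivity
differences, or device pauses. Passing round-trip tests therefore
demonstrates parser/statistics correctness on well-formed and
deliberately damaged inputs, not robustness to every malformation real
basecaller versions can produce.

## Problem sizes in the shipped checks

The test suite runs the round-trip and determinism checks on a
1000-read run per flavor and the full five-stage command-line workflow
on two 10,000-read multi-read runs; the acceptance script uses a
1000-read run in two flavors. These sizes give every code path
(batching, parallel chunking, multi-container runs) realistic work
while keeping the suite quick on a laptop.

## Known limitations

- Only the 512-channel (MinION-class) geometry ships; GridION uses the
  same flow cells, but PromethION geometries are out of scope.
- No 1D² pairing, barcode demultiplexing, BAM/SAM input, or live
  monitoring during a run.
- Comparison draws no statistical inferences between runs; it
  visualizes distributions only.
- The summary-path GC computation requires the passed FASTQ files;
  without them the GC column stays at its sentinel.
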