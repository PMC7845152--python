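# Methods

## Overview

`readqc` computes the standard FastQC analysis modules for a file of
sequencing reads in a single streaming pass. The design separates three
stages:

1. **Input streaming** (`readqc.seqio`): records are parsed one at a time
   from 4-line FASTQ (plain or gzip) or SAM/BAM, so peak memory depends on
   the longest read, never on file size.
2. **Collection** (`readqc.collector`): one pass updates every sufficient
   statistic — positional base and quality counts, per-read GC and
   mean-quality histograms, read lengths, per-tile quality sums, a bounded
   duplication tracker, and cumulative adapter-match counters.
3. **Postprocessing** (`readqc.qc_modules`, `readqc.report`): the analysis
   tables, pass/warn/fail grades and the three output files are derived
   from the accumulator after the pass. Postprocessing is a pure function
   of the accumulator, so re-running it reproduces identical bytes.

The intent is drop-in compatibility with FastQC 0.11.x: module titles,
column layouts, grading thresholds, the `fastqc_data.txt` /` summary.txt`
dialects and the CLI flag surface match the reference tool so downstream
aggregators and pipeline glue work unchanged.

## Input handling

FASTQ records are strict 4-line records; wrapped (multi-line) records are
rejected because both emulated report dialects assume 4-line input. A
record whose base and quality strings differ in length, or a truncated
final record, aborts with the offending line number. Bases are uppercased;
characters outside {A,C,G,T} are counted as N. Zero-length reads are
accepted and drive a fail in the length-distribution module.

SAM input is parsed directly from the text form (header lines skipped,
records with SEQ `*` skipped, reads taken as stored without
reverse-complementing by flag — QC describes the stored bases). BAM goes
through pysam. Gzip is detected by the `.gz` extension or the `1f 8b`
magic bytes.

**Phred encoding** is resolved from the minimum quality character observed
across the whole file: codes 33–63 select offset 33 ("Sanger / Illumina
1.9"), codes ≥ 64 select the legacy offset 64. Codes below 33 are fatal.
A consequence worth knowing when constructing synthetic data: a file whose
every quality is ≥ 31 (char ≥ 64) is indistinguishable from legacy-encoded
data and is reported as offset 64, exactly as the reference tool would.

## Position grouping

Positional tables pool read positions into base groups. Reads up to 75 bp
get one group per position; longer reads keep singletons for positions 1–9
and then use bins of width 5, widening to 10/50/100/500 as the maximum
read length crosses 200/300/1000/2000 bp. `--nogroup` forces singletons.
This reproduces the reference tool's "Base" column labels (e.g. for 150 bp
reads: `1`…`9`, `10-14`, …, `145-149`, `150`).

## Module definitions and grading

All threshold comparisons are strict (a value exactly at a threshold does
not trip it). Defaults live in `readqc/configuration/limits.txt` and can
be overridden with `-l`.

- **Per base sequence quality**: per group, the mean and the 10/25/50/75/90
  percentiles of the pooled quality histogram. Percentile *p* is the lowest
  quality whose cumulative count reaches *p*% of the group total (so the
  median of {10×1, 20×1, 30×2} is 20). Warn when any lower quartile < 10
  or median < 25; fail at < 5 / < 20.
- **Per tile sequence quality**: tile ids parsed from Illumina headers
  (≥ 7 `:`‑fields → field 5; 5–6 fields → field 3). Each cell is the
  tile's mean quality minus the unweighted across-tile mean for that
  group. The grade keys on the largest drop below the average: warn > 5,
  fail > 10. The module is omitted when no tile ids parse. Every read
  contributes (no subsampling).
- **Per sequence quality scores**: histogram of per-read mean quality
  (truncated toward zero). Graded on the mode: warn < 27, fail < 20.
- **Per base sequence content**: %A/%C/%G/%T of unambiguous calls per
  group; graded on the maximum of |%A−%T| and |%G−%C|: warn > 10,
  fail > 20. A group consisting only of N calls reports zeros and is
  excluded from grading.
- **Per sequence GC content**: per-read GC% uses the full read length
  (including N) and half-up rounding. The theoretical curve is a normal
  density located at the distribution mode and scaled so its bin sum
  equals the read count. The mode is taken from a 5-bin moving-average
  smoothing and refined by the center of mass of the ±5 surrounding bins;
  without this, near-ties between adjacent bins move the raw argmax by a
  whole percent and inflate the deviation statistic by ~15 points. The
  scale is the RMS deviation of the observed mass about that location.
  Grade: deviation Σ|obs−theo|/total × 100, warn > 15, fail > 30. The
  statistic carries ~1/√n sampling noise (≈ 4 points at 10,000 reads,
  ≈ 15 at 1,000), so very small libraries can warn on noise alone — also
  true of the reference tool.
- **Per base N content**: %N per group over the reads reaching those
  positions; warn > 5, fail > 20.
- **Sequence length distribution**: one row per length; when lengths vary,
  the smallest "nice" interval (1, 2, 5 × 10^k) giving at most 50 bins.
  Warn when lengths vary; fail when a zero-length read is present.
- **Sequence duplication levels**: the tracker stores the first 100,000
  distinct sequences (reads longer than 75 bp are keyed by their first
  50 bases) and keeps counting stored keys to the end of the file. For a
  sequence seen `c` times, the chance it never entered the tracker is
  ∏_{i=0}^{L−1} (T−c−i)/(T−i) with `T` total reads and `L` the read count
  when the tracker filled; dividing by the complement extrapolates
  tracked counts to the whole library. The correction applies only when
  the tracker actually filled — otherwise every distinct sequence was
  tracked and observed counts are exact. Counts are binned at levels
  1–9, >10, >50, >100, >500, >1k, >5k, >10k, and the headline number is
  the Total Deduplicated Percentage (corrected distinct / corrected
  total); warn < 70, fail < 50.
- **Overrepresented sequences**: tracked sequences whose whole-file count
  exceeds 0.1% of reads, sorted by count. Each is annotated with the best
  contaminant sharing an ungapped window of ≥ 20 aligned bases with at
  most one mismatch (both orientations), else "No Hit". Warn > 0.1%,
  fail > 1%.
- **Adapter content**: a read matches an adapter at the earliest position
  where the full adapter occurs, or where an adapter prefix of ≥ 12 bases
  is flush with the read's 3′ end. The curve is cumulative: at position
  *p*, the percentage of reads (of length ≥ *p*) with a match at or
  before *p*; positions within 11 bp of the read end are not reported
  (no 12-base match can start there). Warn > 5%, fail > 10%.
- **Kmer content** (disabled by default, `kmer ignore 1`): positional
  7-mer counts; a k-mer is reported when its count at some position
  exceeds the expectation from its overall frequency with a binomial tail
  probability < 0.01. The module is graded on −log10 of the smallest
  p-value against the kmer warn/error limits. The exact reference
  statistic is unspecified; this module is a documented approximation.

## Output

`fastqc_data.txt` opens with the `##FastQC\t0.11.8` dialect marker —
downstream parsers dispatch on it — followed by `>>Title<TAB>grade`
blocks terminated by `>>END_MODULE`, LF endings, no timestamps, numbers at
up to 10 significant digits. `summary.txt` is one
`PASS|WARN|FAIL<TAB>title<TAB>filename` line per module. The HTML report
embeds every plot's data as JSON and renders with the Plotly library
loaded from a CDN URL, keeping the combined footprint of the three files
well under 1 MB even for large inputs (report size depends on read length,
not read count).

## Synthetic data

`readqc.fixtures.FixtureSpec` generates FASTQ with planted structure —
fixed or ranged lengths, constant or linearly graded quality with optional
Gaussian jitter, global base-composition bias, exact-count duplicate
blocks, an adapter inserted at a known position in a known fraction of
reads, cycled tile ids with per-tile quality offsets, and per-base N
injection — and returns a manifest of the exact planted truths. One seeded
generator drives all randomness; equal specs give byte-identical files.

What the generator does *not* emulate: positional error-profile
correlations, quality-by-base dependence, fragment-length biology,
bisulfite or UMI structure, and real contaminant mixtures. Passing tests
therefore demonstrate correctness of the statistics and grading on known
inputs, not robustness to every artifact of real libraries.

`two_pass_oracle` recomputes every accumulator field naively (whole file
in memory, per-character loops) and is kept independent of the streaming
implementation; equality on randomized fixtures is part of the test
suite. `compare_reports` diffs two data files at a relative tolerance
(default 1e-2) per numeric cell.

## Numerical and degenerate-input choices

- Per-read GC rounds half-up; per-read mean quality truncates toward
  zero; Basic Statistics %GC is computed over unambiguous calls and
  printed as a rounded integer.
- Quality histograms are stored on the raw char−33 scale and shifted by
  the detected offset at postprocessing, so encoding detection can happen
  after the single pass.
- An empty input produces a report containing only Basic Statistics
  (Total Sequences 0) rather than crashing; data-dependent modules are
  skipped.
- Ties in mode searches resolve to the lowest bin.
- The duplication tracker's `count_at_limit` records the read index at
  the moment the last new key was admitted.

## Problem sizes used in the test suite

Unit tests run on hand-sized inputs; boundary-grade fixtures use 1,000 to
10,000 reads, sized so that each statistic's sampling noise is small
relative to its distance from the nearest threshold (the GC deviation
statistic is the binding case, hence 10,000 reads for its pass fixture).
The acceptance script measures the output footprint on a 100,000-read,
150 bp library.

## Known limitations

- The contaminant list shipped is a curated subset of common Illumina
  adapter/primer sequences, not an exhaustive catalogue; users can supply
  a full list with `-c`.
- `-t/--threads` is accepted for pipeline compatibility, but processing
  is sequential.
- The kmer module's statistic approximates, rather than reproduces, the
  reference implementation (see above), and is off by default.
- Base-call qualities above Phred 93 (chars past `~`) cannot be
  represented, matching the printable-ASCII contract of FASTQ.
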