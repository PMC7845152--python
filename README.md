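# readqc

Single-pass, FastQC-compatible quality control for sequencing reads.

Quality control is the first step of essentially every sequencing
pipeline: before mapping or assembly, one checks the positional
distribution of base calls and Phred quality scores, the per-read GC
distribution, duplication levels, and contamination by adapters and
library-preparation sequences. The de-facto standard report format is
FastQC's, and a large ecosystem (MultiQC-style aggregators, fastqcr-style
parsers, pipeline glue) consumes its `fastqc_data.txt` / `summary.txt`
dialects.

`readqc` produces those reports from a single streaming pass over the
input. Instead of running each analysis module over the reads
independently, one centralized reader updates every sufficient statistic
per read — positional base/quality counts, per-read GC and mean-quality
histograms, per-tile quality sums, a bounded duplication tracker and
cumulative adapter-match counters — and all modules are derived afterwards
from that accumulator. Memory is bounded by the longest read, not the
file size: one read is held at a time.

It is intended for bioinformaticians who want FastQC-equivalent grades
and machine-readable reports as a drop-in pipeline component, plus a
library API for programmatic QC and a deterministic synthetic-read
generator for testing.

## The statistics at the core

- **Per-position quality quantiles.** For each base group the pooled
  quality histogram yields the mean and the 10/25/50/75/90 percentiles,
  where percentile *p* is the lowest quality *q* with
  `cum(q) ≥ p/100 · n`. Grades key on the median and lower quartile.
- **Duplication extrapolation.** The tracker stores the first 100,000
  distinct (truncated) sequences and counts them through the whole file.
  A sequence observed `c` times escaped tracking with probability
  `∏_{i=0}^{L−1} (T−c−i)/(T−i)` (`T` reads total, `L` reads seen when the
  tracker filled), so its corrected count is
  `c / (1 − ∏_{i=0}^{L−1} (T−c−i)/(T−i))`. The headline "Total
  Deduplicated Percentage" is corrected-distinct over corrected-total.
- **GC deviation.** The observed per-read GC% histogram is compared with
  a normal curve located at the (smoothed) mode, scaled to the read
  total; the statistic is `Σ|obs − theo| / n × 100`.
- **Adapter content.** Cumulative percentage of reads in which a known
  adapter (full match anywhere, or a ≥ 12 bp prefix flush with the 3′
  end) has appeared at or before each position.

Grading thresholds ship in `readqc/configuration/limits.txt` in FastQC's
limits dialect and can be replaced per run. See `docs/methods.md` for the
full module-by-module definitions and numerical choices.

## Worked example

Generate a small synthetic library with planted structure, then run QC:

```python
from readqc.fixtures import FixtureSpec, generate_fastq

spec = FixtureSpec(n_reads=2000, length=100, quality=(38, 26), seed=11,
                   tiles=[2101, 2102], adapter=("AGATCGGAAGAG", 60, 0.15),
                   duplicates=[(None, 40)], n_rate=0.005)
generate_fastq(spec, "example.fq")
```

```
$ readqc example.fq -q
$ cat example_fastqc/summary.txt
PASS	Basic Statistics	example.fq
PASS	Per base sequence quality	example.fq
PASS	Per tile sequence quality	example.fq
PASS	Per sequence quality scores	example.fq
PASS	Per base sequence content	example.fq
PASS	Per sequence GC content	example.fq
PASS	Per base N content	example.fq
PASS	Sequence Length Distribution	example.fq
PASS	Sequence Duplication Levels	example.fq
FAIL	Overrepresented sequences	example.fq
FAIL	Adapter Content	example.fq
```

The two failures are exactly the planted defects: the Illumina Universal
Adapter inserted at position 60 in 15% of reads trips the adapter module
(threshold: fail above 10% of reads), and the 40-fold duplicated sequence
is 2% of the library, far above the 1% overrepresentation fail threshold.
The quality gradient (38 → 26) and the two tiles with no offset stay
within pass bounds. The data file opens with the dialect marker and the
usual first block:

```
##FastQC	0.11.8
>>Basic Statistics	pass
#Measure	Value
Filename	example.fq
File type	Conventional base calls
Encoding	Sanger / Illumina 1.9
Total Sequences	2000
Sequences flagged as poor quality	0
Sequence length	100
%GC	50
>>END_MODULE
```

and the duplication block reports the corrected headline number
(`#Total Deduplicated Percentage	98.05` here: 40 duplicate copies among
2000 reads leave 1961 corrected-distinct sequences).

Three files are written per input into `<name>_fastqc/`:
`fastqc_data.txt` (full numeric tables), `summary.txt` (one grade line
per module) and `fastqc_report.html` (interactive Plotly plots; the plot
library is referenced by CDN URL so the report stays small).

The CLI mirrors the reference tool's flags: `-o/--outdir`,
`-f/--format {fastq,sam,bam}`, `-a/--adapters`, `-c/--contaminants`,
`-l/--limits`, `-q/--quiet`, `--nogroup`, `-t/--threads`; unrecognized
reference-tool flags are warned about and ignored rather than fatal.

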