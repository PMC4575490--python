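# titrabench

Cross-platform transcriptional-profiling evaluation: transcript-pattern
probe mapping and titration-based signal, fold-change, and concordance
metrics, with a fully synthetic multi-platform titration generator.

## The problem

Comparing expression platforms (microarrays vs RNA-seq protocols) by gene
symbol alone confounds true platform differences with *which transcripts*
each platform's probes actually measure. `titrabench` implements the
stricter comparison construct of a **transcript pattern**: a gene plus the
exact set of its transcripts jointly targeted by a feature, derived by
intersecting probe genomic coordinates with the exon structure of every
isoform. Features on different platforms that map to the same transcript
set quantify the same RNA species; only those define a pattern, and a gene
may contribute several patterns.

The evaluation design is a five-sample titration between two pure RNA
sources A and B (samples with B-fractions f = 0, 0.75, 0.9375, 0.984375, 1),
so the expected abundance of gene *g* in sample *s* is

    E[x_gs] = f_s · e_B(g) + (1 − f_s) · e_A(g)

Against this linear truth the package computes, per platform:

- **signal range** (five-number summaries of raw values in the pure samples)
  and **signal-to-background** (mean 99th-percentile signal / background;
  for count data the background is a *quasi-background*: the median over the
  three mixtures of the 99th percentile of counts from "noise" genes —
  genes counted only in mixtures, never in either pure source);
- **titration fidelity**: per-feature Pearson r of value vs f, and the
  fraction of features with |r| > 0.5;
- **fold-change metrics** on the four contrasts vs pure A: absolute
  fold-change (ratios < 1 reciprocated), per-contrast and overall means,
  the fraction of genes with FC-vs-titration r > +0.5, and fold-change
  **enhancement** (relative % gain from detection-call or pattern
  restriction);
- **fold-change compression** against a reference platform: OLS fit of
  log2 ratios, with compression = (1 − slope) · 100;
- **qPCR concordance**: delta-delta Ct fold-changes (2^−ΔΔCt with
  housekeeping normalization, Ct QC at >40 cycles / CV > 30 %) compared
  with platform fold-changes via a four-way classifier (compressed /
  opposite / overestimate / concordant); the concordance rate is the
  percent of concordant + overestimate calls.

Feature-level values are summarized to pattern/gene level with a one-step
Tukey biweight on log2(value+1); arrays are quantile normalized; counts
get a +1 pseudocount and library-size CPM scaling with detection at
cpm > 0.25.

The `simulate` module generates the whole study in silico — multi-isoform
annotation, per-platform probes (with optional multi-mapping/partial
decoys), and expression matrices where array platforms respond as
`background + gain·abundance^c` (the exponent c plants a known fold-change
compression) and sequencing platforms draw negative-binomial counts — so
every metric can be validated against planted ground truth.

## Worked example

`python examples/04_foldchange_compression.py` simulates a faithful
reference platform and one with planted response exponent 0.6, then
recovers the compression:

```
ref: overall mean |FC| = 2.69; genes with FC r>+0.5: 77%
cmp: overall mean |FC| = 1.72; genes with FC r>+0.5: 65%

log2-ratio fit cmp ~ ref: slope=0.595  R2=0.967  compression=40.5%
enhancement example: 5.42 -> 8.88 folds = 64% gain
```

The regression slope recovers the planted exponent (0.595 ≈ 0.6), i.e.
the platform reports log2 fold-changes scaled down by ~40 % — exactly what
(1 − slope)·100 quantifies. The enhancement line shows the relative-percent
convention: moving from 5.42 to 8.88 folds is a 64 % gain.

The other scripts in `examples/` each demonstrate one capability
(titration design, pattern derivation, signal metrics, qPCR concordance,
and the end-to-end pipeline). A full run is also available from the shell:

```
titrabench all --seed 11 --outdir titrabench_out
```

which writes the annotation (GTF), probes (BED6), matrices (TSV), pattern
table, per-platform metric tables and a `summary.json` report.

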