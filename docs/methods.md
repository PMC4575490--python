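# Methods

## Titration model

The benchmark rests on mixing two pure RNA sources so truth is known up to
per-gene baselines: with source-B fraction f, the expected pre-noise
abundance of gene g is `f·e_B(g) + (1−f)·e_A(g)`. The canonical series uses
f = 0, 0.75, 0.9375, 0.984375, 1. Sample labels of the form `AG<a>BM<b>`
are read as *a* parts source A per *b* total parts (f = 1 − a/b): the
alternative literal reading "a parts A : b parts B" would give f = b/(a+b)
(e.g. 0.8 for 1:4), which contradicts the canonical percentage series this
package treats as authoritative; the label parser therefore implements the
1-in-n-total convention and the conflict is noted here once.

## Synthetic data generator

The generator emulates the *structure* of a two-source, five-sample,
multi-platform titration study — not any particular dataset's content.

**Annotation.** Each simulated gene lays down 2–8 non-overlapping exon
"slots"; each isoform takes a random sorted subset always containing the
first and last slot. Exons are gene-level objects shared between isoforms,
which makes "the set of transcripts containing this exon" well defined —
the primitive the pattern machinery needs. Coordinates are 0-based
half-open (BED convention) in memory; GTF output uses 1-based inclusive.
Strand is recorded but ignored for interval intersection (probes are
assumed sense-matched).

**Probes.** Probes of fixed length are placed fully inside exons, either
uniformly over slots or 3′-biased (weights proportional to slot rank,
mirrored on the minus strand). A configurable `decoy_fraction` of probes is
emitted as multi-mapping (a second spurious genomic hit) or partial
(slid half-past the exon boundary) to exercise the ambiguity filter.

**Expression.** Array-like platforms emit
`signal = background + gain·abundance^c · exp(σZ)`, Z standard normal.
The power-law exponent c ∈ (0, 1] is the compression knob: a log2
expression ratio scales by exactly c, so the cross-platform log2-ratio
regression should recover c as its slope — this makes compression a
*recoverable* planted parameter rather than an ad-hoc distortion.
Detection p-values are the survival probability of the observed signal
under a log-normal pure-background null (σ floored at 0.1 so noise-free
runs still produce graded p-values). Negative-control features sit at
background.

Sequencing-like platforms emit per-exon negative-binomial counts with mean
`library_size · abundance^c · exon_length · K`, where K is a constant fixed
from the mean of the two pure-source totals. Fixing K (rather than
renormalizing each sample to an exact library size) keeps the NB mean
strictly proportional to abundance across the titration — the property the
mixture-linearity invariant tests — at the cost of library sizes
fluctuating mildly with composition, as real sequencing depth does around
its target. Dispersion α gives Var = μ + αμ²; α = 0 degenerates to
Poisson, and noise scale 0 emits the mean deterministically (used by
exactness tests). "Noise" genes (default 5 % of genes) have zero baseline
in both sources and receive, per mixture column with probability 0.35, a
uniform 1–12 count on one random exon — so gene-level noise counts stay in
the 1–12 range and are zero in the pure columns in every realization.

**Default study conditions.** Five samples; duplicate replicates per
platform (the study design's average); per-gene baselines log-normal
(log-mean 3, log-sd 1.3) with log2 differentials N(0, 1.5); array noise
σ = 0.3, background 20, gain 1; library size 2×10⁶, dispersion 0.05. The
default six-platform layout (four array-like, two sequencing-like) plants
compression exponents {1.0, 0.6, 0.5, 0.7, 1.0, 0.9} so the pipeline's
compression ordering is testable.

What the generator does **not** emulate: sequence-level effects (no reads,
no alignment, no GC or mappability bias), probe cross-hybridization,
isoform-level differential abundance within a gene (abundance is
gene-level), batch effects, and intensity-dependent array noise. Passing
tests therefore demonstrate correctness of the *metrics and mapping logic*
under the stated model, not platform performance claims about real data.

## Pattern derivation

Probes classed multiple/partial are removed first. A probe targets a
transcript iff **every** probe interval is fully contained in that
transcript's exon union — containment, not overlap, because a straddling
probe reports mixed signal (multi-interval probesets count a transcript
only if all intervals are contained). Probes matching no transcript or
transcripts of more than one gene are dropped. A (gene, transcript-set)
pair becomes a pattern iff at least one feature on every required platform
maps to exactly that set; identity is exact set equality, never subset, so
two patterns of one gene stay distinct data points. Sequencing exons enter
by their own transcript membership (set equality alone); whether they must
additionally be probe-targeted is left open by the construct, and the
equality-only choice is the permissive one.

## Numerical choices

- **Quantile normalization**: columns are replaced by the across-column
  mean of sorted values; ties within a column get the mean of the
  reference values over their rank span, which makes the transform
  idempotent.
- **Tukey biweight** (one-step): median m, MAD s, u = (x−m)/(c·s+ε) with
  c = 5, ε = 1e−4 — the conventional constants for probe-set
  summarization; weights (1−u²)² for |u| < 1. Summarization happens on
  log2(value+1), where multiplicative noise is roughly symmetric.
- **CPM**: pseudocount +1 is added *before* library-size scaling and is
  included in the library size (the stated order); the alternative
  (scale, then add) is available via a flag. Detection: cpm > 0.25
  (strict) in ≥ 1 sample for counts, p < threshold for arrays; a
  gene/pattern is detected iff any member feature is, in any sample.
- **Percentiles** use linear interpolation throughout (numpy's default),
  including the 99th percentiles in signal-to-background and
  quasi-background.
- **Correlations**: the titration x-variable is the B-fraction itself, not
  an ordinal index (the mixture expectation is linear in the fraction; an
  ordinal option exists for the fold-change fidelity). Zero-variance
  features are excluded from fidelity denominators — they carry no
  titration information — rather than counted as failures. Signal-level
  fidelity uses |r| > 0.5 two-sided; fold-change fidelity uses r > +0.5
  one-sided.
- **Fold-change tables**: replicates are averaged before all metrics;
  ratios are formed on the linear scale with values floored at 1e−6
  (flooring logged) so logs stay finite.
- **Compression**: unweighted OLS with free intercept, matching the linear
  trend-line convention; compression = (1 − slope)·100.
- **Enhancement** is relative percent, (refined − baseline)/baseline·100:
  the 5.42 → 8.88 = 64 % worked example disambiguates "difference" in
  favor of the relative reading.
- **Concordance classifier**: direction is the sign of the log2 ratio;
  the X/Y ratio is computed on absolute magnitudes (otherwise ill-defined
  across signs). "Either of them greater than 2 or less than 0.5" in the
  opposite rule applies to the individual magnitudes. The rule set leaves
  one cell uncovered — different directions with both magnitudes within
  (0.5, 2) — which is classified concordant (neither measurement claims a
  real change) and flagged in the call for transparency.
- **Ct QC**: a gene-sample cell fails when > 50 % of replicates exceed
  Ct 40 or the replicate CV exceeds 30 %; surviving out-of-range
  replicates are trimmed; replicate Ct values are averaged before ΔCt
  (QC already enforces replicate consistency). Ct uncertainty is not
  propagated into fold-change errors.

## Pipeline

`run_pipeline` executes simulate → pattern mapping → preprocessing →
signal metrics → fold-change metrics → optional concordance, writing GTF /
BED / TSV / YAML artifacts, a per-platform accounting table (total,
non-control, gene-level, detected, pattern-member counts) and a
`summary.json` that is byte-identical across reruns with the same seed.
The thin `titrabench` CLI wraps this for shell use; exit code 2 marks
config errors, 3 data errors.

## Test problem sizes

The verification suite uses deliberately modest simulations chosen as the
smallest sizes at which the checked effects are unambiguous: 2,000 genes ×
10 seeds for compression-exponent recovery (slope within ±0.05 of the
planted value; ordering strict on every seed), 800 genes × 6 seeds × 4
noise levels for the fidelity-vs-noise monotonicity (3-combined-SE band),
50 random genes against a brute-force intersection oracle for pattern
derivation, and ~1,000 randomized cases for the numeric kernels
(biweight, quantile, CPM, ΔΔCt) against independent loop-written oracles.

## Known limitations

Headline numbers from real multi-platform studies (gene-set sizes,
concordance ranges, average compression percentages) depend on deposited
data plus vendor annotation and are out of reach of a synthetic benchmark;
this package reproduces the *methodology* and its closed-form worked
examples exactly, and validates the estimators by parameter recovery.
Vendor preprocessing (RMA, median polish, background correction models)
and read alignment are out of scope: matrices enter as extracted signals
or mapped counts.
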