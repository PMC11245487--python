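# Methods

## The estimation problem

Signal-induced genes (immediate early genes, IEGs) are transcriptionally
inert before stimulation and short (typically ~10–20 kb). Elongation-rate
callers that track the 5′→3′ wavefront of polymerase need long gene bodies
and well-separated timepoints, so they cannot resolve rates on IEGs over a
0–10 min induction. The ROCC approach sidesteps the wavefront: it treats
each 50-bp bin of a gene's quantitation window as an independent
observation of how fast nascent-transcription coverage rises with time.

## Coordinate and region conventions

All coordinates are 0-based, half-open (BED). A gene is its TSS and pA
site; offsets are gene-oriented, so "+500 of the TSS" lies at lower
genomic coordinates on the − strand. Derived windows:

| window | gene-oriented span | default |
|---|---|---|
| promoter-proximal (PP) | [−100, +500) of TSS | `pp_up=100`, `pp_down=500` |
| gene body (GB) | [+500, L) | |
| 3′ end | [L, L+3000) | `three_prime_ext=3000` |
| ROCC region | [+500, L+3000) | GB ∪ 3′ |
| quartiles Q1–Q4 | partition of [0, L) | boundaries at ⌊kL/4⌋ |

Genes with L ≤ 500 bp would have an empty gene body and are excluded with
a warning rather than silently dropped. Quartile boundaries use floor
rounding, so widths differ by at most 1 bp and a 10-kb gene splits into
four exact 2.5-kb quartiles. Quartiles span TSS→pA (the gene's length),
not the ROCC region; ROCC bins past the pA site belong to no quartile.

## Coverage and binning

A coverage track is a set of sorted non-overlapping intervals per
chromosome; uncovered positions are 0. Binned values are **means per bp**
(not sums): a truncated final bin is averaged over its actual width, which
keeps bins comparable and makes constant coverage bin to itself. Binning
is computed analytically from interval overlaps (a prefix-sum over
interval mass evaluated at bin edges); the test suite checks it against a
dense per-base brute-force oracle. Bins are anchored at the gene's 5′ end,
so on the − strand the truncated bin sits at the genomic start.

Normalization: RPKM divides a bin count by (bin_width/1000)·(total/10⁶),
CPM by (total/10⁶). Spike-in scale factors follow the standard convention
factor_i = min_j(count_j)/count_i — the shallowest spike-in sample is the
reference — and can be overridden from a supplied table when factors come
from an external tool. Replicate merging is the per-base mean of
normalized tracks; a chromosome missing from one replicate contributes 0
there, with a warning.

## The ROCC regression

For measurement times (0, 5, 10) min the regression uses effective times
(0.5, 5, 10): IEGs carry no pre-induction signal, so an intercept would be
dominated by negligible t = 0 fluctuations; fixing the intercept at zero
and placing t = 0 at 0.5 min keeps empty bins interpretable (slope 0) and
conditions comparable. The zero-intercept least-squares slope per bin is
the closed form Σt·y/Σt², exact for y linear in effective time and equal
to a generic numeric least-squares fit through the origin (tested to
1e-10 relative).

The single-timepoint variant draws a two-point slope (y_t − y_0)/t for
t = 5 or 10 min, letting the 0-min sample exert maximal influence; it is
the variant used for the quartile breakdown. Signs are kept per bin; the
gene-level Proxy Rate is the mean of |slope| over the ROCC region
("absolute average"). Taking |mean| instead is available behind a flag —
the two coincide for purely induced genes and differ only on noisy bins.
Quartile membership is by bin midpoint, so boundary bins are never
double-counted; an empty quartile (possible for genes shorter than ~2 kb
past the region offset) is reported as NaN with a warning.

Proxy Rates are in signal·min⁻¹, linear in coverage scale; they order
conditions and genes but are not bp/min.

## The simulator and what passing tests show

The generator emits, per gene, condition and timepoint, a step-function
wave: density β behind a front at v·t bp from the TSS (β·pileup_gain past
the pA site), basal density ahead of it, basal-only at t = 0. Defaults:
v = 1000 bp/min (control) vs 2000 bp/min (accelerated condition, the 2×
contrast the estimator must resolve), β = 10 signal units/bp, basal = 0,
timepoints (0, 5, 10) min, Poisson noise at 100 expected counts per 50-bp
bin at density β (counts are drawn per bin and rescaled to density).
Genes are 10–16 kb — long enough that v ∈ {500, …, 4000} bp/min fronts
remain distinguishable within 10 min — and a fixed seed makes bedGraph
output byte-identical.

This emulates the *statistical* structure the estimator assumes: silent
start, advancing plateau, count noise, 3′ pileup. It does not emulate
promoter-proximal pausing dynamics, burst-like initiation, mappability or
library-prep biases, or between-replicate variance beyond Poisson, so
passing recovery tests demonstrate estimator correctness under the model,
not robustness to every artefact of real sequencing data. Negative
binomial noise is a noted extension.

## Clustering conventions

IEG clusters are inclusive thresholds on induction log2FC (≥1, 2, 3, 4 →
2-, 4-, 8-, 16-fold) over up-regulation only; membership is cumulative, so
cluster sizes nest. Non-DE genes are expressed genes within ±log2(1.4).
The expression filter requires min_count reads in min_samples samples,
both inclusive (defaults 10-in-6; use 50-in-4 for metabolically labelled
RNA data). The DE model that produces log2FC is out of scope; a plain
log2 ratio of mean counts with pseudocount 0.5 is provided as a
documented stand-in only.

## Quantitation choices

Region density is a per-bp mean, so PP/GB/3′ densities are comparable
across gene lengths. Condition log2FC uses pseudocount ε = 0.01
(configurable) to stay finite at zero density; it is antisymmetric in its
arguments. Box summaries follow Tukey: quartiles by linear interpolation
(numpy default, R type 7), whiskers at the most extreme data within
1.5×IQR of the box, outliers listed. Metagene matrices rescale each gene
body to a fixed number of near-equal segments (floor boundaries, per-bp
means), flanks binned at a fixed width, all rows reading 5′→3′.
Significance on paired contrasts is the two-sided Wilcoxon signed-rank
test from scipy, reported rather than re-derived; correlations between
rate vectors report Pearson, Spearman and Kendall (τ-b tie convention)
with their large-sample p-values.

## Problem sizes

The analysis scripts use 30 genes × 2 conditions × 3 timepoints; rate
recovery uses 50 genes with per-gene rates drawn uniformly from
500–4000 bp/min; the condition contrast uses 100 seeded replicates of 20
genes. These sizes give stable medians and correlations (Spearman ρ > 0.9
in recovery) while the whole suite plus the acceptance script runs in
well under a minute.

## Known limitations

- The Proxy Rate saturates once a front clears the whole ROCC region
  within the first induced timepoint; rates above ~(L+3000)/5 bp/min are
  not distinguishable on a gene of length L with the default grid.
- Replicate merging by per-base mean assumes tracks are already on a
  common normalization; it does not re-estimate scale.
- The spike-in factor rule is a convention; factors from external
  pipelines should be supplied directly when available.
- bigWig input is read-only and optional; bedGraph is the canonical
  dialect.
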