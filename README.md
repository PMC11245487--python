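# proxyrate

Quantitative analysis of RNA polymerase II elongation kinetics from
nascent-transcription (PRO-Seq-style) coverage time courses.

Immediate early genes (IEGs) are silent before stimulation, so classical
elongation-rate estimators that track the polymerase wavefront over long
gene bodies cannot be applied to these short, rapidly induced genes. This
package implements the **ROCC (Rate of Change in Coverage)** estimator:
for each 50-bp bin *b* of a gene's quantitation window, the normalized
coverage *y*<sub>b,t</sub> is regressed on time with the intercept fixed
at zero,

&nbsp;&nbsp;&nbsp;&nbsp;ROCC<sub>b</sub> = Σ<sub>t</sub> *t·y*<sub>b,t</sub> / Σ<sub>t</sub> *t*²,

over effective times *t* ∈ {0.5, 5, 10} min (the pre-induction sample is
positioned at 0.5 min so the abscissa stays positive). The gene-level
**Proxy Rate** is the mean of |ROCC<sub>b</sub>| over the window from
500 bp past the TSS to 3000 bp past the pA site. It is a rate *surrogate*
— not bp/min — that preserves the ordering of true elongation rates, which
is what condition contrasts need.

Around the estimator the package provides, as importable modules:

- `annotation` — BED gene models; promoter-proximal (−100/+500 of TSS),
  gene-body (+500 → pA), 3′-end (pA → +3000) and gene-length quartile
  regions, strand-aware and 0-based half-open throughout.
- `coverage` — bedGraph I/O (bigWig optional), gene-oriented 50-bp
  binning, RPKM/CPM scaling, spike-in scale factors, replicate merging.
- `clustering` — IEG classes from log2 fold-change thresholds
  (≥1/2/3/4 → 2-/4-/8-/16-fold, cumulative membership), expression
  filters, non-DE background (<1.4-fold either way).
- `quant` — region densities, condition log2FC, Tukey box statistics,
  scale-regions metagene matrices.
- `rocc` — ROCC slopes (global and single-timepoint variants), Proxy
  Rates, quartile breakdowns, rate benchmarking correlations.
- `simulate` — a wavefront simulator producing induction time courses
  with *known* per-gene elongation rates, plus synthetic DE tables, so
  every stage is testable without sequencing data.

## Worked example

The numbered scripts under `analysis/` run the whole study on simulated
data (30 genes, two conditions differing only in elongation rate —
control 1000 bp/min vs "depleted" 2000 bp/min — Poisson count noise):

```sh
cd analysis
python 01_simulate_timecourse.py
python 04_proxy_rates.py
```

prints

```
Median Proxy Rate by condition and variant (signal units / min):
condition  control  depleted
variant
global      0.5925    1.0366
single_10   0.6009    1.0003
single_5    0.5648    1.1957

Global variant: depleted/control median ratio = 1.75 (Wilcoxon signed-rank W = 0, p = 1.86e-09)
```

A doubled true elongation rate roughly doubles the median Proxy Rate in
every variant, and the per-gene contrast is uniformly positive (W = 0).
The quartile table from the same script shows the wave's position: at
5 min the control wave has only filled quartiles Q1–Q2 while the faster
condition already reaches Q3. `05_benchmark_rates.py` correlates Proxy
Rates with the simulator's true rates over 50 genes (Pearson r = 0.91,
Spearman ρ = 0.97, Kendall τ = 0.87), and `02_cluster_iegs.py` recovers a
requested IEG composition exactly (cumulative n = 236/69/34/16).

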