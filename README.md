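# circquant

Quantification and comparative analysis of circular RNAs (circRNAs) from
back-splice junction read counts, for plant (and other bulk) RNA-seq
experiments where circRNA abundance must be compared **across** organs or
sample types.

## The problem

A circRNA is evidenced by reads spanning its non-colinear back-splice
junction, so its abundance in a library is a small count `c_ij` (circRNA
*i*, sample *j*). Comparing such counts across organs is dominated by
differences in transcriptome composition: rRNA depletion efficiency and the
chloroplast read load vary strongly between photosynthetic and
non-photosynthetic tissues, so dividing by raw library size systematically
distorts circRNA abundances. Droplet digital PCR (ddPCR) provides absolute
copy numbers (copies per µg of total RNA) and can arbitrate between
normalization schemes.

`circquant` implements:

- **Six normalization schemes** `n_ij = c_ij · S / d_j` with per-sample
  denominators `d_j`: total reads `T_j`; back-spliced read sum `B_j`;
  median-of-ratios size factors `f_j` (the median over circRNAs of
  `c_ij / g_i`, `g_i` the geometric mean of circRNA *i* across samples);
  `T_j` minus rRNA and chloroplast reads; back-spliced sum excluding
  rRNA/chloroplast-derived circles `B'_j`; and raw reads on the endogenous
  marker gene *ACT2* (AT3G18780).
- **ddPCR quantification**: Poisson occupancy
  `λ = −ln(1 − n_pos/n_total)`, conversion to cp/µg through droplet volume,
  reaction volume and RNA mass, *ACT2* reference normalization, and a limit
  of quantification (LoQ) defined by replicate dispersion (sd ≥ mean).
- **Concordance evaluation**: Pearson correlation between normalized means
  and ddPCR means, pooled and per sample type, plus calibration of a
  normalized-read detection threshold from the ddPCR LoQ via a
  zero-intercept fit.
- **Filtering and set analyses**: ≥2-read support filter, two-caller
  intersection (CIRI2-style primary counts confirmed by a second caller's
  id set), replicate-reproducibility Venn regions, abundance thresholding,
  nuclear/chloroplast partition and organ-overlap sets.
- **Differential accumulation**: two-fold / p ≤ 0.05 pairwise organ
  comparisons (Welch t-test on log2 values), organ-specific calls,
  discrete high/medium/low/not-detected abundance classes with
  average-linkage clustered ordering, and circular-vs-linear correlation
  and enrichment (≥1.5×) analysis.
- **A synthetic-data generator** producing organ-structured truth
  (reproducible + stochastic one-off circRNAs, planted organ-specific
  circles), R−/R+ protocol effects (depth, circle enrichment, per-species
  RNase R loss), library composition statistics, droplet-level ddPCR
  replicates and linear-counterpart abundances — so every pipeline stage is
  testable against known ground truth.

A transcription of the published 8-circRNA × 4-sample-type ddPCR/RNA-seq
benchmark panel ships with the package (`circquant.load_benchmark_panel()`).

## Worked example

```python
import circquant as cq

tab = cq.concordance_from_panel(cq.load_benchmark_panel())
print(tab.rounded())
```

```
          library_size  backspliced_sum  size_factor  library_size_excl  backspliced_sum_excl  marker_gene
all               0.67             0.77         0.76               0.76                  0.75         0.77
seedling          0.76             0.75         0.76               0.78                  0.75         0.76
root              0.90             0.89         0.90               0.90                  0.89         0.90
leaf              0.92             0.92         0.92               0.92                  0.92         0.92
flower            0.87             0.85         0.88               0.87                  0.85         0.88
```

Pooled across sample types ("all"), raw library-size normalization agrees
worst with ddPCR (r = 0.67) while every composition-aware scheme reaches
0.75–0.77 — the quantitative basis for not normalizing circRNA counts by
library size. Within a single sample type all schemes are nearly equivalent
(root 0.89–0.90, leaf 0.92): composition differences, not the schemes
themselves, drive the cross-organ distortion.

The `examples/` directory contains one short script per capability
(normalization, ddPCR quantification and LoQ, concordance, filtering and
overlap sets, differential accumulation, circular-vs-linear comparison);
each builds or simulates a small input, runs the method and prints what the
numbers mean.

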