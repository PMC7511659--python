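# Methods

## Quantification model

The unit of circRNA evidence is the back-spliced read count `c_ij`
(circRNA *i*, library *j*). All six normalization schemes are per-sample
positive rescalings `n_ij = c_ij · S / d_j`, so within one sample the rank
order of circRNAs is identical under every scheme, and any statistic that
is invariant to a per-axis positive rescaling — Pearson correlations, fold
changes, abundance-class assignments — is invariant to the scale constant
`S`. `S` defaults to 10^6 (a per-million convention) and is recorded in the
run metadata; published normalized-read values appear to use a scale on the
order of the library size itself (values in "read units"), and any choice
is equivalent for every downstream result except the absolute numeric value
of the detection threshold, which is therefore calibrated, not assumed
(below).

Size factors are median-of-ratios on the back-spliced count matrix itself:
`f_j = median_i { c_ij / g_i }` over circRNAs whose geometric mean `g_i`
across samples is positive (no zero anywhere). Back-spliced matrices are
sparse, so the estimator can be undefined; the error message directs users
to the back-spliced-sum scheme in that case. Computing factors from the
circRNA matrix (rather than a whole-gene matrix) is a deliberate choice:
it is the only matrix guaranteed to exist in this package's inputs.

Replicate aggregation uses the arithmetic mean and the sample standard
deviation (ddof = 1; zero for a single replicate), appropriate at n = 4.

## ddPCR model

Droplet counts follow the standard Poisson partition estimator
`λ = −ln((n_total − n_pos)/n_total)` (copies per droplet), strictly
increasing in `n_pos` and undefined at saturation (all droplets positive).
Conversion to copies per µg of input total RNA uses three explicit
parameters: droplet volume (default 0.85 nL, the QX200 convention),
reaction volume (default 20 µL) and the RNA mass represented in one
reaction (default 0.05 µg — 1 µL of a 20 µL reverse-transcription reaction
primed with 1 µg). All three are configurable because different dilution
schemes move cp/µg proportionally.

Reference-gene normalization divides each target measurement by the mean of
the *ACT2* technical repeats within the same biological replicate, making
the result invariant to any common rescaling of cp/µg values.

**Limit of quantification.** A replicate series is called unreliable when
its sample standard deviation reaches its mean (CV ≥ 1) or its mean is
zero; the LoQ is the smallest observed mean among targets that are reliable
in *every* sample type, snapped to one significant figure. The CV ≥ 1 rule
operationalizes "dispersion comparable to the signal" and is recorded in
`LoqResult.rule`. For LoQ *calibration from a dilution series*, the
simulated panel uses 8 replicate measurements per concentration rather than
the 3 biological replicates of the assay itself: near the LoQ a reaction
contains only ~1–3 positive droplets, and a 3-point sample CV of such
discrete counts is too unstable to define a threshold. With the default
droplet statistics the calibrated LoQ lands at 40–70 cp/µg across seeds,
i.e. the droplet-partition noise floor itself produces a threshold of about
50 cp/µg.

## Concordance and threshold calibration

Concordance cells are Pearson correlations on raw (untransformed) mean
values — ddPCR means over 3 biological replicates against normalized means
over 4 — pooled over all (target, sample type) pairs and within each sample
type. Computing on raw values reproduces the published benchmark panel's
printed correlations; reported values are rounded to 2 dp, full precision
retained internally. One cell of the packaged panel (seedling,
library-size) computes to 0.756 from the panel's 1-dp printed inputs and
may round a unit of the last digit away from the published 0.75; tests
therefore compare at a tolerance of 0.005 (reporting) + 0.005 (input
rounding).

The detection threshold on the normalized-read scale is the image of the
ddPCR LoQ under a zero-intercept least-squares line fitted to pairs at or
above the LoQ (a circRNA absent from the RNA must yield zero expected
reads), snapped to the nearest one significant figure. Snapping to nearest
(rather than always up) keeps the threshold continuous in the fitted slope:
a hard ceiling at this resolution would jump from 10 to 20 on a 0.1%
slope perturbation.

## Filtering conventions

- The ≥ k back-spliced read support filter (default k = 2) pools evidence
  over the replicates of each library type ((organ, protocol) group); a
  per-replicate mode is available by flag. Thresholds are inclusive.
- The two-caller confirmation consumes only an id set from the secondary
  caller and matches coordinates exactly (no fuzzy junction matching);
  counts always come from the primary caller.
- The abundance filter applies to replicate-averaged normalized values per
  organ (a per-dataset grand-mean mode is a one-line variant on the
  aggregated matrix); the union over organs defines the analysis set.
- Coordinates are 1-based fully closed (`chrom:start-end`); conversion to
  BED's 0-based half-open intervals happens only in the BED writer.
  Chloroplast circRNAs are recognized by chromosome name membership in a
  configurable organelle set (default `{chloroplast, Pt, ChrC}`). Strand is
  carried but never used in computation.

## Differential accumulation

Fold changes use replicate means with a pseudocount of 0.5 on the
normalized scale (finite, direction-correct log2FC at zeros). Significance
comes from a two-sided Welch t-test on `log2(value + 0.5)` across
replicates — chosen for robustness to unequal variances at n = 4; the
test is a documented package choice, pluggable in principle, and recorded
in run metadata. A call is significant when |log2FC| ≥ 1 and p ≤ 0.05. No
multiple-testing correction is applied by default, matching the
p-value-threshold convention of the analyses this package supports; a
Benjamini–Hochberg option exists behind a flag. With fewer than 2
replicates the fold change is reported, the p-value is NaN, and the call is
never significant. An organ-specific circRNA is one whose comparison
against every other organ is a significant increase.

Abundance classes per organ: `high` = top `ceil(0.05 n)` detected values;
`medium` = strictly above the 80th percentile of detected values, excluding
high; `low` = remainder; `not_detected` = zero/absent. Ties break by the
stable row order, so the partition is deterministic and always satisfies
`|high| + |medium| + |low| = n_detected`. Heatmap ordering uses
average-linkage agglomerative clustering on Euclidean distances between
`log2(value + 1)` profiles.

Circular-vs-linear comparisons require the two matrices to declare the same
normalization tag (or leave it unset): ratios presuppose comparable units.
CircRNAs without a detected linear partner (intergenic, or silent host
gene) are excluded from the correlation, counted separately, and kept in
the ratio table with an absent linear value; a present circle with an
undetected partner counts as enriched.

## Synthetic data generator

The generator emulates a 4-organ × 4-replicate design at reference depth
~60.3 M read pairs (R−) and a 0.43× shallower, 10× circle-enriched R+
protocol, with organ-specific rRNA fractions (R− roots ~0.6–1.2% up to
leaves ~6–7.6%; R+ 0.27–3.2%) and chloroplast fractions (high in
photosynthetic tissues, ~0.5–2% in roots). Counts are Poisson around
`cp · noise · κ · T_eff` where `T_eff = T − R − P` is the effective
(informative) read pool and `κ` (capture coefficient, default 4·10⁻⁹ reads
per effective read per cp/µg) makes one back-spliced read ≈ 5 cp/µg at
reference depth — hence 10 normalized reads (in read units) correspond to
~50 cp/µg, tying the two detection thresholds together. Replicate noise is
lognormal with σ = 0.3 (CV ≈ 31%, a typical biological-replicate
dispersion).

The population mixes ~5% reproducible circRNAs (lognormal baseline,
median 3 cp/µg, σ = 1.5 on the log scale; multiplicative organ effects
σ = 0.4) with stochastic one-off molecules that exist in exactly one
(organ, replicate) isolate — and therefore in both protocol libraries of
that replicate, since one RNA isolate feeds both. These defaults place the
fraction of circRNAs detected in all four replicates in the low single-digit
percent range per organ, the regime the design emulates. Planted
organ-specific circles (default 5 per organ, 15 cp/µg baseline, 8-fold in
their organ) provide known positives for end-to-end recovery tests. RNase R
loss is a per-species Bernoulli (default survival 0.9, a free parameter not
anchored to measurement): a lost species vanishes from every R+ library,
mimicking hydrolysis followed by exonucleolytic digestion.

ddPCR simulation inverts the cp/µg conversion to a droplet occupancy and
draws positives binomially (15,000 droplets), with lognormal replicate
noise σ = 0.15; at low concentrations the droplet-partition noise dominates
and reproduces the large low-end CVs seen in real panels (CV ≈ 0.6–0.7 at
70 cp/µg).

Linear counterparts are bivariate-lognormal with the circle truth. The
configured circ–linear correlation is the **raw-scale** target (what a
Pearson correlation of abundances measures); the generator inverts the
lognormal attenuation formula
`r = (e^{ρ·σx·σy} − 1)/√((e^{σx²}−1)(e^{σy²}−1))` to obtain the log-scale
`ρ`, and raises an error when the target is infeasible at the configured
variances.

What the generator does **not** model: read-level sequence content, fuzzy
junction coordinates, caller-specific error modes, negative-binomial
overdispersion beyond Poisson (a configurable-dispersion variant is a
natural extension), batch effects, and organ-correlated stochastic
production. Tests passing on this generator therefore demonstrate the
pipeline's correctness and calibration under the stated noise model, not
robustness to caller artefacts or overdispersed real libraries.

## Problem sizes and numerical choices

Simulation-based checks run at 2,000 circRNAs × 16 libraries (the package's
chosen desk-scale design), 200-trial Poisson round trips at 15,000
droplets, and 127-pair circular-linear cohorts; all complete in seconds.
Dataset-scale candidate counts (thousands of candidates from tens of
millions of reads) are properties of deposited sequencing data and are
represented here only through the generator's scaled-down population.
Degenerate inputs fail loudly: zero denominators name the sample and
method; constant vectors refuse a correlation; saturated droplet counts
refuse a concentration; an empty caller intersection warns rather than
errors. Determinism is contractual: identical configurations (including
seeds) produce byte-identical outputs, and result writers render floats at
a fixed significant-digit precision with sorted metadata keys.
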