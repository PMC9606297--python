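# Methods

This note documents the models, estimators, numerical choices and
limitations behind `scna`.  Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Clonality from multi-region copy number

A patient contributes several tumour regions, each with an
allele-specific copy-number segmentation (raw minor/major copy number per
segment) and a sample ploidy.  The ploidy-normalised total copy number of
a segment is `raw_total_CN = log2((raw_minor + raw_major)/ploidy)`,
computed **per segment**; a segment is a gain when `raw_total_CN >
log2(2.5/2)` and a loss when `raw_total_CN < log2(1.5/2)`.  Both
inequalities are strict: a value exactly at a threshold is neutral.  A
total raw copy number of zero maps to the homozygous-null sentinel
(−inf), classified as loss.

A patient-level **consensus profile** uses the intersection segmentation
over the union of all regions' breakpoints, so every region contributes
exactly one value per consensus segment.  Per-region values are carried,
never averaged — clonality needs each region's own state.  Intervals
overlapping the (user-supplied, BED) mappability mask are removed, as are
consensus pieces not covered by every region.  A region additionally
carries **LOH** at a segment when `raw_minor < 0.25` (default;
configurable).  The 0.25 cut splits a true minor copy number of 0 from
one of 0.5 under symmetric noise.  A region "has loss" when it classifies
as loss *or* carries LOH; clonal = event in all regions, subclonal = in
at least one but not all.  Gain and loss labels are independent fields
per locus (different regions may gain and lose).  Single-region patients
cannot have subclonal labels; the classifier restricts the label set and
logs a warning.

Clonality is called per consensus segment and aggregated to genomic bins
by interval overlap; contiguous same-label segments are not merged into
larger "events", so event counts are segmentation-resolution dependent.
In cohort frequency tracks the denominator at a bin is the number of
patients with at least one consensus segment overlapping it; a bin
covered by no patient (e.g. fully masked) is reported missing, not 0.

## Gene-level copy number

Adjusted copy number (ACN) is on the ploidy-adjusted integer scale;
relative copy number (RCN) is log2-ratio, converted where needed by
`ACN = ploidy · 2^RCN` (default ploidy 2).  Continuous ACN is categorised
with half-open-on-the-left bins at 0.5/1.5/2.5/4.5 — consistent with the
integer conventions "gain = 3 or 4 copies, amplification ≥ 5" since 3 and
4 fall in [2.5, 4.5) and 5 in [4.5, ∞).  The 3-level view maps rounded
ACN ≤ 2 → "2", 3 → "3", ≥ 4 → "4+".  A gene takes the ACN of the segment
with the largest overlap, ties broken toward the higher copy number so
focal amplifications split across a breakpoint are not missed.  Missing
values are excluded from denominators, never imputed.  In marker-group
frequency differences the reference group is marker-neutral samples only
by default (`comparison="non_altered"` pools losses in instead); the loss
difference is reported on a reverse (negated) scale.

## Dose-response estimation

Each plate is standardized by the **median** control-well signal, so
untreated viability sits at 1 and the estimates are invariant to a global
rescaling of the raw signal.  Technical replicates enter as individual
points (never averaged) so the outlier rule keeps per-well semantics.

**Outlier flagging.**  A degree-4 polynomial in (centred, scaled) log
dose is fitted by iteratively reweighted least squares with Tukey's
bisquare ψ, tuning constant c = 4.685 (95% Gaussian efficiency,
configurable).  Wells with final robust weight < 0.4 are outliers and are
removed before curve fitting.  The residual scale is Huber's proposal-2
estimate by default.  We also provide the iterated normalised-MAD scale
(`scale_est="mad"`), but do not recommend it: once the redescending
weights kick in, the MAD of the downweighted residuals underestimates the
noise level of plates whose noise is proportional to signal
(multiplicative error), and good wells at the top of the curve get
flagged.  On simulated plates with one planted ×5 spike among 24 wells
the Huber-scale default flags exactly the spiked well in 99% of runs (the
spike itself is caught in >99%); the MAD variant false-flags extra wells
in ~20% of runs.  Non-convergence of the robust fit falls back to a
pass-through (no outliers) with a logged warning.  Degenerate plates with
(near-)zero residual scale — e.g. all responses identical — keep all
weights at 1.

**Spline fit and AUC/IC50.**  The cleaned standardized responses are
fitted by least squares on a cubic M-spline basis (non-negative,
unit-integral rescaled B-splines) over [min log dose, max log dose], with
interior knots at quantiles of the distinct observed log doses, count =
max(1, n_distinct − 4).  With the standard 8-point series this schedule
interpolates the per-dose means; the unconstrained interpolant can
overshoot between doses by up to ~0.03 on steep sigmoids.  A
monotone-non-increasing option writes the curve as `c0 + Σ aᵢ Iᵢ(x)` on
the I-spline (integrated M-spline) basis with `aᵢ ≤ 0` via bounded least
squares; it removes the overshoot and is the right choice when the truth
is known to be monotone.  AUC is the exact integral of the fitted spline
(closed-form antiderivative — the I-spline representation), divided by
the log-dose range so that a constant-1 curve has AUC 1 and AUCs are
comparable across drugs with different ranges.  IC50 is the lowest dose
in range where the fitted curve crosses 0.5 of control viability
(bisection between grid points; 512-point grid); if the curve never
crosses, the IC50 is censored.  Doses are handled in natural log
internally; the normalized AUC is log-base invariant.

**5PL cross-check.**  A five-parameter log-logistic
`c + (d−c)/(1+exp(b(x−e)))^f` is fitted by bounded nonlinear least
squares and reports its own AUC/IC50 plus the discrepancy against the
spline estimates; non-convergence flags the cross-check as unavailable
without touching the spline results.

**Cohort view.**  Per-drug Z-scores of AUC across samples feed
two-dimensional complete-linkage clustering: drugs on Euclidean distances
between rows of the drug–drug Spearman correlation matrix, samples on
Euclidean distances between Z-score rows.  Constant drugs (sd 0) are
dropped with a warning.

## Resampling and association statistics

All Monte-Carlo p-values use the add-one rule `p = (b+1)/(B+1)` with ties
counted as "at least as extreme" (conservative); exact enumerations
report the exact tail proportion.  Every stochastic routine takes one
integer seed and is bit-reproducible.

- **Permutation mean-difference test** (one-sided): statistic
  `mean(in) − mean(out)`, labels permuted.  The patient-level variant for
  SCNA co-occurrence permutes the marker gene's copy-number row across
  samples and re-derives every per-gene frequency difference per
  resample; the observed statistic is the mean difference (PI3K/RAS genes
  minus other cancer genes) of per-gene gain/amp frequency differences
  between marker-altered and marker-neutral samples.
- **Bootstrap correlation-set test**: both sets resampled with
  replacement; one-sided percentile-tail p for mean difference ≤ 0.
  Size-1 sets are allowed but warned (degenerate resampling).
- **Jonckheere–Terpstra**: statistic Σ over ordered group pairs of
  Mann–Whitney counts with ties counted ½.  Exact enumeration up to 10⁶
  distinct assignments (automatically chosen below 5·10⁴ — the recursion
  precomputes the pairwise comparison matrix and accumulates group
  contributions); otherwise vectorised permutation (B = 10⁴ default) or a
  tie-corrected normal approximation, mode logged.
- **Null simulation**: independent standard-normal drug responses and
  copy numbers uniform on {1..6} (marginals configurable; the summary is
  insensitive to the marginal shape at n = 20), gene count uniform in the
  configured range; per replicate the min/max/mean |Pearson r| over all
  drug × gene pairs is recorded.
- **GSEA**: classic weighted running sum (weight = |statistic|, exponent
  1); null by random same-size gene sets; NES = ES / mean |permuted ES|
  of the same sign; p is the sign-conditional tail
  P(|ES_perm| ≥ |ES| | same sign) with the add-one rule — the standard
  convention, calibrated at nominal level under the null (a doubled tail
  would halve the rejection rate).
- **Gene ranking**: genes with counts-per-million < 0.5 in more than 90%
  of samples are discarded; remaining genes ranked by the Welch
  t-statistic of high-vs-low group means on log2(CPM + 0.5).
  Zero-variance genes are dropped with a warning.
- **CN–expression correlation groups**: per-gene Spearman ρ; genes
  partitioned into driver (cancer ∧ prevalent), cancer non-prevalent,
  non-cancer prevalent, and the rest, with the prevalence threshold
  sweepable (default 5% cohort SCNA frequency); pairwise two-sided
  Mann–Whitney tests between groups.
- **Prediction ellipse**: `{v : (v−μ)ᵀΣ⁻¹(v−μ) ≤ χ²₂(0.95)}` with sample
  μ, Σ, after a rank-based normal-quantile transform where required;
  singular Σ yields a flagged degenerate segment.
- **Ordered association**: Pearson chi-square (unordered) plus the
  linear-by-linear statistic `M² = (N−1)r²` with equally spaced integer
  scores on both margins, 1-df chi-square reference.  Zero-margin levels
  dropped with a warning.
- **Pre-specified associations**: per gene–drug pair, a one-sided Wald
  t-test of the slope of AUC on log2 RCN and a one-sided JT across the
  3-level ACN, both in the pre-specified direction; configured
  non-independent or high-variability samples are excluded first; fewer
  than 4 usable samples marks the pair untestable.  No multiplicity
  correction inside the pre-specified set (a Benjamini–Hochberg option
  exists for exploratory sweeps).
- **KS sensitivity**: one-sample KS of observed p-values against
  Uniform(0,1), compared with the KS p-value distribution over random
  same-size sets drawn from the candidate universe.

## Synthetic-data generators

Each generator takes one integer seed, draws from a single
`numpy.random.Generator` in a fixed order, and returns machine-readable
ground truth computed from the generating model (closed form or
quadrature), never from the noisy output.

**Multi-region cohorts.**  Defaults: 30 patients, 2–6 regions each
(median 4), five 100-Mb chromosomes, base ploidy 2, Poisson(4) clonal and
Poisson(4) subclonal events per patient, event lengths log-uniform on
5–30 Mb, additive Gaussian noise (sd 0.1) on each raw allele copy number
truncated at 0, no mask.  The scale mirrors a multi-region whole-genome
cohort of a few dozen patients at a few regions each; event sizes are in
the chromosome-arm/focal-amplicon range, and noise sd 0.1 leaves planted
states ~2.5σ from the call thresholds — realistic difficulty without
making recovery trivial.  A gain adds one copy to the major allele in
carrying regions; a loss zeroes the minor allele (an LOH loss, the
dominant loss mode in a ploidy-2 genome).  Subclonal events go to a
uniformly chosen strict nonempty proper subset of regions.  Segments tile
each chromosome exactly (union of the patient's event breakpoints), so
all regions of a patient share a segmentation; consensus refinement
across discordant segmentations is exercised by hand-built fixtures in
the unit tests instead.  Events are placed non-overlapping by rejection;
an event that finds no free slot after 200 attempts is dropped (and hence
absent from the truth table).

**Plates.**  8-point half-log dilution series from 1 nM, technical
triplicates, 16 control wells, truth curve a 5PL with slope 1.5, lower
asymptote 0.1, upper 1.0, inflection at 100 nM; multiplicative noise
`1 + cv·N(0,1)` truncated at 0.01 with cv = 0.05; optional ×5 spike
outliers at uniformly chosen test wells, indices recorded.  Control wells
sit at the truth upper asymptote, so the standardized truth curve is the
5PL divided by its upper asymptote; truth AUC is its dose-range-normalized
integral by adaptive quadrature and truth IC50 the root at 0.5.

**Cohort genotypes.**  MYC amplified (ACN 5) in 30% of samples by
default; each panel gene altered (ACN 5) with probability
`sigmoid(logit(0.2) + LOR·1[MYC amplified])` for PI3K/RAS-pathway genes
and at baseline 0.2 otherwise.  The default panel lists 10 PI3K/RAS genes
and 10 other cancer genes.

**Expression coupling.**  Per gene, copy number uniform on {1..6};
expression = effect · CN + N(0, noise_sd) with group-specific effects;
methylation beta values centred at `0.5 − 0.3·effect` (clipped) plus
noise, so stronger CN–expression coupling co-occurs with lower
methylation.

What the generators do **not** emulate: breakpoint mechanisms or
length/position distributions of real genomes, purity/subclonal-fraction
mixtures, segmentation error from upstream callers, plate spatial
effects, biological (as opposed to technical) replicate variance, and
correlated gene–gene SCNA structure beyond the single planted
co-occurrence effect.  Passing tests therefore demonstrate correctness of
the estimators under the stated noise models, not performance on real
sequencing data; the raw-copy-number noise level is a free parameter, not
calibrated to any cohort.

## Numerical and design notes

- Intervals are 0-based half-open (BED) everywhere; a `--one-based` read
  option converts inclusive 1-based input.
- `raw_minor > raw_major` rows are normalised by swapping, with a
  warning; overlapping segments within a region are a hard error naming
  the overlap and line number.
- The SEG-like TSV dialect uses a commented header line; frequency tracks
  are also written as bedGraph (missing bins skipped).
- Pipeline runs emit a JSON manifest (tool version, config hash, input
  checksums, per-stage seeds); identical configs reproduce outputs
  bit-for-bit.
- Problem sizes in the test suite and acceptance script (10–50 simulated
  patients, 100–200 plates, 200 calibration replicates, B ≈ 200 for
  calibration loops and up to 4·10⁴ for enumeration comparisons) were
  chosen so each check has enough resolution for its tolerance while the
  whole suite stays fast; all are single-CPU.

## Known limitations

- Clonality is resolved at consensus-segment granularity; an event
  boundary-matching rule across regions (same breakpoints vs any overlap)
  is intentionally not imposed.
- The "MYC diploid" comparison group excludes marker-loss samples by
  default; pooling them is a documented option, and results can differ
  when losses are common.
- The unconstrained spline interpolates the standard 8-dose design;
  between-dose values are spline interpolants, not data.
- The 5PL fit can sit in a local minimum for very shallow curves; it is a
  cross-check only and never replaces the spline estimates.
- Exact JT enumeration is exponential; above 10⁶ arrangements only
  permutation/normal modes are available.
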