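# Methods

This note documents the models, statistics and numerical choices behind
`tetrameth`, and what the synthetic-data suite does and does not establish.

## Bisulfite clone methylation

Bisulfite conversion deaminates unmethylated cytosines to uracil (read as T)
and leaves 5-methylcytosine intact. For a cloned PCR molecule aligned to the
unconverted reference, each reference CpG cytosine is called methylated (C),
unmethylated (T) or non-informative (any other base or a deletion — the
target region carries polymorphic CpGs). Reads whose length differs from the
reference are anchored by global pairwise alignment performed in "bisulfite
space" (C collapsed to T on both sequences), so conversion itself never
counts as a mismatch. A molecule is rejected as incompletely converted when
more than 5% of the reference's non-CpG cytosines are retained as C; the
threshold is configurable, and the 5% default reflects common bisulfite QC
practice.

Per-molecule methylation is `100 × methylated / (methylated + unmethylated)`
with non-informative sites excluded from the denominator. Clone summaries are
the mean and SD of molecule percents over conversion-passing molecules;
since reporting conventions vary on whether conversion failures are
excluded from clone means, the filter is an explicit argument (`require_conversion`).

The variance partition is a one-way sum-of-squares decomposition of molecule
percents by clone, reported as percents of total SS (among + within = 100
exactly). This "explained variance" reading is exactly reproducible, unlike
REML variance components, and matches how the split is usually quoted.

The per-CpG "informativeness" statistic is the Pearson correlation, across
molecules where the site is informative, between the site's binary state and
the molecule's overall percent. Sites with zero variance are *undefined*
(NaN), never 0. The focal site is included in the overall percent by default (either
convention is defensible); `exclude_focal=True` removes it.

## MS-qPCR and relative demethylation

Quantification cycles are called at the maximum of the second derivative of
the fluorescence curve: Savitzky–Golay smoothing (window 5, order 3),
discrete second differencing, then parabolic interpolation around the
discrete maximum, clipped to ±1 cycle. For a logistic curve the
second-derivative maximum precedes the midpoint by `ln(2+√3)/ln E` cycles;
only Cq *differences* enter any downstream quantity, so this constant offset
cancels. Curves whose total rise is under 10× the smoothing-residual noise
report "no Cq"; between 10× and 20× the call is flagged low-confidence; a
curve already at ≥80% of its final level on the first cycle raises an error
(missed exponential phase).

The relative demethylation level of a sample is

RDL = E^[(Cq_den − Cq_u)_sample − (Cq_den − Cq_u)_reference],

where the unmethylated-specific reaction is the numerator and the
denominator reaction is methylated-specific (LINE-1) or
methylation-independent (SST1); the formula is identical, the denominator's
meaning is recorded in metadata. Amplification efficiency defaults to E = 2:
every sample is normalized against the same reference DNA, which cancels
first-order efficiency bias; a per-assay efficiency parameter is exposed.
Duplicate reactions are averaged on the Cq scale, as in standard qPCR
practice. Missing Cq values propagate to a missing record rather than
raising.

Somatic demethylation is ΔRDL = log2 RDL_tumor − log2 RDL_normal, classed as
strong (ΔRDL > 3), moderate (1 < ΔRDL ≤ 3) or none (ΔRDL ≤ 1). The conventional
thresholds leave equality unassigned; this package assigns boundaries
downward (1 → none, 3 → moderate) and tests both sides of each boundary.

Strongly demethylated tumors are alternatively identified as regression
outliers: OLS of tumor on normal log2 RDL, flagging tumors above the upper
95% *prediction* interval for a new observation. The prediction band (not
the mean-response band) is the default because an outlier rule must enclose
ordinary new patients; a `band="mean"` switch is provided.

## Nuclei morphometry

Genome doubling doubles nuclear volume, scaling projected area by
`2^(2/3) ≈ 1.587` under isotropic growth. Area distributions are summarized
by mean, SD (n−1) and CV = SD/mean. Mode detection runs a Gaussian KDE on
log-areas (right-skewed data) with Silverman's bandwidth, scaled by an
optional `bw_adjust`; peaks below 1% relative prominence are treated as
noise. The suggested ploidy threshold is the first antimode above the
principal mode, *capped at principal × 2^(2/3)*: a diploid/tetraploid
boundary cannot lie beyond the area a doubled-volume nucleus would have, and
an antimode beyond the cap means the doubled mode was merged into a higher
cluster by the bandwidth. When no valid antimode exists the cap itself is
the threshold. Notably, a small tetraploid subpopulation (~10–20% weight)
under realistic dispersion produces only a *shoulder*, not a separate KDE
peak — the mixture density is then genuinely unimodal, and the
volume-scaling fallback is the correct, not a degraded, answer.

Clones are split into small/large nuclear size by average-linkage
agglomerative clustering on mean area cut at two groups, with a
deterministic label-order tie-break.

Equality of CVs across samples uses the Feltz–Miller asymptotic statistic:
with mᵢ = nᵢ − 1 and pooled c̄ = Σmᵢcᵢ/Σmᵢ,
`D = Σmᵢ(cᵢ − c̄)² / [c̄²(0.5 + c̄²)] ~ χ²(k−1)`. The test assumes
approximately normal data: at the generator's default lognormal shape
(σ = 0.18) the empirical type-I error at α = 0.05 is ≈0.06, but it grows
anticonservative for strongly skewed data (≈0.09 at σ = 0.3, ≈0.10 at
σ = 0.42). Conclusions from heavily skewed area distributions should be
checked by resampling.

## Two-type diploid/tetraploid growth model

State: diploid (D) and tetraploid (T) abundances per diploid generation.
Each diploid mitosis fails cytokinesis with probability p, consuming the
mitosis and yielding exactly one tetraploid cell; tetraploids never revert
and complete ρ ∈ (0, 1] divisions per diploid generation:

D' = 2(1−p)·D, T' = 2^ρ·T + p·D.

The "80% relative proliferation" is read as ρ = 0.8 divisions per diploid
generation (growth factor 2^0.8), the exponential-growth interpretation;
with p = 0.03 it reproduces the ~13% equilibrium, which supports the
reading. Time is measured in diploid generations (60 days ≈ 40 generations
at a 36 h doubling time). When diploids outgrow tetraploids
(2(1−p) > 2^ρ) the tetraploid/diploid ratio has the fixed point
x* = p / (2(1−p) − 2^ρ) and the tetraploid fraction converges to
f* = x*/(1+x*) from any interior state; otherwise the model signals
tetraploid takeover. At p = 0.03, ρ = 0.8: f* = 13.1%, and the equilibrium
fraction increases in both p and ρ on the valid region.

Rate estimation inverts the fraction recursion by bisection on p ∈ [0, 0.5]
(tolerance 1e-8, fractions renormalized each generation to avoid overflow)
so that forward iteration from the first observed tetraploid fraction over
the stated generations matches the second. Confidence intervals are a
parametric bootstrap: karyotype counts are re-drawn binomially at both
timepoints (the second from the fitted trajectory's fraction) and re-solved;
solutions are clipped to the bisection bounds when a resample is
uninformative. For the observed 1/95 → 10/75 shift over 40 generations at
ρ = 0.8 the estimate is p̂ = 3.1% (~1 per 33 mitoses). Parameter-recovery
simulations (p = 0.05, 95-/75-metaphase karyotype subsamples) cover the
truth in ≥90/100 seeds.

The stochastic twin draws Binomial(D, p) cytokinesis failures and
Binomial(T, 2^ρ − 1) completed tetraploid divisions per generation, matching
the deterministic recursion in expectation; at n₀ = 10⁵ the final fraction
agrees with the recursion within Monte-Carlo error.

## Cohort association statistics

Fisher's exact test is two-sided by the minimum-likelihood rule (the
convention of mainstream statistical software), verified against exhaustive
rational-arithmetic enumeration in the test suite. Cross-tabulations support
three contrasts (none vs rest, strong vs rest, none vs strong excluding
moderate) with pairwise deletion of missing factor values; degenerate tables
are flagged rather than tested. Raw p-values are reported, as is standard
for descriptive association tables; Benjamini–Hochberg adjustment is
available through the usual statsmodels/scipy routes on the output table.
Pearson correlations carry Fisher-z confidence intervals; paired and
summary-statistic t-tests are pooled-variance. The continuous-response
analysis pairs per-factor two-group pooled t-tests with a joint OLS fit of
all factors (dummy coding, rank-checked; collinear designs are flagged).
Under the null, exact-test p-values are discrete and conservative, so their
distribution is super-uniform: calibration is asserted on the rejection
rate at α, not on distributional uniformity.

## Synthetic-data generators

The generators emulate the statistical structure the analyses assume, with
explicit seeds and ground truth returned alongside:

- **Bisulfite**: molecules draw their methylation probability from a Beta
  with clone mean μ and dispersion ρ (a = μ(1−ρ)/ρ, b = (1−μ)(1−ρ)/ρ;
  ρ → 0 degenerates to a binomial), sites are independent Bernoulli draws,
  polymorphic masking is per molecule-site, and conversion failures are
  per-molecule flags. Defaults: 28 CpGs, dispersion 0.2 — the large
  intra-clonal spread seen in repeat-element bisulfite data.
- **qPCR**: 4-parameter logistic fluorescence in cycle number, growth rate
  ln E, midpoint shifted by −ln(template)/ln E, additive Gaussian noise.
  The duplicate-level noise SD is a free parameter (replicate noise is
  assay- and instrument-specific); default 0 for oracle tests.
- **Nuclei**: lognormal mixture with components median-centered at the
  modal areas (defaults 65/115/180 μm², σ = 0.18, n = 2000), so closed-form
  tail masses are available as oracles.
- **Cohort**: normal-tissue SST1 log2 RDL ~ N(0,1); tumors add the class
  shift (none 0, moderate U(1.2, 2.8), strong U(3.5, 6)) plus N(0, 0.25)
  measurement noise; LINE-1 ΔRDL is built from the standardized SST1 ΔRDL
  at the target correlation (default 0.5); TP53 mutation odds (base
  p = 0.4) are multiplied by `tp53_odds` (default 10) in strong cases.
  Class fractions default to the observed cohort composition (~5% strong,
  ~12% moderate).
- **Trajectories**: the stochastic branching version of the growth model,
  above.

What passing on synthetic data does *not* show: the generators use idealized
noise (Gaussian fluorescence, exact lognormal areas, independent CpGs within
a molecule) and contain none of the batch structure, PCR bias, segmentation
error or population stratification of real data. They validate the
*computations*; accuracy claims about real samples inherit the assay's own
error characteristics.

## Problem sizes and determinism

Simulation-based tests use seeded generators throughout (seeds are function
arguments, never global state). Calibration suites run at the scale needed
for their assertion: 1000 replicate pairs (Feltz–Miller type I), 100 seeded
cohorts/trajectories (outlier sensitivity, bootstrap coverage), 2000-patient
cohorts for correlation targets, and n₀ = 10⁵ populations for
law-of-large-numbers checks; the whole suite completes in well under a
minute. The acceptance script's quantities are deterministic up to the
seeded bootstrap CI.

## Known limitations

- The growth model has no death, reversion or aneuploidy-progression terms;
  it is a two-type caricature adequate for equilibrium-fraction and
  rate-order questions only.
- Efficiency is fixed at 2 in the RDL formula; instrument-side efficiency
  corrections applied by qPCR software are not modeled.
- The bisulfite aligner is simple global anchoring; it is not a substitute
  for a dedicated bisulfite mapper on noisy reads.
- Feltz–Miller is anticonservative on strongly skewed data (above).
- The KDE threshold inherits bandwidth sensitivity; both the antimode and
  the volume-scaling derivations are exposed and neither is privileged.
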