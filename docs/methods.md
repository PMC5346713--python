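# Methods

This note documents the statistical procedures implemented in `mircna`,
the design choices made where the methodology was genuinely open, the
behaviour of the synthetic-data generator, and known limitations.

## Normalization

Raw panel counts are normalized to the cohort's common geometric mean.
For sample *s* with counts *c<sub>is</sub>*, the pseudocounted geometric
mean is *g<sub>s</sub>* = exp(mean<sub>i</sub> ln(*c<sub>is</sub>* + 1))
and the size factor is *f<sub>s</sub>* = *G*/*g<sub>s</sub>* with *G* the
geometric mean of the *g<sub>s</sub>* across samples.  Reported values are
log2(*c<sub>is</sub>* · *f<sub>s</sub>* + 1).

Choices: the pseudocount of 1 avoids log(0) on count data and is the
conventional panel-data default; the geometric mean is computed over **all**
probes rather than a top-expressed subset (both conventions exist for
NanoString-style panels; the all-probe choice is simpler and is what the
rest of the pipeline assumes).  Two exact consequences used by the tests:
*f<sub>s</sub>* · *g<sub>s</sub>* = *G* for every sample, and doubling one
sample's counts changes all normalized values by the same constant
log2(2)/*n* while leaving every between-sample contrast untouched.

## Differential expression

Per miRNA, a two-sided two-sample t-test on the normalized log2 values with
pooled variance (Student), not Welch.  Pooled was chosen because it is the
default of the classical array tools this workflow emulates and because the
same pooled formula reproduces printed clinical-table p-values from summary
statistics (below); Welch remains available via `equal_var=False`.
Significance uses the dual threshold *P* < 0.01 **and** BH-FDR *q* < 0.05.
A miRNA with zero variance in both groups has no defined t statistic; it is
reported with *p* = 1 and a `degenerate` flag and can never be significant.
log2FC = mean(group A) − mean(group B): positive means up-regulated in the
reference group A (the lexicographically first label by default).

"Top-*n*" tables rank the significant miRNAs of each direction by
|log2FC|, matching the usual per-direction presentation.

## Clustering

Samples are clustered by average linkage (UPGMA) on the distance
1 − Pearson correlation between expression profiles.  *Supervised* mode
restricts the profile to the significant miRNAs; *unsupervised* uses all.
Two clusters are obtained by cutting the final merge, and the
misclassification count is minimized over the two cluster↔label pairings
(hence it is at most ⌊n/2⌋).  A sample with a constant profile has no
defined correlation and is rejected with its name.

## Copy-number calling and penetrance

The caller is deliberately simple: a maximal run of consecutive probes on
one chromosome, every probe strictly beyond the gain (+0.25) or loss
(−0.25) log2-ratio threshold, with more than 3 probes, is one segment.
Proprietary scored-segmentation algorithms (e.g. Agilent's ADM-2) are not
reimplemented — the downstream logic needs only direction and location, and
pre-segmented SEG input lets any external caller be substituted.  The same
±0.25 / >3-probe aberration filter is applied to SEG rows on read.

log2 ratios are interpreted as log2(test/reference), so gains are positive.
Strand is ignored throughout copy-number logic.

Cytoband penetrance is the fraction of cases with at least one overlapping
call of a given direction; a case counts at most once per (band, direction)
regardless of how many of its segments overlap.  Bands with gain or loss
penetrance at or above the recurrence threshold (default 0.33, i.e. a third
of cases; a second tier such as 0.40 or 0.50 can be configured) form the
recurrent-region set.  A band recurrent in both directions is kept with
both, flagged as tied.

All intervals are 0-based half-open internally; BED is read as-is, GFF3 and
1-based inclusive locus tables are converted on read; chromosome names are
normalized by stripping an optional `chr` prefix.  A position on a shared
band boundary belongs to the band on the right.

## Concordance integration

Significant miRNAs are located in the recurrent bands (a multi-miRNA probe
label such as `hsa-miR-520d-5p, 518a-5p, 527` is expanded to all member
miRNAs, and all loci of a multi-locus miRNA are evaluated).  A mapping is
concordant when the band's copy-number direction matches the expression
direction: gain with log2FC > 0 or loss with log2FC < 0.  For a tied band
either direction may match; the record is then flagged ambiguous.  The
concordant subset, deduplicated by miRNA, is the panel.

Target voting retains a predicted target gene when at least
`min_support` = 2 of the prediction databases report it for **any** panel
miRNA (pooled support; a stricter per-miRNA mode is available).  The voted
set is intersected with the genes residing in the recurrent bands, and the
reduction is reported as a percentage of the voted set; running the
intersection once per recurrence tier yields nested Venn counts.

## ROC analysis

AUC is the Mann–Whitney midrank statistic (ties count ½), which equals the
trapezoidal area under the empirical ROC curve exactly.  The 95% CI uses
DeLong's structural-component variance estimator, propagated to
logit(AUC) by the delta method and mapped back.  The logit scale keeps the
interval inside (0, 1) and was adopted after a direct coverage comparison:
for a true AUC of 0.85 at n = 24/28 the plain Wald interval covers ~92.0%
of the time while the logit interval covers ~95.4% (50,000 replicates).
Perfect separation gives zero component variance; the CI then collapses to
the point estimate and is flagged degenerate.

The combined panel score is the mean over panel miRNAs of
sign(log2FC) · z, with z the miRNA's expression z-scored using the pooled
mean/sd across all samples.  This combiner is transparent and weight-free;
an in-sample logistic-regression score is available behind a flag.  The
operating point maximizes the Youden index (sensitivity + specificity − 1)
with ties broken toward the lower threshold, and the reported
sensitivity/specificity pair always lies on the empirical ROC curve.

## Clinical statistics

Continuous variables printed as mean ± SEM with group sizes are compared by
the pooled-variance Student t reconstructed from the summaries
(sd = SEM·√n); the ± values are treated as SEM because only SEM reproduces
the printed p-values of the reference clinical table.  Stage and grade
distributions use the Pearson chi-square without continuity correction;
binary follow-up variables use the two-sided Fisher exact test with the
minimum-likelihood rule.  All tests are two-sided.

Panel regressions fit one OLS per miRNA: normalized log2 expression on
intercept + group + age + tumor size + lymph-node status, with listwise
deletion of samples missing any regressor.  Standard errors are
heteroskedasticity-robust (HC3): log2-transformed count outcomes have
group- and abundance-dependent residual variance, and model-based OLS
standard errors measurably under-cover planted effects in simulation.
BH-FDR is applied per covariate across the panel.  Stage and grade are not
modeled because they are degenerate in the cohorts this reproduces (no
stage-I or grade-1 cases).

## Synthetic-data generator

`generate_bundle` produces a complete, internally consistent input bundle
with planted truth.  Defaults emulate the reference study's magnitudes:
800 miRNA probes, 24 vs 28 samples, 256 differentially expressed miRNAs
with |log2FC| drawn uniformly from [0.7, 3.1], 26 of them concordant, and
3 miRNA–age associations of 0.03 log2 units per year.

* **Counts** are negative-binomial with baseline means log-uniform on
  [20, 2000] and dispersion 0.1 (variance m + 0.1 m²), emulating the
  overdispersion of counting panels; dispersion 0 degrades to Poisson.
  Group means split a planted effect symmetrically
  (mean<sub>A</sub> = base·2^{lfc/2}, mean<sub>B</sub> = base·2^{−lfc/2}).
* **Genome** is synthetic: 23 chromosomes of 12 Mb with 8 equal cytobands
  each.  Copy-number regions are placed on whole cytobands so band-level
  frequency accounting is exact by construction (real aberrations straddle
  bands).  Recurrent regions (default 8, carried by 50% of cases) host the
  concordant miRNAs with matching effect signs; other planted DE miRNAs
  are kept out of recurrent bands so the planted panel is the exact ground
  truth; null miRNAs are placed uniformly.
* **Probe tracks** have 100 kb spacing, planted segment level ±0.3 and
  Gaussian probe noise with sd 0.01.  The noise is deliberately small —
  the strict run-based caller requires every probe beyond threshold, so
  the tracks represent post-smoothing residual noise rather than raw
  array noise (a caller for realistically noisy arrays would need scored
  segmentation, which is out of scope).
* **Target databases** derive from a latent true-target matrix (rate 0.02
  per miRNA–gene pair) observed by 3 databases with 80% sensitivity and a
  0.2% false-report rate, giving controlled inter-database overlap.
* **Clinical covariates** mirror the reference cohorts: group ages
  N(50.7, 8²) and N(53.7, 11.4²) truncated at 25, log-normal tumor sizes,
  stage/grade distributions without stage-I/grade-1 cases, and 7 samples
  with one missing field.  Age effects multiply a miRNA's mean by
  2^{β·(age − mean age)}.
* **Determinism**: each component draws from its own RNG sub-stream
  derived from `(seed, component index)`, so adding a component never
  perturbs earlier draws and a bundle is byte-identical across runs of the
  same configuration.

What passing on synthetic data does **not** show: robustness to probe
sequence bias, batch effects, FFPE degradation, segmentation of noisy
arrays, or aberrations that straddle band boundaries — none of which the
generator emulates.

## Problem sizes used in the test suite

The stochastic acceptance checks run at the study's cohort sizes
(800 × 52): single fixed-seed bundles for DE power, type-I calibration and
exact panel recovery (two seeds), 1,000 replicates for DeLong CI coverage
of a planted AUC of 0.85, and 100 seeded bundles for regression-effect
recovery (300 planted effects, ≥ 95% within 2 robust SEs) and for the
combined-panel-dominance property.  Unit tests use a reduced bundle
(60 miRNAs, 8 + 9 samples, 4-chromosome genome) exercising every feature.

## Known limitations

* The run-based caller has no merge step: a single sub-threshold probe
  splits a segment.  It is adequate for the low-noise synthetic tracks and
  for pre-segmented input, not for raw noisy arrays.
* The concordance rule uses band-level direction only; within-band focal
  events of opposite sign are not resolved.
* The combined panel score is unweighted; no cross-validation is applied,
  so in-sample AUCs of the panel are optimistic by construction.
* Clinical comparisons assume the printed ± values are SEMs; tables using
  SDs would need the conversion removed.
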