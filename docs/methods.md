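# Methods

## Model

`morphoscore` operates on wide tables of bilaterally averaged
Desikan–Killiany ROI measurements — subcortical volumes (mm³), cortical
thicknesses (mm) and surface areas (mm²), 75 ROIs in the default
atlas — with age (years), sex (0/1 indicator), intracranial volume
(ICV, mm³) and a group label per subject.

**Deconfounding.** Each ROI is fit by OLS on the covariates over a
*norm* subset of subjects, and every subject's measurement becomes a
standardized residual z = (value − predicted) / s, where s is the
norm-subset residual SD with denominator n − p − 1 (p covariates).
The norm subset defaults to the **pooled sample** — cases and controls
together — so each subject deviates from the whole-sample norm; a
controls-only mode supports conventional normative modelling, and an
explicit subject list is also accepted.  With an empty covariate list
the procedure reduces exactly to the classical z-score
(x − mean)/SD(ddof=1).  ICV is included for all metric classes,
thickness included, with a configurable covariate list for users who
prefer metric-specific deconfounding.  Internally the design matrix is
standardized before the least-squares solve, which keeps residual–
covariate correlations at ~1e−15 even with ICV's ~10⁶ scale; the
raw-scale coefficients are recovered for reporting and serialized in
the model JSON alongside the standardized form used for prediction.

Because the scale estimate is the unbiased residual SD, the norm-subset
z columns satisfy mean = 0 and Σz²/(n − p − 1) = 1 exactly; the
ddof = 1 sample SD of z equals √((n−p−1)/(n−1)), i.e. 1 up to O(p/n).
Scale checks in the validation suite use the matching denominator.

**The score.** For a weight set {d_r} (signed Cohen's d per ROI from a
meta-analysis) the default `all_rois` rule is the signed-product mean
MRS_i = (1/M) Σ_r d_r z_ir over the M non-missing ROIs of the weight
set.  This reading is linear in z, uses every ROI, and reproduces the
canonical single-ROI narrative (putamen volume, d = +0.37: a subject
one SD larger than expected scores +0.37 on that ROI).  The
`congruent_only` rule instead averages |d_r z_ir| over only the ROIs
where sign(z) = sign(d) (z = 0 or d = 0 count as incongruent); it is
non-linear and drops counter-directional evidence.  Both are first-class
options and every output row is labelled with the rule used, because
the published description ("weighted in the same direction", "the
absolute weighted ROIs were then averaged") admits both readings; the
signed product is the default as the only linear, all-ROI reading.
M is the per-subject non-missing count, not a fixed 75; subjects whose
coverage falls below `min_coverage` (default 0.8 of the weight set)
get a missing score with a stated reason.  Scores are accumulated in
sorted ROI order, so ROI column order can never change a value.

**Unweighted control.** The negative-control mode replaces d_r by
sign(d_r): direction kept, magnitude dropped.  A fully directionless
mean of z would be ≈0 by construction under a pooled norm and would
test nothing; keeping the sign isolates the contribution of the effect
*magnitudes*.  A raw mean-z option is available via a custom weight set
of ones if wanted.

**Group comparison.** The score is z-scored across the compared
subjects, so the group coefficient β is in score-SD units (magnitudes
directly comparable across scores and samples).  β and its p-value come
from the parametric OLS fit of standardized score on the group
indicator (plus optional covariates; default none, since age/sex/ICV
are already removed per ROI).  The 95% CI is a percentile bootstrap
with stratified (within-group) case resampling, default n_boot = 5000,
mandatory seed, re-standardizing within each resample; p and CI are
labelled separately since one is parametric and one resampling-based.
The cross-disorder matrix runs every weight set in every non-reference
group against the reference and Bonferroni-corrects across all cells;
per-cell bootstrap seeds are spawned deterministically from the base
seed.

**Per-ROI effect sizes.** Cohen's d between groups is computed on the
deconfounded z (hence "adjusted" d), with pooled SD and the pooled-
variance t-test, Bonferroni-corrected over the ROIs actually tested.
Spatial correlation against a prior profile is plain Pearson (Spearman
optional) over the ROI-name intersection, p from the t transform; no
spatial-autocorrelation (spin) correction is applied.

**Sign test.** Exact one-sided binomial tail P(X ≥ k | n, ½) toward
the hypothesised direction, zeros dropped with a warning.

**QC.** Tukey fences per ROI at Q1 − k·IQR / Q3 + k·IQR, k = 1.5,
quartiles by linear interpolation between order statistics (the
dominant "type 7" convention).  Flags are a report — the protocol this
mirrors routes flagged segmentations to visual inspection rather than
automatic removal — with an explicit `drop_flagged` helper and a
pipeline `drop_outliers` option for those who want removal.

## Synthetic cohorts

The generator emulates exactly the structure the score assumes: for
subject i in group g, ROI r,

raw_ir = baseline_r + slopes_r·(age_i − μ_age, sex_i − ½, icv_i − μ_icv)
       + m_ir · κ_g · d_r · σ_r + ε_ir,

with ε exchangeably correlated across ROIs within subject
(corr ρ, SD σ_r) and m_ir ~ Bernoulli(π) over the profile ROIs — the
heterogeneity mask encoding that not every patient expresses every
regional alteration (π = 1 → homogeneous shifts).  Ground truth (masks,
shifts) is returned for recovery tests.

Default parameters, chosen as representative of adult single-site
morphometry: age ~ N(35, 10²) years, sex ~ Bernoulli(½),
ICV ~ N(1.45×10⁶, (1.3×10⁵)²) mm³; subcortical baselines at typical
bilateral averages (thalamus 7800, putamen 5100, … accumbens 600 mm³)
with residual SD 8% of baseline; thickness 2.5 ± 0.12 mm; area
2500 ± 250 mm²; age slopes mildly atrophic (−0.004 mm/yr thickness,
−0.2%/yr volume), male sex +3% volume/area, and volume/area loading on
ICV (≈0.4–0.45 of baseline per mean ICV); ρ = 0.2.  The bundled
`scz_like`/`adhd_like` profiles are reproducible synthetic tables on
the realistic |d| ≤ 0.55 scale with a handful of literature-anchored
subcortical values; they are clearly not the published supplementary
weight tables, which users must supply for real analyses.

What the generator does **not** model: anatomically structured
covariance beyond exchangeability, site/scanner effects (the intended
use is site-by-site analysis), non-linear covariate effects,
non-Gaussian tails, and segmentation failure modes.  Passing tests
therefore demonstrate the statistical machinery under the assumed
generative structure, not robustness to real-data artefacts.

## Validation studies and problem sizes

The `experiments` module runs the replicate studies the test suite
asserts on: null calibration of the group comparison (κ = 0, 100/100
per group, 1000 replicates, parametric p, rejection at α = 0.05
expected at 5% ± binomial noise); weighted-vs-unweighted power
(κ = 0.5, π = 0.8, 125 controls / 50 cases, 200 replicates);
three-group cross-disorder specificity and effect-size profile
recovery (κ = 0.5, 100 per group, 100 replicates).  Convergence checks
(law-of-large-numbers shift recovery, empirical d → κ·d_r, the
analytic E[ΔMRS] = κ·mean(d²) under π = 1) run at n = 2000–4000 per
group, where Monte-Carlo noise is comfortably inside the asserted
bands.  Fixed seeds make every study reproducible.

## Numerical and design notes

- OLS is solved once per cohort with a shared design matrix and
  multi-RHS `lstsq`; ROIs with missing cells fall back to per-ROI
  solves on their complete rows.
- Pooled-norm deconfounding makes scores very weakly negatively
  correlated across subjects (Σz = 0 per column), shrinking the null
  β spread by ≈√((N−2)/N); the calibration study shows the rejection
  rate stays within the nominal band at N = 200.
- Rank-deficient designs are rejected naming the collinear covariate
  pair; constant covariates and constant ROIs are hard errors; zero
  pooled SD in an effect-size contrast yields a missing d with a
  warning, not an error.
- CSV I/O is comma-separated UTF-8 with header; floats are written at
  shortest round-tripping precision and read with correctly rounded
  parsing, so write→read is exact.
- Bootstrap CIs are reproducible bit-for-bit from (seed, n_boot);
  with covariates the bootstrap refits per resample, without them it
  uses a closed-form vectorized path.
- The congruent-only score of an all-zero deviation row is undefined
  (no congruent ROIs) and reported missing, with the reason recorded.

## Limitations

The score is norm-relative: values are comparable within the sample
(or fixed norm model) that defined the z-scores, not across studies
without care.  Weight-table quality bounds score quality — profiles
trained on different instruments or populations will transfer
imperfectly.  The implementation scores ROI tables only; voxel- or
vertex-wise scoring and multimodal (e.g. white-matter) weight sets are
out of scope.
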