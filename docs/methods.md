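# Methods

## Model and procedure

Each region is analysed with an ANCOVA whose terms are selected per region
by explicit screening rules (an "adaptive" or ad-hoc GLM).  The candidate
terms are the group factor `Med`, the covariates `Age` and `TIV`, and the
interactions `Med×Age`, `Med×TIV`.  Selection:

1. **Covariate screen.**  Pooled-sample Pearson correlation between the
   covariate and the region's GMV; the covariate enters iff p < 0.05 and
   |r| > 0.4, both strict.  The absolute value matters: age–GMV
   correlations are negative, and a signed rule could never admit Age.  The
   pooled (not within-group) sample is used; under the null of no group
   effect the two coincide in expectation, and pooling is the simpler,
   better-powered choice.
2. **Interaction screen.**  Only for covariates that entered: the model
   `GMV ~ 1 + Med + cov + Med×cov` is fitted by OLS and the interaction
   enters iff its two-sided coefficient p-value is < 0.05.
3. **Zone.**  The four inclusion booleans map to a nine-cell code:
   Zone 1 (nothing), 2A (TIV), 2B (Age), 2C (TIV + Med×TIV),
   2D (Age + Med×Age), 3A (Age + TIV), 3B (+Med×TIV), 3C (+Med×Age),
   3D (everything).  The intermediate labels 2A–2D/3B–3C are this package's
   reconstruction: they enumerate exactly the models the stated rules
   permit between the named endpoints (group-only and full model), and the
   endpoints plus 3A are pinned by published examples.  The taxonomy is a
   design choice, not an external standard.

**Coding and the group test.**  The group factor is sum-to-zero (−½/+½) and
covariates are mean-centered before interaction columns are formed, so the
`Med` coefficient is the group difference at average covariate values even
in interaction zones.  The group test is the partial F (df1 = 1) comparing
the zone model with the same model minus the `Med` column — a
Type-III-style test that coincides with Type II in the zones without
interactions (1, 2A, 2B, 3A), which is where essentially all real regions
land.  `η²p = SS_Med/(SS_Med+SS_err) = F/(F+df_err)` is asserted on every
fit.  Group means/SDs and the relative difference are raw per-group
statistics, not model-adjusted, matching how such tables are reported.

**Sex** is never a model term: TIV is strongly sex-dependent, and a factor
that predicts a covariate violates the ANCOVA assumptions; including TIV
absorbs the sex difference.  The pipeline instead reports a sex→TIV
two-sample t-test as a dataset audit.

**Diagnostics** (Shapiro–Wilk on internally studentized residuals,
median-centered Levene across groups, |standardized residual| > 3 outlier
count, slope-homogeneity p per included covariate) are advisory flags only.
Silent model switching on a post-hoc check would change the inference path;
a user who distrusts a flagged fit can rerun with different thresholds.

## FDR

q-values follow Storey–Tibshirani: π̂₀(λ) = #{p>λ}/(m(1−λ)) on the grid
0, 0.05, …, 0.90, smoothed by a natural cubic smoothing spline whose
roughness penalty is tuned (by bisection on the smoother-matrix trace) to
3 effective degrees of freedom, evaluated at λ = 0.90 and clamped into
(0, 1].  The step-up pass is `q(p(i)) = min(π₀·p(i)/(i/m), q(p(i+1)))`;
dividing by `i/m` rather than multiplying by `m/i` makes the π₀ = 1 case
bit-identical to Benjamini–Hochberg adjusted p-values.  Families with
m < 20 always use π₀ = 1 — the spline is unstable at tiny m, and for the
3-member hemispheres/whole-brain family this exactly reproduces the
published common q.  FDR is applied separately per atlas family (lobar-16,
AAL-116, hemispheres+whole-brain): the published per-family q blocks are
only mutually consistent under separate families.

## ROI volumetrics

A region's volume is `Σ voxel values × voxel volume / 1000` mL, the voxel
volume being |det| of the 3×3 spatial affine (the product of voxel sizes
for axis-aligned grids).  No value thresholding (the modulated-map totals
convention), no implicit resampling — maps and atlas must share grid and
affine, and a mismatch is a hard error because silent interpolation changes
volumes.  TIV = GM + WM + CSF whole-image totals.  mL is the canonical
unit throughout; one published AAL table labels its columns mm³ while the
magnitudes are clearly mL, and this package standardizes on mL.

## Synthetic cohorts

The generator emulates the study cohort: 23 subjects per group, 17 F / 6 M
each, ages uniform on 21–63 y (SD ≈ 12 y, close to the reported ~11 y;
uniform because only mean/SD/range are known and the bounded choice is the
simplest), TIV ~ Normal(1390 F / 1610 M, SD 100) mL.  The sex gap (~15%)
sits at the upper end of the intracranial-volume literature; it is chosen
so that the generator's contract — a sex→TIV t-test at p < 0.0001 on ≥95%
of default cohorts of n = 46 — holds with margin (empirically ~98%).

Regional GMV is the fitted model run generatively:
`baseline·(1 + effect_pct/100·Med) + age_slope·(Age−Āge) +
tiv_slope·(TIV−T̄IV) + Med·interaction terms + N(0, noise_sd)`, with
negative draws clipped to zero under a warning.  The effect is
multiplicative on the baseline because group differences are reported as
percentages.  The whole-brain calibration (baseline 611 mL, effect 6.9 %,
age slope −3.5 mL/y, TIV slope 0.32 mL/mL, noise 42.3 mL) yields a control
SD of ~74.6 mL with pooled r(GMV,TIV) ≈ 0.60 and r(GMV,Age) ≈ −0.57, so
cortical-like regions screen into Zone 3A with high probability; the
brainstem-like regions carry no covariate structure and land in Zone 1.
Cortical region specs scale these slopes by baseline/611 so every region
shares the same correlation structure.  Regions are generated
independently (the true inter-regional covariance is unknown); an analysis
that depends on cross-region correlation is therefore not exercised by
these fixtures.  The generator also omits spatial autocorrelation,
smoothing effects and realistic brain geometry — passing tests demonstrate
the statistical machinery, not robustness to real-image artefacts.

NIfTI fixtures tile a small grid with disjoint cubes, one label per region,
and spread each region's volume uniformly over its cube, so extraction
reproduces the generated table to ≲1e-13 mL.

## Numerical choices and problem sizes

* OLS via `numpy.linalg.lstsq` with a rank check; a rank-deficient design
  is a hard error naming the column count.  Coefficients agree with the
  normal-equations solution to 1e-8 and with statsmodels to machine noise.
* Strict inequalities at every threshold (p < 0.05, |r| > 0.4); a
  zero-variance vector fails screening with a flag rather than erroring.
* Degenerate p-value families: all-identical p → π₀ = 1 with a flag;
  all-tiny p → π₀ clamped strictly above zero.
* Reports round F/mL/percent to 2 decimals and p/q/η² to 4, with a
  full-precision companion file; identical config + seed gives
  byte-identical output.
* Stochastic checks run at 2000 region fits (type-I), 500 replicates
  (effect recovery, sex audit), 60–300 replicates for module-level
  simulation tests — sizes chosen to keep Monte-Carlo error well inside
  the asserted bounds while the whole suite stays fast.

## Known limitations

Voxelwise statistics, random-field/cluster inference, segmentation,
normalization and smoothing are out of scope: the pipeline consumes
finished modulated maps or volume tables.  The zone taxonomy between the
named endpoints is a reconstruction (above).  The screening correlation is
pooled; a within-group variant would differ in small samples.  The partial-F
sums-of-squares convention only matters in interaction zones (3B–3D),
which real regions rarely reach.
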