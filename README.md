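# ahglm — adaptive regional grey-matter-volume ANCOVA

`ahglm` is a pipeline for comparing regional grey-matter volume (GMV)
between two groups of subjects — e.g. long-term meditators vs matched
controls — from voxel-based-morphometry outputs.  It is aimed at
neuroimaging researchers who have modulated tissue-probability maps (SPM /
DARTEL style) or pre-extracted region×subject volume tables and want a
reproducible, testable region-level analysis instead of voxelwise cluster
statistics.

## The method

For each atlas region *r* the full candidate model is the ANCOVA

```
GMV_j = β0 + Med_j + β1·Age_j + β2·TIV_j + β3·(Med×TIV)_j + β4·(Med×Age)_j + ε_j
```

where `Med` is the group factor, `Age` the subject's age and `TIV` the total
intracranial volume (GM+WM+CSF; including TIV intrinsically controls for
sex, which is therefore never a model term).  The model *adapts itself* to
each region:

* a covariate is kept only if its pooled Pearson correlation with the
  region's GMV satisfies **p < 0.05 and |r| > 0.4**;
* a group×covariate interaction is kept only if its covariate was kept and
  the interaction term has **p < 0.05**.

The surviving terms define the region's **zone** — from Zone 1
(`GMV = β0 + Med + ε`, no covariates) through 2A–2D (one covariate, with or
without its interaction) to 3A (both covariates) and 3D (the full model).
The group effect is tested with a 1-df partial F on the zone's OLS fit
(sum-to-zero group coding, mean-centered covariates), and the effect size
is partial eta squared,

```
η²p = SS_Med / (SS_Med + SS_error) = F / (F + df_error)   (1-df effect).
```

Multiplicity over the regions of each atlas family (16 lobar regions, 116
AAL regions, or the 3-member hemispheres/whole-brain family) is handled
with Storey–Tibshirani q-values: π₀ is estimated by a 3-df cubic smoothing
spline over the λ-grid 0, 0.05, …, 0.90 (families with m < 20 use π₀ = 1,
which makes the q-values exactly Benjamini–Hochberg), and significance is
declared at q < 0.05.  Shapiro–Wilk, Levene, outlier and
slope-homogeneity diagnostics are reported as advisory flags and never
change the fitted model.

Region volumes are computed from NIfTI images by summing modulated GM voxel
values over the atlas label and multiplying by the voxel volume (the
`get_totals` convention) — no thresholding, no resampling; a grid mismatch
is an error.

## Worked example

Simulate a study-like cohort (23+23 subjects, 17F/6M per group, ages
21–63 y, sex-dependent TIV, a ~6.9 % whole-brain group effect) and run the
full analysis:

```
$ ahglm simulate --preset study --seed 7 --out-dir sim
$ ahglm run --volumes sim/volumes.tsv --subjects sim/subjects.tsv \
            --family study --out results
study: 10 significant region(s) at q<0.05: temporal_R, hemisphere_R, ...
$ head -3 results/study.tsv
region     zone  F      p_nominal  q       mean_ctrl  sd_ctrl  mean_med  sd_med  relative_diff_pct  eta2_partial  flags
frontal_R  3A    11.92  0.0013     0.0040  77.33      10.52    84.58     9.42    9.37               0.2211
frontal_L  3A    19.16  0.0001     0.0005  77.29      9.58     85.23     7.21    10.27              0.3133
```

Each row is one region: its selected zone (here 3A — both Age and TIV
survived screening, no interactions), the partial F and nominal p for the
group effect, the family-wise q-value, raw per-group means ± SD in mL, the
relative difference `(mean_med − mean_ctrl)·100/mean_ctrl` in %, and η²p.
The demographics audit confirms the built-in sex→TIV structure:

```
$ ahglm audit --subjects sim/subjects.tsv
tiv_by_sex_t    7.48966
tiv_by_sex_p    2.20419e-09
```

and the q-value subcommand reproduces the small-family behaviour — three
p-values of 0.004/0.007/0.005 share the single q-value 0.007:

```
$ printf "0.004\n0.007\n0.005\n" > p.txt && ahglm qvalue --pvals p.txt
p       q
0.004   0.007
0.007   0.007
0.005   0.007
```

The library API mirrors the CLI: `generate_cohort` / `generate_volumes`,
`extract_roi_table`, `fit_region`, `qvalue_family`, `run_family`,
`write_report`.

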