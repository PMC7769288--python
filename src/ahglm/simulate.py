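"""Synthetic cohorts with the statistical structure of a meditation VBM study.

The generator emulates a cross-sectional cohort of 23 long-term meditators
and 23 matched controls (17 F / 6 M per group, ages ~21-63 y) in which

* TIV is strongly sex-dependent (males ~150 mL larger on average), so a
  sex -> TIV two-sample t-test is highly significant on a default cohort;
* regional GMV follows the generative ANCOVA
  GMV = baseline * (1 + effect_pct/100 * Med) + age_slope * (Age - mean Age)
        + tiv_slope * (TIV - mean TIV) + Med * interaction terms + noise,
  with a negative age slope and positive TIV slope for cortical-like
  regions (so they screen into Zone 3A) and no covariate structure for a
  brainstem-like region (Zone 1);
* the whole-brain region has control mean 611 mL, SD ~75 mL and a ~6.9%
  group effect.

NIfTI fixtures place each region in a disjoint axis-aligned block of a
small grid so that ROI extraction recovers the generated table exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .volumetrics import AtlasDefinition, ROIVolumeTable, SubjectRecord, TissueMap

import pandas as pd

__all__ = [
    "CohortSpec",
    "RegionSpec",
    "generate_cohort",
    "generate_volumes",
    "generate_nifti_fixture",
    "whole_brain_spec",
    "lobar16_preset",
    "hemi3_preset",
    "null_preset",
    "recovery_preset",
    "AFFECTED_LOBAR",
]


@dataclass(frozen=True)
class CohortSpec:
    """Cohort layout: two groups with fixed sex counts, uniform ages,
    sex-dependent Gaussian TIV."""

    n_per_group: int = 23
    n_female_per_group: int = 17
    age_range: tuple[float, float] = (21.0, 63.0)
    tiv_mean_f_ml: float = 1390.0
    tiv_mean_m_ml: float = 1610.0
    tiv_sd_ml: float = 100.0

    def __post_init__(self) -> None:
        if self.n_per_group <= 0 or not (0 <= self.n_female_per_group <= self.n_per_group):
            raise ValueError("invalid group/sex counts")
        if not self.age_range[0] < self.age_range[1]:
            raise ValueError("age_range must be increasing")


@dataclass(frozen=True)
class RegionSpec:
    """Generative parameters of one region (the ANCOVA run in reverse)."""

    name: str
    baseline_ml: float  # control mean
    effect_pct: float  # group difference, % of baseline
    age_slope: float = 0.0  # mL / year, typically <= 0
    tiv_slope: float = 0.0  # mL / mL
    interaction_age: float = 0.0  # extra age slope in meditators
    interaction_tiv: float = 0.0  # extra TIV slope in meditators
    noise_sd_ml: float = 1.0

    def __post_init__(self) -> None:
        if self.baseline_ml <= 0:
            raise ValueError("baseline_ml must be positive")
        if self.noise_sd_ml <= 0:
            raise ValueError("noise_sd_ml must be positive")


def generate_cohort(spec: CohortSpec = CohortSpec(), seed: int = 0) -> list[SubjectRecord]:
    """Draw one cohort: ages ~ Uniform(age_range), TIV ~ Normal by sex."""
    rng = np.random.default_rng(seed)
    subjects: list[SubjectRecord] = []
    for med, prefix in ((0, "C"), (1, "M")):
        for i in range(spec.n_per_group):
            sex = "F" if i < spec.n_female_per_group else "M"
            age = rng.uniform(*spec.age_range)
            mu = spec.tiv_mean_f_ml if sex == "F" else spec.tiv_mean_m_ml
            tiv = mu + spec.tiv_sd_ml * rng.standard_normal()
            subjects.append(
                SubjectRecord(id=f"{prefix}{i + 1:02d}", med=med, age=float(age),
                              sex=sex, tiv_ml=float(max(tiv, 1.0)))
            )
    return subjects


def generate_volumes(
    cohort: list[SubjectRecord],
    regions: list[RegionSpec],
    seed: int = 0,
) -> ROIVolumeTable:
    """Generate a subjects x regions volume table from the generative ANCOVA.

    Covariates are centered at the cohort means, so the control group mean of
    each region is ``baseline_ml`` in expectation.  Negative draws are
    clipped to zero with a warning.
    """
    rng = np.random.default_rng(seed)
    med = np.array([s.med for s in cohort], dtype=float)
    age = np.array([s.age for s in cohort])
    tiv = np.array([s.tiv_ml for s in cohort])
    age_c = age - age.mean()
    tiv_c = tiv - tiv.mean()
    vols = np.empty((len(cohort), len(regions)))
    for j, rs in enumerate(regions):
        mu = (
            rs.baseline_ml * (1.0 + rs.effect_pct / 100.0 * med)
            + rs.age_slope * age_c
            + rs.tiv_slope * tiv_c
            + med * (rs.interaction_age * age_c + rs.interaction_tiv * tiv_c)
        )
        vols[:, j] = mu + rs.noise_sd_ml * rng.standard_normal(len(cohort))
    if np.any(vols < 0):
        warnings.warn("negative generated volumes clipped to 0")
        vols = np.clip(vols, 0.0, None)
    return ROIVolumeTable(
        subjects=list(cohort), regions=[rs.name for rs in regions], volumes=vols
    )


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------
# Whole-brain calibration: with uniform ages on (21, 63) (SD ~12.1 y) and the
# sex-mixture TIV (SD ~139 mL), slopes of -3.5 mL/y and 0.32 mL/mL plus
# 42.3 mL noise give a control SD of ~74.6 mL with pooled r(GMV, TIV) ~ 0.60
# and r(GMV, Age) ~ -0.57, so cortical-like regions screen into Zone 3A.

def whole_brain_spec(effect_pct: float = 6.9) -> RegionSpec:
    return RegionSpec("whole_brain", baseline_ml=611.0, effect_pct=effect_pct,
                      age_slope=-3.5, tiv_slope=0.32, noise_sd_ml=42.3)


def _cortical(name: str, baseline: float, effect: float) -> RegionSpec:
    scale = baseline / 611.0
    return RegionSpec(name, baseline_ml=baseline, effect_pct=effect,
                      age_slope=-3.5 * scale, tiv_slope=0.32 * scale,
                      noise_sd_ml=max(42.3 * scale, 1e-3))


_LOBAR_BASE: list[tuple[str, float, float]] = [
    # (name, control mean mL, group effect %): four clearly affected regions
    # (temporal/frontal cortex and brainstem) among 16 lobar areas
    ("frontal_R", 78.35, 9.4),
    ("frontal_L", 76.57, 9.0),
    ("temporal_R", 46.65, 9.0),
    ("temporal_L", 45.90, 5.0),
    ("parietal_R", 36.00, 5.0),
    ("parietal_L", 35.50, 5.0),
    ("occipital_R", 24.00, 5.0),
    ("occipital_L", 23.50, 5.0),
    ("limbic_R", 28.00, 5.0),
    ("limbic_L", 27.50, 5.0),
    ("sublobar_R", 33.00, 5.0),
    ("sublobar_L", 32.50, 5.0),
    ("brainstem_R", 1.67, 19.7),
    ("brainstem_L", 1.67, 5.0),
    ("cerebellum_R", 52.00, 5.0),
    ("cerebellum_L", 51.50, 5.0),
]


def lobar16_preset(null: bool = False) -> list[RegionSpec]:
    """16 lobar regions; brainstem has no covariate structure (Zone 1)."""
    specs = []
    for name, base, eff in _LOBAR_BASE:
        if name.startswith("brainstem"):
            rs = RegionSpec(name, baseline_ml=base, effect_pct=eff,
                            noise_sd_ml=0.28)
        else:
            rs = _cortical(name, base, eff)
        specs.append(replace(rs, effect_pct=0.0) if null else rs)
    return specs


def hemi3_preset(null: bool = False) -> list[RegionSpec]:
    """Right hemisphere, left hemisphere and whole brain (3-member family)."""
    specs = [
        _cortical("hemisphere_R", 284.92, 7.0),
        _cortical("hemisphere_L", 276.62, 6.7),
        whole_brain_spec(6.9),
    ]
    return [replace(rs, effect_pct=0.0) for rs in specs] if null else specs


def null_preset() -> list[RegionSpec]:
    return lobar16_preset(null=True)


AFFECTED_LOBAR = ("frontal_R", "frontal_L", "temporal_R", "brainstem_R")


def recovery_preset() -> list[RegionSpec]:
    """Lobar preset with group effects only in the four affected regions."""
    return [
        rs if rs.name in AFFECTED_LOBAR else replace(rs, effect_pct=0.0)
        for rs in lobar16_preset()
    ]


# ---------------------------------------------------------------------------
# NIfTI fixtures
# ---------------------------------------------------------------------------

def generate_nifti_fixture(
    table: ROIVolumeTable,
    grid_shape: tuple[int, int, int] = (16, 16, 16),
    block: int = 4,
    voxel_mm: float = 1.0,
) -> tuple[dict[str, TissueMap], AtlasDefinition]:
    """Build GM maps + a block atlas whose extraction reproduces ``table``.

    The grid is tiled with disjoint ``block``-sized cubes, one label per
    region; each subject's map spreads the region's volume uniformly over
    its block so that the within-block sum times the voxel volume equals the
    table entry exactly (up to float rounding).
    """
    nb = [g // block for g in grid_shape]
    n_blocks = int(np.prod(nb))
    n_regions = len(table.regions)
    if n_regions > n_blocks:
        raise ValueError(
            f"grid {grid_shape} with block {block} has only {n_blocks} blocks "
            f"for {n_regions} regions"
        )
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    vox_mm3 = voxel_mm**3
    vox_per_block = block**3

    label_img = np.zeros(grid_shape, dtype=np.int32)
    slices = []
    bi = 0
    for r in range(n_regions):
        ix, iy, iz = np.unravel_index(bi, nb)
        sl = (
            slice(ix * block, (ix + 1) * block),
            slice(iy * block, (iy + 1) * block),
            slice(iz * block, (iz + 1) * block),
        )
        label_img[sl] = r + 1
        slices.append(sl)
        bi += 1

    labels = pd.DataFrame(
        {
            "label_id": np.arange(1, n_regions + 1),
            "region_name": table.regions,
            "family": "synthetic",
        }
    )
    atlas = AtlasDefinition(label_image=label_img, affine=affine, labels=labels)

    gm_maps: dict[str, TissueMap] = {}
    for i, subj in enumerate(table.subjects):
        data = np.zeros(grid_shape)
        for r, sl in enumerate(slices):
            # uniform density whose block total reproduces the table cell
            data[sl] = table.volumes[i, r] * 1000.0 / (vox_per_block * vox_mm3)
        gm_maps[subj.id] = TissueMap(data=data, affine=affine)
    return gm_maps, atlas
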