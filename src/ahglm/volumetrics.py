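"""Atlas-based region-of-interest volumetrics for modulated tissue maps.

Regional volumes are obtained by summing modulated tissue-probability values
over the voxels of an atlas label and scaling by the voxel volume (the
``get_totals`` convention widely used with SPM outputs).  No thresholding is
applied to the tissue values, and atlas membership is exact integer-label
equality.  All volumes are reported in mL; multiply by 1000 for mm^3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "TissueMap",
    "AtlasDefinition",
    "SubjectRecord",
    "ROIVolumeTable",
    "total_volume",
    "compute_tiv",
    "extract_roi_table",
    "read_label_table",
    "write_label_table",
    "read_subject_table",
    "read_volume_table",
    "write_volume_table",
]

SUBJECT_COLUMNS = ("id", "group", "age", "sex", "tiv_ml")
_GROUP_CODES = {"control": 0, "meditator": 1, "0": 0, "1": 1}


@dataclass(frozen=True)
class TissueMap:
    """A single modulated tissue-probability volume on a fixed voxel grid.

    Parameters
    ----------
    data : np.ndarray
        3-D array of non-negative modulated tissue densities (dimensionless).
    affine : np.ndarray
        4x4 voxel-to-world affine; the voxel volume is the absolute
        determinant of its 3x3 spatial part.
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        affine = np.asarray(self.affine, dtype=float)
        if data.ndim != 3:
            raise ValueError(f"tissue map must be 3-D, got shape {data.shape}")
        if affine.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {affine.shape}")
        if not np.all(np.isfinite(data)):
            raise ValueError("tissue map contains non-finite voxel values")
        if np.any(data < 0):
            raise ValueError("tissue map contains negative voxel values")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "affine", affine)
        if self.voxel_volume_mm3 <= 0:
            raise ValueError("degenerate affine: voxel volume is not positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "TissueMap":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        if data.ndim == 4 and data.shape[3] == 1:
            data = data[..., 0]
        return cls(data=data, affine=img.affine)

    def to_nifti(self, path: str | Path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.float64), self.affine), str(path))


@dataclass(frozen=True)
class AtlasDefinition:
    """An integer label image plus the table mapping labels to named regions.

    ``labels`` has columns ``label_id``, ``region_name``, ``family``;
    region order within a family follows table order.  Label 0 is background.
    """

    label_image: np.ndarray
    affine: np.ndarray
    labels: pd.DataFrame

    def __post_init__(self) -> None:
        img = np.asarray(self.label_image)
        if not np.issubdtype(img.dtype, np.integer):
            rounded = np.rint(img)
            if not np.allclose(img, rounded):
                raise ValueError("atlas label image must contain integers")
            img = rounded.astype(np.int64)
        labels = self.labels.reset_index(drop=True)
        missing = set(("label_id", "region_name", "family")) - set(labels.columns)
        if missing:
            raise ValueError(f"label table missing columns: {sorted(missing)}")
        if labels["label_id"].duplicated().any():
            raise ValueError("duplicate label_id in label table")
        if (labels["label_id"] <= 0).any():
            raise ValueError("label_id values must be positive integers")
        present = set(np.unique(img)) - {0}
        unknown = present - set(labels["label_id"].tolist())
        if unknown:
            raise ValueError(
                f"label image contains ids absent from the label table: {sorted(unknown)}"
            )
        object.__setattr__(self, "label_image", img)
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=float))
        object.__setattr__(self, "labels", labels)

    @property
    def families(self) -> dict[str, pd.DataFrame]:
        return {name: grp for name, grp in self.labels.groupby("family", sort=False)}

    def family_regions(self, family: str) -> pd.DataFrame:
        fams = self.families
        if family not in fams:
            raise KeyError(f"family {family!r} not in atlas (have {sorted(fams)})")
        return fams[family]


@dataclass(frozen=True)
class SubjectRecord:
    """One participant: group indicator, age, sex and total intracranial volume."""

    id: str
    med: int  # 0 control, 1 meditator
    age: float  # years
    sex: str  # 'F' or 'M'
    tiv_ml: float

    def __post_init__(self) -> None:
        if self.med not in (0, 1):
            raise ValueError(f"med must be 0 or 1, got {self.med}")
        if not self.age > 0:
            raise ValueError(f"age must be positive, got {self.age}")
        if not self.tiv_ml > 0:
            raise ValueError(f"tiv_ml must be positive, got {self.tiv_ml}")
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be 'F' or 'M', got {self.sex!r}")


@dataclass
class ROIVolumeTable:
    """Subjects x regions grey-matter volumes (mL) with subject covariates."""

    subjects: list[SubjectRecord]
    regions: list[str]
    volumes: np.ndarray = field(repr=False)  # (n_subjects, n_regions), mL

    def __post_init__(self) -> None:
        vols = np.asarray(self.volumes, dtype=float)
        if vols.shape != (len(self.subjects), len(self.regions)):
            raise ValueError(
                f"volumes shape {vols.shape} does not match "
                f"{len(self.subjects)} subjects x {len(self.regions)} regions"
            )
        ids = [s.id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate subject ids")
        if np.any(vols < 0):
            raise ValueError("negative volumes")
        self.volumes = vols

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.subjects]

    @property
    def covariates(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "med": [s.med for s in self.subjects],
                "age": [s.age for s in self.subjects],
                "sex": [s.sex for s in self.subjects],
                "tiv_ml": [s.tiv_ml for s in self.subjects],
            },
            index=pd.Index(self.ids, name="id"),
        )

    def region_values(self, region: str) -> np.ndarray:
        try:
            j = self.regions.index(region)
        except ValueError:
            raise KeyError(f"region {region!r} not in table") from None
        return self.volumes[:, j]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.volumes, index=pd.Index(self.ids, name="id"), columns=self.regions
        )


# ---------------------------------------------------------------------------
# Core volume computations (get_totals semantics)
# ---------------------------------------------------------------------------

def _check_same_grid(a_shape, a_affine, b_shape, b_affine, what: str) -> None:
    if tuple(a_shape) != tuple(b_shape):
        raise ValueError(f"{what}: grid shapes differ, {tuple(a_shape)} vs {tuple(b_shape)}")
    if not np.allclose(a_affine, b_affine, atol=1e-6):
        raise ValueError(f"{what}: affines differ; refusing to resample implicitly")


def total_volume(tissue: TissueMap, mask: np.ndarray) -> float:
    """Total tissue volume (mL) inside a boolean mask.

    Sums the modulated voxel values where the mask is true and multiplies by
    the voxel volume.  No thresholding of tissue values is performed.
    """
    mask = np.asarray(mask)
    if mask.shape != tissue.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match map shape {tissue.shape}"
        )
    return float(tissue.data[mask.astype(bool)].sum() * tissue.voxel_volume_mm3 / 1000.0)


def compute_tiv(gm: TissueMap, wm: TissueMap, csf: TissueMap) -> float:
    """Total intracranial volume (mL): GM + WM + CSF whole-image totals."""
    _check_same_grid(gm.shape, gm.affine, wm.shape, wm.affine, "GM vs WM")
    _check_same_grid(gm.shape, gm.affine, csf.shape, csf.affine, "GM vs CSF")
    full = np.ones(gm.shape, dtype=bool)
    return total_volume(gm, full) + total_volume(wm, full) + total_volume(csf, full)


def extract_roi_table(
    gm_maps: Mapping[str, TissueMap],
    atlas: AtlasDefinition,
    family: str,
    subjects: Sequence[SubjectRecord],
) -> ROIVolumeTable:
    """Per-subject, per-region GM volumes for one atlas family.

    Each cell is the ``total_volume`` of the subject's GM map over the voxels
    carrying the region's integer label.  Region order follows the label
    table.  A family label absent from the label image is recorded as zero
    volume with a warning.
    """
    fam = atlas.family_regions(family)
    missing = [s.id for s in subjects if s.id not in gm_maps]
    if missing:
        raise KeyError(f"no GM map provided for subjects: {missing}")

    present = set(np.unique(atlas.label_image)) - {0}
    masks = []
    for lid, rname in zip(fam["label_id"], fam["region_name"]):
        if lid not in present:
            warnings.warn(
                f"label {lid} ({rname}) absent from atlas image; volume recorded as 0",
                stacklevel=2,
            )
        masks.append(atlas.label_image == lid)

    vols = np.zeros((len(subjects), len(fam)), dtype=float)
    for i, subj in enumerate(subjects):
        tm = gm_maps[subj.id]
        _check_same_grid(
            tm.shape, tm.affine, atlas.label_image.shape, atlas.affine,
            f"subject {subj.id} vs atlas",
        )
        for j, mask in enumerate(masks):
            vols[i, j] = total_volume(tm, mask)
    return ROIVolumeTable(
        subjects=list(subjects), regions=list(fam["region_name"]), volumes=vols
    )


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def _read_table(path: str | Path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, dtype=str)


def read_label_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV/CSV label table with columns label_id, region_name, family."""
    df = _read_table(path)
    required = {"label_id", "region_name", "family"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"label table {path}: missing columns {sorted(missing)}")
    extra = set(df.columns) - required
    if extra:
        warnings.warn(f"label table {path}: ignoring unknown columns {sorted(extra)}")
    out = df[["label_id", "region_name", "family"]].copy()
    try:
        out["label_id"] = out["label_id"].astype(int)
    except ValueError as exc:
        raise ValueError(f"label table {path}: non-integer label_id") from exc
    if out["label_id"].duplicated().any():
        raise ValueError(f"label table {path}: duplicate label_id")
    return out


def write_label_table(labels: pd.DataFrame, path: str | Path) -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    labels[["label_id", "region_name", "family"]].to_csv(path, sep=sep, index=False)


def read_subject_table(path: str | Path) -> list[SubjectRecord]:
    """Read subject covariates: columns id, group, age, sex, tiv_ml."""
    df = _read_table(path)
    missing = set(SUBJECT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"subject table {path}: missing columns {sorted(missing)}")
    extra = set(df.columns) - set(SUBJECT_COLUMNS)
    if extra:
        warnings.warn(f"subject table {path}: ignoring unknown columns {sorted(extra)}")
    if df["id"].duplicated().any():
        raise ValueError(f"subject table {path}: duplicate subject ids")
    subjects = []
    for _, row in df.iterrows():
        grp = str(row["group"]).strip().lower()
        if grp not in _GROUP_CODES:
            raise ValueError(
                f"subject table {path}: group must be control/meditator or 0/1, "
                f"got {row['group']!r}"
            )
        subjects.append(
            SubjectRecord(
                id=str(row["id"]),
                med=_GROUP_CODES[grp],
                age=float(row["age"]),
                sex=str(row["sex"]).strip().upper(),
                tiv_ml=float(row["tiv_ml"]),
            )
        )
    return subjects


def read_volume_table(
    volumes_path: str | Path, subjects: Sequence[SubjectRecord] | str | Path
) -> ROIVolumeTable:
    """Read a wide volume table (first column ``id``, one column per region).

    ``subjects`` may be a list of :class:`SubjectRecord` or a path to a
    subject covariate table; every row of the volume table must have a
    matching subject record.
    """
    if isinstance(subjects, (str, Path)):
        subjects = read_subject_table(subjects)
    df = _read_table(volumes_path)
    if df.columns[0] != "id":
        raise ValueError(f"volume table {volumes_path}: first column must be 'id'")
    if df["id"].duplicated().any():
        raise ValueError(f"volume table {volumes_path}: duplicate subject ids")
    by_id = {s.id: s for s in subjects}
    missing = [sid for sid in df["id"] if sid not in by_id]
    if missing:
        raise ValueError(f"volume table {volumes_path}: no covariates for {missing}")
    regions = list(df.columns[1:])
    vols = df[regions].astype(float).to_numpy()
    return ROIVolumeTable(
        subjects=[by_id[sid] for sid in df["id"]], regions=regions, volumes=vols
    )


def write_volume_table(table: ROIVolumeTable, path: str | Path) -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    table.to_frame().to_csv(path, sep=sep)


def write_subject_table(subjects: Sequence[SubjectRecord], path: str | Path) -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    pd.DataFrame(
        {
            "id": [s.id for s in subjects],
            "group": ["meditator" if s.med else "control" for s in subjects],
            "age": [s.age for s in subjects],
            "sex": [s.sex for s in subjects],
            "tiv_ml": [s.tiv_ml for s in subjects],
        }
    ).to_csv(path, sep=sep, index=False)
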