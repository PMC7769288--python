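"""Pipeline: screening -> zoning -> fitting -> FDR -> family reports.

Runs the adaptive ANCOVA over every region of an atlas family, attaches
family-wise q-values, and computes the summary arithmetic reported alongside
such analyses: per-region relative differences, the summed group difference
over significant regions, and that sum's share of the whole-brain group
difference.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .fdr import QValueResult, qvalue_family
from .model import RegionFit, fit_region, run_diagnostics
from .volumetrics import ROIVolumeTable, SubjectRecord

__all__ = [
    "Config",
    "FamilyReport",
    "run_family",
    "relative_difference",
    "share_of_difference",
    "write_report",
    "read_report",
    "demographics_audit",
]

logger = logging.getLogger("ahglm")

REPORT_COLUMNS = [
    "region", "zone", "F", "p_nominal", "q", "mean_ctrl", "sd_ctrl",
    "mean_med", "sd_med", "relative_diff_pct", "eta2_partial", "flags",
]


@dataclass(frozen=True)
class Config:
    """Analysis thresholds and options (YAML-loadable)."""

    screen_p: float = 0.05
    screen_r: float = 0.4
    interaction_p: float = 0.05
    q_threshold: float = 0.05
    pi0: float | None = None  # None = automatic (spline / small-family fallback)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            warnings.warn(f"config {path}: ignoring unknown keys {sorted(unknown)}")
        return cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})


@dataclass
class FamilyReport:
    """Per-family results: fits, q-values and the summary arithmetic."""

    family: str
    fits: list[RegionFit]
    qresult: QValueResult
    qvals: dict[str, float]
    significant: list[str]  # regions with q < threshold, in q order
    failed: dict[str, str] = field(default_factory=dict)
    sum_sig_diff_ml: float = 0.0
    share_of_wholebrain_pct: float | None = None
    mean_relative_diff_pct: float = float("nan")
    sd_relative_diff_pct: float = float("nan")
    flags: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f in self.fits:
            flags = list(f.diagnostics.flags) if f.diagnostics else []
            rows.append(
                {
                    "region": f.region_name,
                    "zone": f.zone.zone_code,
                    "F": f.F_med,
                    "p_nominal": f.p_nominal,
                    "q": self.qvals[f.region_name],
                    "mean_ctrl": f.group_mean_ctrl,
                    "sd_ctrl": f.group_sd_ctrl,
                    "mean_med": f.group_mean_med,
                    "sd_med": f.group_sd_med,
                    "relative_diff_pct": f.relative_diff_pct,
                    "eta2_partial": f.eta2_partial,
                    "flags": ";".join(flags),
                }
            )
        return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def relative_difference(mean_ctrl: float, mean_med: float) -> float:
    """Group difference as a percentage of the control mean."""
    if mean_ctrl <= 0:
        raise ValueError(f"control mean must be positive, got {mean_ctrl}")
    return (mean_med - mean_ctrl) * 100.0 / mean_ctrl


def share_of_difference(part_ml: float, whole_ml: float) -> float:
    """A partial group difference as a percentage of the whole-brain one."""
    if whole_ml == 0:
        raise ValueError("whole-brain difference is zero")
    return part_ml * 100.0 / whole_ml


def run_family(
    table: ROIVolumeTable,
    family: str = "family",
    config: Config = Config(),
    regions: list[str] | None = None,
    wholebrain_diff_ml: float | None = None,
    diagnostics: bool = True,
) -> FamilyReport:
    """Adaptive ANCOVA + family-wise FDR over one set of regions.

    Each region is screened, zoned, fitted and (optionally) checked for
    assumption violations; regions that fail to fit are recorded and the
    rest continue.  ``wholebrain_diff_ml`` supplies the denominator for the
    share-of-whole-brain summary; if None and the family contains a region
    named ``whole_brain``, that region's raw group difference is used.
    """
    regions = list(table.regions) if regions is None else list(regions)
    fits: list[RegionFit] = []
    failed: dict[str, str] = {}
    for region in regions:
        try:
            fit = fit_region(
                table, region,
                screen_p=config.screen_p, screen_r=config.screen_r,
                interaction_p=config.interaction_p,
            )
            if diagnostics:
                fit.diagnostics = run_diagnostics(fit, table)
            fits.append(fit)
        except (ValueError, KeyError, np.linalg.LinAlgError) as exc:
            logger.warning("region %s failed: %s", region, exc)
            failed[region] = str(exc)

    pvals = np.array([f.p_nominal for f in fits])
    qres = qvalue_family(pvals, pi0=config.pi0)
    qvals = {f.region_name: float(q) for f, q in zip(fits, qres.qvals)}
    sig = sorted(
        (f.region_name for f in fits if qvals[f.region_name] < config.q_threshold),
        key=lambda r: qvals[r],
    )

    diffs = {f.region_name: f.group_mean_med - f.group_mean_ctrl for f in fits}
    sum_sig = float(sum(diffs[r] for r in sig))
    flags: list[str] = []
    if sig and not (all(diffs[r] >= 0 for r in sig) or all(diffs[r] <= 0 for r in sig)):
        flags.append("mixed-sign-differences")

    if wholebrain_diff_ml is None and "whole_brain" in diffs:
        wholebrain_diff_ml = diffs["whole_brain"]
    share = (
        share_of_difference(sum_sig, wholebrain_diff_ml)
        if wholebrain_diff_ml not in (None, 0)
        else None
    )

    rels = np.array([f.relative_diff_pct for f in fits])
    return FamilyReport(
        family=family,
        fits=fits,
        qresult=qres,
        qvals=qvals,
        significant=sig,
        failed=failed,
        sum_sig_diff_ml=sum_sig,
        share_of_wholebrain_pct=share,
        mean_relative_diff_pct=float(rels.mean()) if len(rels) else float("nan"),
        sd_relative_diff_pct=float(rels.std(ddof=1)) if len(rels) > 1 else float("nan"),
        flags=flags,
    )


# ---------------------------------------------------------------------------
# Report output
# ---------------------------------------------------------------------------

def _rounded(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in ("F", "mean_ctrl", "sd_ctrl", "mean_med", "sd_med", "relative_diff_pct"):
        out[col] = out[col].map(lambda v: f"{v:.2f}")
    for col in ("p_nominal", "q", "eta2_partial"):
        out[col] = out[col].map(lambda v: f"{v:.4f}")
    return out


def write_report(
    reports: list[FamilyReport] | FamilyReport,
    out_dir: str | Path,
    config: Config = Config(),
) -> list[Path]:
    """Write per-family TSVs (rounded + full precision) and a run log.

    Every emitted row re-verifies the printed-table identities: partial eta
    squared equals F/(F + df_error) and the relative difference equals
    (mean_med - mean_ctrl) * 100 / mean_ctrl.
    """
    if isinstance(reports, FamilyReport):
        reports = [reports]
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for rep in reports:
        for f in rep.fits:  # invariant audit on every emitted row
            assert abs(f.eta2_partial - f.F_med / (f.F_med + f.df_error)) < 1e-9
            assert abs(
                f.relative_diff_pct
                - relative_difference(f.group_mean_ctrl, f.group_mean_med)
            ) < 1e-9
        df = rep.to_frame()
        p1 = out_dir / f"{rep.family}.tsv"
        _rounded(df).to_csv(p1, sep="\t", index=False)
        p2 = out_dir / f"{rep.family}.full.tsv"
        df.to_csv(p2, sep="\t", index=False, float_format="%.12g")
        written.extend([p1, p2])
    log = {
        "config": asdict(config),
        "version": __version__,
        "families": {
            r.family: {
                "pi0": r.qresult.pi0,
                "method": r.qresult.method_note,
                "significant": r.significant,
                "failed": r.failed,
                "sum_sig_diff_ml": r.sum_sig_diff_ml,
                "share_of_wholebrain_pct": r.share_of_wholebrain_pct,
                "mean_relative_diff_pct": r.mean_relative_diff_pct,
                "sd_relative_diff_pct": r.sd_relative_diff_pct,
            }
            for r in reports
        },
    }
    plog = out_dir / "run_log.json"
    plog.write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    written.append(plog)
    return written


def read_report(path: str | Path) -> pd.DataFrame:
    """Read back a full-precision family report TSV."""
    df = pd.read_csv(path, sep="\t")
    missing = set(REPORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"report {path}: missing columns {sorted(missing)}")
    return df


def demographics_audit(subjects: list[SubjectRecord]) -> dict[str, float]:
    """Dataset audit: does TIV differ by sex (justifying TIV-for-sex control)?

    Returns the two-sample t and p for TIV by sex, plus group age balance.
    Not part of the inference path.
    """
    tiv = np.array([s.tiv_ml for s in subjects])
    sex = np.array([s.sex for s in subjects])
    med = np.array([s.med for s in subjects])
    age = np.array([s.age for s in subjects])
    t_sex, p_sex = stats.ttest_ind(tiv[sex == "M"], tiv[sex == "F"])
    t_age, p_age = stats.ttest_ind(age[med == 1], age[med == 0])
    return {
        "tiv_by_sex_t": float(t_sex),
        "tiv_by_sex_p": float(p_sex),
        "age_by_group_t": float(t_age),
        "age_by_group_p": float(p_age),
    }
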