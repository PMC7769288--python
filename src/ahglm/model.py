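"""Adaptive per-region ANCOVA ("AH-GLM") for regional grey-matter volumes.

For every brain region the model terms are chosen by explicit screening
rules rather than fixed in advance:

* a covariate (Age or TIV) enters the model only if its pooled Pearson
  correlation with the region's GMV has p < 0.05 **and** |r| > 0.4;
* a group x covariate interaction enters only if its covariate entered and
  the interaction coefficient has p < 0.05 in the single-covariate model.

The surviving terms define the region's *zone* (1, 2A-2D, 3A-3D), from the
group-only model (Zone 1) to the full two-covariate, two-interaction model
(Zone 3D).  The group effect is then tested with a partial F (1 df) on the
zone's ordinary-least-squares fit; the effect size is partial eta squared,
SS_group / (SS_group + SS_error) = F / (F + df_error) for a 1-df effect.

Coding: the group factor is sum-to-zero (-1/2 control, +1/2 meditator) and
covariates are mean-centered before interaction columns are formed, so the
group main effect stays interpretable at average covariate values in the
interaction zones.  Sex is never a model term: TIV absorbs it (the pipeline
reports the sex->TIV t-test as a dataset audit instead).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .volumetrics import ROIVolumeTable

__all__ = [
    "ScreenResult",
    "ZoneClassification",
    "RegionFit",
    "DiagnosticsReport",
    "screen_covariate",
    "screen_interaction",
    "classify_zone",
    "classify_region",
    "fit_region",
    "run_diagnostics",
    "ZONE_TABLE",
]

SCREEN_P = 0.05
SCREEN_R = 0.4
INTERACTION_P = 0.05

# (include_age, include_tiv, include_med_x_age, include_med_x_tiv) -> zone code
ZONE_TABLE: dict[tuple[bool, bool, bool, bool], str] = {
    (False, False, False, False): "1",
    (False, True, False, False): "2A",
    (True, False, False, False): "2B",
    (False, True, False, True): "2C",
    (True, False, True, False): "2D",
    (True, True, False, False): "3A",
    (True, True, False, True): "3B",
    (True, True, True, False): "3C",
    (True, True, True, True): "3D",
}


@dataclass(frozen=True)
class ScreenResult:
    """Outcome of screening one covariate against a region's GMV."""

    covariate: str  # 'Age' or 'TIV'
    r: float
    p: float
    passes: bool
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class ZoneClassification:
    zone_code: str
    include_age: bool
    include_tiv: bool
    include_med_x_age: bool
    include_med_x_tiv: bool
    screen_age: ScreenResult | None = None
    screen_tiv: ScreenResult | None = None
    interaction_age_p: float | None = None
    interaction_tiv_p: float | None = None


@dataclass(frozen=True)
class DiagnosticsReport:
    shapiro_p: float | None
    levene_p: float | None
    n_outliers: int
    slope_homogeneity_p: dict[str, float]
    flags: tuple[str, ...] = ()


@dataclass
class RegionFit:
    """Fitted region model: group test, effect size and raw group summaries."""

    region_name: str
    zone: ZoneClassification
    terms: list[str]
    beta: np.ndarray = field(repr=False)
    F_med: float
    df1: int
    df_error: int
    p_nominal: float
    eta2_partial: float
    group_mean_ctrl: float
    group_sd_ctrl: float
    group_mean_med: float
    group_sd_med: float
    relative_diff_pct: float
    ss_med: float
    ss_error: float
    residuals: np.ndarray = field(repr=False)
    design: np.ndarray = field(repr=False)
    diagnostics: DiagnosticsReport | None = None


# ---------------------------------------------------------------------------
# Screening
# ---------------------------------------------------------------------------

def _screen_decision(r: float, p: float, screen_p: float = SCREEN_P,
                     screen_r: float = SCREEN_R) -> bool:
    # strict inequalities at both thresholds
    return (p < screen_p) and (abs(r) > screen_r)


def screen_covariate(
    gmv: np.ndarray,
    cov: np.ndarray,
    name: str = "covariate",
    screen_p: float = SCREEN_P,
    screen_r: float = SCREEN_R,
) -> ScreenResult:
    """Pooled-sample Pearson screen of one covariate against regional GMV.

    The covariate passes when the two-sided correlation p-value is below
    ``screen_p`` and |r| exceeds ``screen_r`` (both strict).
    """
    gmv = np.asarray(gmv, dtype=float)
    cov = np.asarray(cov, dtype=float)
    if gmv.shape != cov.shape or gmv.ndim != 1:
        raise ValueError("gmv and covariate must be 1-D vectors of equal length")
    if len(gmv) < 4:
        raise ValueError("need at least 4 observations to screen a covariate")
    if np.ptp(gmv) == 0 or np.ptp(cov) == 0:
        return ScreenResult(name, np.nan, 1.0, False, flags=("zero-variance",))
    r, p = stats.pearsonr(gmv, cov)
    return ScreenResult(name, float(r), float(p),
                        _screen_decision(r, p, screen_p, screen_r))


def screen_interaction(
    gmv: np.ndarray,
    cov: np.ndarray,
    med: np.ndarray,
    interaction_p: float = INTERACTION_P,
) -> tuple[float, bool]:
    """Test the group x covariate interaction in the single-covariate model.

    Fits ``GMV ~ 1 + Med + cov + Med x cov`` by least squares (sum-to-zero
    group coding, centered covariate) and returns the two-sided p-value of
    the interaction coefficient together with the inclusion decision
    (p < ``interaction_p``).  Only called for covariates that passed
    screening.
    """
    gmv = np.asarray(gmv, dtype=float)
    cov_c = np.asarray(cov, dtype=float) - np.mean(cov)
    med_c = np.asarray(med, dtype=float) - 0.5
    X = np.column_stack([np.ones_like(gmv), med_c, cov_c, med_c * cov_c])
    n, k = X.shape
    xtx = X.T @ X
    if np.linalg.matrix_rank(xtx) < k:
        warnings.warn("singular design in interaction screen; interaction excluded")
        return 1.0, False
    beta = np.linalg.solve(xtx, X.T @ gmv)
    resid = gmv - X @ beta
    sigma2 = resid @ resid / (n - k)
    se = np.sqrt(sigma2 * np.linalg.inv(xtx)[3, 3])
    t = beta[3] / se
    p = 2.0 * stats.t.sf(abs(t), df=n - k)
    return float(p), bool(p < interaction_p)


def classify_zone(
    screen_age: ScreenResult,
    screen_tiv: ScreenResult,
    interaction_age: tuple[float, bool] | None = None,
    interaction_tiv: tuple[float, bool] | None = None,
) -> ZoneClassification:
    """Map screening outcomes to the model zone (1 ... 3D).

    An interaction decision may only be supplied for a covariate that passed
    screening; supplying one for a failed covariate is a hard error.
    """
    inc_age = screen_age.passes
    inc_tiv = screen_tiv.passes
    if interaction_age is not None and not inc_age:
        raise ValueError("Age interaction decision supplied but Age failed screening")
    if interaction_tiv is not None and not inc_tiv:
        raise ValueError("TIV interaction decision supplied but TIV failed screening")
    inc_ixa = bool(interaction_age[1]) if (inc_age and interaction_age) else False
    inc_ixt = bool(interaction_tiv[1]) if (inc_tiv and interaction_tiv) else False
    code = ZONE_TABLE[(inc_age, inc_tiv, inc_ixa, inc_ixt)]
    return ZoneClassification(
        zone_code=code,
        include_age=inc_age,
        include_tiv=inc_tiv,
        include_med_x_age=inc_ixa,
        include_med_x_tiv=inc_ixt,
        screen_age=screen_age,
        screen_tiv=screen_tiv,
        interaction_age_p=interaction_age[0] if interaction_age else None,
        interaction_tiv_p=interaction_tiv[0] if interaction_tiv else None,
    )


def classify_region(
    gmv: np.ndarray,
    age: np.ndarray,
    tiv: np.ndarray,
    med: np.ndarray,
    screen_p: float = SCREEN_P,
    screen_r: float = SCREEN_R,
    interaction_p: float = INTERACTION_P,
) -> ZoneClassification:
    """Full screening cascade for one region: covariates, then interactions."""
    s_age = screen_covariate(gmv, age, "Age", screen_p, screen_r)
    s_tiv = screen_covariate(gmv, tiv, "TIV", screen_p, screen_r)
    i_age = screen_interaction(gmv, age, med, interaction_p) if s_age.passes else None
    i_tiv = screen_interaction(gmv, tiv, med, interaction_p) if s_tiv.passes else None
    return classify_zone(s_age, s_tiv, i_age, i_tiv)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _design(zone: ZoneClassification, med, age, tiv) -> tuple[np.ndarray, list[str]]:
    med_c = np.asarray(med, dtype=float) - 0.5
    age_c = np.asarray(age, dtype=float) - np.mean(age)
    tiv_c = np.asarray(tiv, dtype=float) - np.mean(tiv)
    cols = [np.ones_like(med_c), med_c]
    names = ["const", "med"]
    if zone.include_age:
        cols.append(age_c)
        names.append("age")
    if zone.include_tiv:
        cols.append(tiv_c)
        names.append("tiv")
    if zone.include_med_x_age:
        cols.append(med_c * age_c)
        names.append("med:age")
    if zone.include_med_x_tiv:
        cols.append(med_c * tiv_c)
        names.append("med:tiv")
    return np.column_stack(cols), names


def _ols_rss(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError(
            f"singular design matrix (rank {rank} < {X.shape[1]} columns)"
        )
    resid = y - X @ beta
    return beta, float(resid @ resid)


def fit_region(
    table: ROIVolumeTable,
    region: str,
    zone: ZoneClassification | None = None,
    screen_p: float = SCREEN_P,
    screen_r: float = SCREEN_R,
    interaction_p: float = INTERACTION_P,
) -> RegionFit:
    """Fit the zone's ANCOVA for one region and test the group effect.

    If ``zone`` is None the full screening cascade is run first.  The group
    test is the partial F comparing the zone model against the same model
    with the group column removed (df1 = 1); group means/SDs and the
    relative difference are raw per-group statistics, not model-adjusted.
    """
    gmv = table.region_values(region)
    cov = table.covariates
    med = cov["med"].to_numpy(dtype=float)
    age = cov["age"].to_numpy(dtype=float)
    tiv = cov["tiv_ml"].to_numpy(dtype=float)
    n = len(gmv)
    if int((med == 0).sum()) < 3 or int((med == 1).sum()) < 3:
        raise ValueError("need at least 3 subjects per group")

    if zone is None:
        zone = classify_region(gmv, age, tiv, med, screen_p, screen_r, interaction_p)

    X, names = _design(zone, med, age, tiv)
    k = X.shape[1]
    df_error = n - k
    if df_error <= 0:
        raise ValueError(f"no error degrees of freedom (n={n}, k={k})")
    beta, rss_full = _ols_rss(X, gmv)
    X_red = np.delete(X, names.index("med"), axis=1)
    _, rss_red = _ols_rss(X_red, gmv)

    ss_med = max(rss_red - rss_full, 0.0)
    F = ss_med / (rss_full / df_error) if rss_full > 0 else np.inf
    p = float(stats.f.sf(F, 1, df_error))
    eta2 = ss_med / (ss_med + rss_full) if (ss_med + rss_full) > 0 else 0.0

    g_ctrl = gmv[med == 0]
    g_med = gmv[med == 1]
    mean_ctrl = float(np.mean(g_ctrl))
    mean_med = float(np.mean(g_med))
    if mean_ctrl <= 0:
        raise ValueError("control group mean must be positive for a relative difference")

    return RegionFit(
        region_name=region,
        zone=zone,
        terms=names,
        beta=beta,
        F_med=float(F),
        df1=1,
        df_error=df_error,
        p_nominal=p,
        eta2_partial=float(eta2),
        group_mean_ctrl=mean_ctrl,
        group_sd_ctrl=float(np.std(g_ctrl, ddof=1)),
        group_mean_med=mean_med,
        group_sd_med=float(np.std(g_med, ddof=1)),
        relative_diff_pct=float((mean_med - mean_ctrl) * 100.0 / mean_ctrl),
        ss_med=ss_med,
        ss_error=rss_full,
        residuals=gmv - X @ beta,
        design=X,
    )


# ---------------------------------------------------------------------------
# Diagnostics (advisory only; never alters the fitted model)
# ---------------------------------------------------------------------------

def run_diagnostics(fit: RegionFit, table: ROIVolumeTable) -> DiagnosticsReport:
    """Assumption checks on a fitted region model.

    Shapiro-Wilk on internally studentized residuals, median-centered Levene
    across the two groups, a |standardized residual| > 3 outlier count, and a
    slope-homogeneity p-value per included covariate (from the
    interaction-augmented model).  Failures raise flags only.
    """
    flags: list[str] = []
    X, e = fit.design, fit.residuals
    n, k = X.shape
    H = X @ np.linalg.solve(X.T @ X, X.T)
    h = np.clip(np.diag(H), 0.0, 1.0 - 1e-12)
    s = np.sqrt(fit.ss_error / fit.df_error) if fit.df_error > 0 else np.nan
    std_resid = e / (s * np.sqrt(1.0 - h)) if s > 0 else np.zeros_like(e)

    shapiro_p: float | None = None
    if n >= 3 and s > 0:
        shapiro_p = float(stats.shapiro(std_resid).pvalue)
        if shapiro_p < 0.05:
            flags.append("non-normal-residuals")
    else:
        flags.append("shapiro-not-computable")

    med = table.covariates["med"].to_numpy(dtype=float)
    levene_p: float | None = None
    if min((med == 0).sum(), (med == 1).sum()) >= 2 and s > 0:
        levene_p = float(
            stats.levene(e[med == 0], e[med == 1], center="median").pvalue
        )
        if levene_p < 0.05:
            flags.append("heteroscedastic")
    else:
        flags.append("levene-not-computable")

    n_outliers = int(np.sum(np.abs(std_resid) > 3))
    if n_outliers:
        flags.append("outliers")

    gmv = table.region_values(fit.region_name)
    age = table.covariates["age"].to_numpy(dtype=float)
    tiv = table.covariates["tiv_ml"].to_numpy(dtype=float)
    slope_p: dict[str, float] = {}
    for name, cov in (("Age", age), ("TIV", tiv)):
        included = fit.zone.include_age if name == "Age" else fit.zone.include_tiv
        if not included:
            continue
        p_int, _ = screen_interaction(gmv, cov, med)
        slope_p[name] = p_int
        if p_int < 0.05:
            flags.append(f"nonhomogeneous-slope-{name.lower()}")

    return DiagnosticsReport(
        shapiro_p=shapiro_p,
        levene_p=levene_p,
        n_outliers=n_outliers,
        slope_homogeneity_p=slope_p,
        flags=tuple(flags),
    )
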