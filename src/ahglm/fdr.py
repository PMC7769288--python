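"""Storey-Tibshirani q-values for families of per-region p-values.

The q-value of a test is the minimum false discovery rate at which it would
be called significant.  The estimator has two ingredients:

* ``pi0``, the estimated proportion of true null hypotheses, obtained by
  evaluating pi0_hat(lambda) = #{p_i > lambda} / (m (1 - lambda)) on a
  lambda grid and smoothing with a natural cubic smoothing spline tuned to
  3 effective degrees of freedom, read off at the largest lambda;
* a step-up pass over the ordered p-values,
  q(p_(i)) = min(pi0 * m * p_(i) / i, q(p_(i+1))).

With pi0 = 1 the q-values coincide exactly with Benjamini-Hochberg adjusted
p-values.  Small families (m < 20) fall back to pi0 = 1, where the spline
estimator is unstable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import make_smoothing_spline

__all__ = ["QValueResult", "estimate_pi0", "qvalues", "qvalue_family"]

DEFAULT_LAMBDA_GRID = np.round(np.arange(0.0, 0.901, 0.05), 10)
SMALL_FAMILY_M = 20
SPLINE_DF = 3.0


@dataclass(frozen=True)
class QValueResult:
    pvals: np.ndarray
    pi0: float
    qvals: np.ndarray
    lambda_grid: np.ndarray
    method_note: str  # 'spline' or 'fixed-pi0-1'
    flags: tuple[str, ...] = ()


def _check_pvals(pvals) -> np.ndarray:
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("p-values must be a 1-D vector")
    if p.size and (np.any(~np.isfinite(p)) or p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return p


def _spline_edf(x: np.ndarray, lam: float) -> float:
    """Effective df (smoother-matrix trace) of the smoothing spline at lam."""
    n = len(x)
    tr = 0.0
    eye = np.eye(n)
    for j in range(n):
        spl = make_smoothing_spline(x, eye[j], lam=lam)
        tr += float(spl(x[j]))
    return tr


_LAM_CACHE: dict[tuple, float] = {}


def _lam_for_df(x: np.ndarray, df: float) -> float:
    """Bisect the roughness penalty so the spline has the requested edf.

    edf decreases monotonically in lam, from n (interpolation) to 2 (line);
    the result depends only on the abscissae, so it is cached per grid.
    """
    key = (tuple(np.round(x, 12)), round(df, 6))
    if key in _LAM_CACHE:
        return _LAM_CACHE[key]
    lo, hi = 1e-9, 1e9
    for _ in range(80):
        mid = np.sqrt(lo * hi)
        if _spline_edf(x, mid) > df:
            lo = mid
        else:
            hi = mid
        if hi / lo < 1 + 1e-10:
            break
    _LAM_CACHE[key] = float(np.sqrt(lo * hi))
    return _LAM_CACHE[key]


def estimate_pi0(pvals, lambda_grid=None, spline_df: float = SPLINE_DF
                 ) -> tuple[float, tuple[str, ...]]:
    """Spline estimate of the proportion of true nulls.

    Returns ``(pi0, flags)`` with pi0 clamped into (0, 1].  Degenerate input
    (all p-values identical) yields pi0 = 1 with a flag.
    """
    p = _check_pvals(pvals)
    grid = DEFAULT_LAMBDA_GRID if lambda_grid is None else np.asarray(lambda_grid, float)
    m = p.size
    if m == 0:
        raise ValueError("cannot estimate pi0 from an empty p-value vector")
    if np.ptp(p) == 0:
        return 1.0, ("degenerate-pvals",)
    pi0_hat = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in grid])
    lam = _lam_for_df(grid, spline_df)
    spl = make_smoothing_spline(grid, pi0_hat, lam=lam)
    pi0 = float(spl(grid[-1]))
    flags: tuple[str, ...] = ()
    if pi0 > 1.0:
        pi0, flags = 1.0, ("pi0-clamped-high",)
    elif pi0 <= 0.0:
        # clamp strictly above zero at the smallest observed estimate
        pi0, flags = max(float(pi0_hat.min()), 1.0 / m), ("pi0-clamped-low",)
    return pi0, flags


def qvalues(pvals, pi0: float = 1.0) -> np.ndarray:
    """Step-up q-values for a given pi0, returned in input order.

    Ties share the q-value of their rank block; every q is capped at 1 and
    at the q of the next-larger p (monotonicity).
    """
    p = _check_pvals(pvals)
    if not (0.0 < pi0 <= 1.0):
        raise ValueError(f"pi0 must lie in (0, 1], got {pi0}")
    m = p.size
    if m == 0:
        return np.empty(0)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    # divide by i/m (not multiply by m/i) so that pi0 = 1 reproduces
    # Benjamini-Hochberg adjusted p-values bit-for-bit
    q = pi0 * ranked / (np.arange(1, m + 1) / m)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def qvalue_family(pvals, pi0: float | None = None, lambda_grid=None) -> QValueResult:
    """q-values for one family of tests, with the small-family pi0 fallback.

    If ``pi0`` is given it is used as-is.  Otherwise families with fewer
    than 20 members use pi0 = 1 (exactly Benjamini-Hochberg); larger
    families use the smoothing-spline estimate.
    """
    p = _check_pvals(pvals)
    grid = DEFAULT_LAMBDA_GRID if lambda_grid is None else np.asarray(lambda_grid, float)
    flags: tuple[str, ...] = ()
    if p.size == 0:
        return QValueResult(p, 1.0, np.empty(0), grid, "fixed-pi0-1")
    if pi0 is not None:
        note = f"fixed-pi0-{pi0:g}"
    elif p.size < SMALL_FAMILY_M:
        pi0, note = 1.0, "fixed-pi0-1"
    else:
        pi0, flags = estimate_pi0(p, grid)
        note = "spline"
    return QValueResult(p, pi0, qvalues(p, pi0), grid, note, flags)
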