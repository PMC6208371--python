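"""Chou-Talalay median-effect model and combination-index synergy scoring.

The median-effect equation relates fraction affected fa to dose,

    fa/(1 - fa) = (D/Dm)^m,

linear in log-odds of fa versus log D; Dm is the median-effect dose
(fa = 0.5) and m the sigmoidicity.  For viability data, fa = 1 -
normalized viability (the anchor — typically vehicle NC — must be
declared upstream).

The combination index at a measured combination (d1, d2, fa) is

    CI = d1/Dx1(fa) + d2/Dx2(fa),

where Dx_i(fa) is the dose of agent i alone producing fa, computed
from that agent's median-effect fit.  CI < 1 indicates synergy, = 1
Loewe additivity, > 1 antagonism; verdicts use a configurable
additivity band (default +/- 0.1) purely for reporting.  This is the
classic two-term (mutually exclusive) CI; points are evaluated at
their own dose pair (non-constant-ratio design).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FitError
from .screen_model import CombinationTable

DEFAULT_ADDITIVITY_BAND = 0.1


@dataclass(frozen=True)
class MedianEffectFit:
    """Median-effect line fit: slope m, median-effect dose Dm, fit R^2."""

    agent: str
    m: float
    dm: float
    r2: float
    n_points: int
    fa_min: float = 0.0
    fa_max: float = 1.0

    def fa(self, dose: np.ndarray) -> np.ndarray:
        """Fraction affected at dose (inverse of :func:`dx`)."""
        dose = np.asarray(dose, dtype=float)
        return 1.0 / (1.0 + (self.dm / dose) ** self.m)


@dataclass(frozen=True)
class CombinationPoint:
    """One combination measurement scored against the single-agent fits."""

    dose_1: float
    dose_2: float
    fa: float
    dx_1: float
    dx_2: float
    ci: float
    verdict: str
    extrapolated: bool = False


def fit_median_effect(
    doses: np.ndarray, fa: np.ndarray, agent: str = "agent"
) -> MedianEffectFit:
    """OLS of log(fa/(1-fa)) on log D; points with fa at 0 or 1 are dropped."""
    doses = np.asarray(doses, dtype=float)
    fa = np.asarray(fa, dtype=float)
    usable = (doses > 0) & (fa > 0) & (fa < 1)
    n_dropped = int((~usable).sum())
    if n_dropped:
        warnings.warn(
            f"{agent}: {n_dropped} point(s) with fa at 0/1 or dose 0 excluded "
            "from the median-effect fit"
        )
    d, f = doses[usable], fa[usable]
    if d.size < 2:
        raise FitError(f"{agent}: <2 usable points for the median-effect fit")
    x = np.log(d)
    y = np.log(f / (1.0 - f))
    if np.allclose(x, x[0]):
        raise FitError(f"{agent}: all usable doses identical; slope undefined")
    res = stats.linregress(x, y)
    m = float(res.slope)
    if m <= 0:
        warnings.warn(f"{agent}: nonstandard median-effect slope m = {m:.4g} <= 0")
    dm = float(math.exp(-res.intercept / m))
    r2 = float(res.rvalue**2) if not math.isnan(res.rvalue) else 1.0
    return MedianEffectFit(agent, m, dm, r2, int(d.size),
                           fa_min=float(f.min()), fa_max=float(f.max()))


def dx(fit: MedianEffectFit, fa: float) -> float:
    """Single-agent dose producing fraction affected ``fa``."""
    if not (0.0 < fa < 1.0):
        raise ValueError(f"fa must be in (0,1), got {fa}")
    return float(fit.dm * (fa / (1.0 - fa)) ** (1.0 / fit.m))


def _verdict(ci: float, band: float) -> str:
    if ci < 1.0 - band:
        return "synergy"
    if ci > 1.0 + band:
        return "antagonism"
    return "additive"


def combination_index(
    fit_1: MedianEffectFit,
    fit_2: MedianEffectFit,
    dose_1: float,
    dose_2: float,
    fa: float,
    band: float = DEFAULT_ADDITIVITY_BAND,
) -> CombinationPoint:
    """CI of one combination point against the two single-agent fits.

    Points whose fa lies outside both agents' observed fa ranges are
    still scored but flagged ``extrapolated``.
    """
    if not (0.0 < fa < 1.0):
        raise ValueError(f"fa must be in (0,1), got {fa}")
    dx1 = dx(fit_1, fa)
    dx2 = dx(fit_2, fa)
    ci = dose_1 / dx1 + dose_2 / dx2
    outside = not (
        (fit_1.fa_min <= fa <= fit_1.fa_max) or (fit_2.fa_min <= fa <= fit_2.fa_max)
    )
    if outside:
        warnings.warn(
            f"fa = {fa:.3g} outside both agents' observed ranges; CI extrapolated"
        )
    return CombinationPoint(
        float(dose_1), float(dose_2), float(fa), dx1, dx2, float(ci),
        _verdict(ci, band), extrapolated=outside,
    )


def ci_matrix(
    fit_1: MedianEffectFit,
    fit_2: MedianEffectFit,
    table: CombinationTable,
    band: float = DEFAULT_ADDITIVITY_BAND,
) -> pd.DataFrame:
    """Score every row of a combination table; per-point failures never abort.

    Returns a DataFrame with dx_1, dx_2, ci, verdict, extrapolated and
    an ``error`` column (empty on success).
    """
    rows = []
    for rec in table.data.itertuples(index=False):
        base = {"dose_1": rec.dose_1, "dose_2": rec.dose_2, "fa": rec.fa}
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pt = combination_index(fit_1, fit_2, rec.dose_1, rec.dose_2, rec.fa, band)
            rows.append({**base, "dx_1": pt.dx_1, "dx_2": pt.dx_2, "ci": pt.ci,
                         "verdict": pt.verdict, "extrapolated": pt.extrapolated,
                         "error": ""})
        except (ValueError, FitError) as exc:
            rows.append({**base, "dx_1": math.nan, "dx_2": math.nan, "ci": math.nan,
                         "verdict": "", "extrapolated": False, "error": str(exc)})
    return pd.DataFrame(
        rows,
        columns=["dose_1", "dose_2", "fa", "dx_1", "dx_2", "ci",
                 "verdict", "extrapolated", "error"],
    )


def ci_summary(matrix: pd.DataFrame) -> dict[str, float]:
    """Fraction of scored points per verdict."""
    ok = matrix[matrix["error"] == ""]
    n = len(ok)
    if n == 0:
        return {"synergy": 0.0, "additive": 0.0, "antagonism": 0.0, "n_scored": 0}
    out = {v: float((ok["verdict"] == v).mean()) for v in ("synergy", "additive", "antagonism")}
    out["n_scored"] = n
    return out
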