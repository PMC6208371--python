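"""Four-parameter logistic dose-response fitting and curve comparison.

The curve family is the standard 4PL for inhibition data,

    V(D) = bottom + (top - bottom) / (1 + (D/IC50)^h),

decreasing in dose for h > 0, with ``top`` the zero-dose viability and
``bottom`` the high-dose plateau.  Fitting is nonlinear least squares
(trust-region reflective) with a multi-start over a log-spaced IC50
grid; the hill slope starts at 1.  Zero doses contribute to asymptote
estimation but are excluded from the IC50 initialization grid.

Nested-model comparison uses the extra-sum-of-squares F test: the null
model fits one shared curve to the pooled data (all four parameters
shared by default; ``share='ic50'`` shares the potency only), the
alternative fits each table separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import DegenerateFitError, FitError
from .screen_model import DoseResponseTable


def four_pl(dose: np.ndarray, bottom: float, top: float, ic50: float, hill: float) -> np.ndarray:
    """4PL viability at dose (vectorized; exact at dose 0)."""
    dose = np.asarray(dose, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(dose > 0, dose / ic50, 0.0)
    return bottom + (top - bottom) / (1.0 + ratio**hill)


@dataclass(frozen=True)
class DoseResponseFit:
    """Fitted 4PL parameters and least-squares diagnostics."""

    agent: str
    bottom: float
    top: float
    ic50: float
    hill: float
    ssr: float
    n_points: int
    converged: bool

    def predict(self, dose: np.ndarray) -> np.ndarray:
        return four_pl(dose, self.bottom, self.top, self.ic50, self.hill)


@dataclass(frozen=True)
class CurveComparison:
    """Extra-sum-of-squares F comparison of two dose-response tables."""

    f_stat: float
    df_num: int
    df_den: int
    p_value: float
    shared_ssr: float
    separate_ssr: float


def _start_grid(doses: np.ndarray, n: int = 7) -> np.ndarray:
    pos = doses[doses > 0]
    return np.geomspace(pos.min(), pos.max(), n)


def _fit_arrays(
    dose: np.ndarray,
    viab: np.ndarray,
    agent: str,
    max_top_factor: float = 1.2,
    bottom_floor: float = 0.0,
) -> DoseResponseFit:
    if np.unique(dose[dose > 0]).size < 4:
        raise FitError(f"{agent}: need >=4 distinct nonzero doses for a 4PL fit")
    if np.ptp(viab) < 1e-12:
        raise DegenerateFitError(f"{agent}: response is flat; no dose dependence to fit")
    top_cap = max_top_factor * float(viab.max())
    lo = [bottom_floor, bottom_floor, 1e-12, 1e-3]
    hi = [top_cap, top_cap, np.inf, 50.0]
    p0_top = float(viab[dose == dose.min()].mean()) if (dose == 0).any() else float(viab.max())
    p0_bottom = max(bottom_floor, float(viab.min()))

    best = None
    for ic0 in _start_grid(dose):
        p0 = [p0_bottom, min(p0_top, top_cap), ic0, 1.0]
        try:
            popt, _ = optimize.curve_fit(
                four_pl, dose, viab, p0=p0, bounds=(lo, hi),
                maxfev=20000, xtol=1e-15, ftol=1e-15, gtol=1e-15,
            )
        except (RuntimeError, optimize.OptimizeWarning):
            continue
        ssr = float(np.sum((viab - four_pl(dose, *popt)) ** 2))
        if best is None or ssr < best[1]:
            best = (popt, ssr)
    if best is None:
        return DoseResponseFit(agent, math.nan, math.nan, math.nan, math.nan,
                               math.inf, int(dose.size), False)
    popt, ssr = best
    bottom, top, ic50, hill = (float(x) for x in popt)
    if bottom > top:  # reparameterize to the bottom < top convention
        bottom, top, hill = top, bottom, -hill
    return DoseResponseFit(agent, bottom, top, ic50, hill, ssr, int(dose.size), True)


def fit_4pl(table: DoseResponseTable, **kwargs) -> DoseResponseFit:
    """Fit a 4PL to a dose-response table (viability on the fraction scale)."""
    return _fit_arrays(table.doses, table.viability_fraction, table.agent, **kwargs)


def ic_fraction(fit: DoseResponseFit, f: float) -> float:
    """Dose producing relative inhibition ``f`` between top and bottom.

    f = 0.5 returns the IC50 exactly; f = 0.2 is the IC20 used to pick
    the screen's sub-lethal drug dose.
    """
    if not (0.0 < f < 1.0):
        raise ValueError(f"inhibition fraction must be in (0,1), got {f}")
    if not fit.converged:
        raise FitError(f"{fit.agent}: cannot invert a non-converged fit")
    return float(fit.ic50 * (f / (1.0 - f)) ** (1.0 / fit.hill))


def fold_shift(fit_ref: DoseResponseFit, fit_combo: DoseResponseFit) -> float:
    """IC50 ratio reference/combination; >1 means the combination sensitizes."""
    for f in (fit_ref, fit_combo):
        if not f.converged:
            raise FitError(f"{f.agent}: non-converged fit in fold-shift")
    return fit_ref.ic50 / fit_combo.ic50


def _joint_ssr_shared_ic50(
    d1: np.ndarray, v1: np.ndarray, d2: np.ndarray, v2: np.ndarray,
    f1: DoseResponseFit, f2: DoseResponseFit,
) -> float:
    """SSR of the 7-parameter null model sharing only the IC50."""

    def resid(theta):
        b1, t1, b2, t2, log_ic50, h1, h2 = theta
        ic = math.exp(log_ic50)
        r1 = v1 - four_pl(d1, b1, t1, ic, h1)
        r2 = v2 - four_pl(d2, b2, t2, ic, h2)
        return np.concatenate([r1, r2])

    x0 = [f1.bottom, f1.top, f2.bottom, f2.top,
          math.log(math.sqrt(f1.ic50 * f2.ic50)), f1.hill, f2.hill]
    sol = optimize.least_squares(resid, x0, method="lm", max_nfev=20000)
    return float(np.sum(sol.fun**2))


def compare_curves(
    a: DoseResponseTable, b: DoseResponseTable, share: str = "all"
) -> CurveComparison:
    """Extra-sum-of-squares F test: one shared curve vs separate curves.

    ``share='all'`` (default) shares all four 4PL parameters in the
    null model (df_num = 4); ``share='ic50'`` shares the potency only
    (df_num = 1).
    """
    if share not in ("all", "ic50"):
        raise ValueError("share must be 'all' or 'ic50'")
    fa = fit_4pl(a)
    fb = fit_4pl(b)
    if not (fa.converged and fb.converged):
        raise FitError("cannot compare: a separate fit did not converge")
    separate_ssr = fa.ssr + fb.ssr
    n = fa.n_points + fb.n_points

    if share == "all":
        pooled_dose = np.concatenate([a.doses, b.doses])
        pooled_viab = np.concatenate([a.viability_fraction, b.viability_fraction])
        shared_ssr = _fit_arrays(pooled_dose, pooled_viab, "pooled").ssr
        df_num = 4
        n_sep_params = 8
    else:
        shared_ssr = _joint_ssr_shared_ic50(
            a.doses, a.viability_fraction, b.doses, b.viability_fraction, fa, fb
        )
        df_num = 1
        n_sep_params = 8
    shared_ssr = max(shared_ssr, separate_ssr)  # nested models: never better
    df_den = n - n_sep_params
    if df_den <= 0:
        raise FitError("not enough points for the F comparison")
    if separate_ssr == 0.0:
        f_stat = math.inf if shared_ssr > 0 else 0.0
        p = 0.0 if shared_ssr > 0 else 1.0
    else:
        f_stat = ((shared_ssr - separate_ssr) / df_num) / (separate_ssr / df_den)
        p = float(stats.f.sf(f_stat, df_num, df_den))
    return CurveComparison(float(f_stat), df_num, df_den, p, shared_ssr, separate_ssr)
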