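"""Per-mimic two-arm statistics and sensitizer/desensitizer/drug-neutral calls.

Each library entry occupies one well, measured in replicate under a
vehicle arm and a drug arm.  Statistics run on the NC-relative
viability scale (fraction of the plate's negative-control mean), not on
z-scores: the screen's selection quantity is the ratio
mu_drug/mu_vehicle of per-arm mean viabilities.

Hit classes, in precedence order:

1. ``drug_neutral`` — the mimic itself shifts vehicle viability by more
   than 25% (and significantly vs the plate NC wells); such entries are
   excluded from drug-interaction calls regardless of their ratio.
2. ``sensitizer`` — BH q <= Q (default 0.5%) AND ratio in the lowest
   2.5 percentile of the screen's ratio distribution AND at least a 10%
   viability reduction.
3. ``desensitizer`` — BH q <= Q AND ratio at or above the mirrored
   97.5 percentile.
4. ``no_effect`` otherwise.

The FDR gate and the magnitude (percentile) gate are combined with AND:
a hit must be both statistically significant and large.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .qc_normalize import (
    ControlSummary,
    control_summary,
    screen_control_summary,
)
from .screen_model import ScreenDataset, WellRole

HIT_CLASSES = ("sensitizer", "desensitizer", "drug_neutral", "no_effect")


@dataclass(frozen=True)
class HitCallConfig:
    """Gates of the three-way classification.

    fdr_q            BH false-discovery-rate cut (fraction).
    ratio_percentile magnitude gate: lowest percentile of the
                     mu_drug/mu_vehicle ratio distribution (sensitizers);
                     mirrored at 100 - p for desensitizers.
    neutral_threshold vehicle-arm viability change that disqualifies an
                     entry as drug-neutral (fraction).
    neutral_alpha    significance level of the vehicle-vs-NC test.
    min_reduction    extra floor on 1 - ratio for sensitizer calls.
    """

    fdr_q: float = 0.005
    ratio_percentile: float = 2.5
    neutral_threshold: float = 0.25
    neutral_alpha: float = 0.05
    min_reduction: float = 0.10
    mirror_desensitizer: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.fdr_q < 1):
            raise ValueError("fdr_q must be in (0,1)")
        if not (0 < self.ratio_percentile < 100):
            raise ValueError("ratio_percentile must be in (0,100)")
        for name in ("neutral_threshold", "neutral_alpha", "min_reduction"):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise ValueError(f"{name} must be in [0,1)")


@dataclass(frozen=True)
class MimicResult:
    """Per-entity screen statistics and (once classified) the hit class."""

    entity: str
    mu_vehicle: float
    mu_drug: float
    ratio: float
    vehicle_change: float
    t_stat: float
    df: int
    p_value: float
    q_value: float = math.nan
    vehicle_p: float = math.nan
    percentile_rank: float = math.nan
    hit_class: str = "no_effect"


def pooled_t_test(a: np.ndarray, b: np.ndarray) -> tuple[float, int, float]:
    """Classical equal-variance two-sample t-test of a vs b (two-sided).

    Returns (t, df, p) with df = len(a)+len(b)-2.  Degenerate inputs
    (pooled variance 0) yield t = 0, p = 1 for equal means and a signed
    infinite-t sentinel with p = 0 for unequal means.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("need >=2 replicates per group")
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if sp2 == 0.0:
        if diff == 0.0:
            return 0.0, df, 1.0
        return math.copysign(math.inf, diff), df, 0.0
    t = diff / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), df, float(p)


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    """Welch two-sided p with the same degenerate-variance conventions."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def benjamini_hochberg(
    p_values: np.ndarray, q: float = 0.005
) -> tuple[np.ndarray, np.ndarray]:
    """BH step-up q-values and rejection flags at FDR level ``q``.

    q(i) = min_{j>=i} m*p(j)/j (sorted order), capped at 1; rejects the
    largest prefix with p(k) <= k*q/m.  NaN p-values are excluded from
    the procedure (their q is NaN, never rejected) with a warning.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values outside [0,1]")
    mask = np.isnan(p)
    qvals = np.full(p.shape, np.nan)
    reject = np.zeros(p.shape, dtype=bool)
    if mask.any():
        warnings.warn(f"{int(mask.sum())} NaN p-value(s) excluded from BH")
    ok = ~mask
    if ok.any():
        rej, qv, _, _ = multipletests(p[ok], alpha=q, method="fdr_bh")
        qvals[ok] = qv
        reject[ok] = rej
    return qvals, reject


def score_screen(
    dataset: ScreenDataset, normalization: str = "plate", contrast: str = "arm"
) -> list[MimicResult]:
    """Compute per-entity arm means, ratio and tests (no classes yet).

    ``normalization`` is 'plate' (each plate's own NC wells anchor its
    viabilities; default) or 'screen' (one NC anchor per arm for the
    whole screen).  ``contrast`` picks the per-mimic test: 'arm'
    (default; drug vs vehicle replicate viabilities, pooled variance)
    or 'nc' (drug-arm mimic viabilities vs the drug-arm NC wells).
    """
    if normalization not in ("plate", "screen"):
        raise ValueError("normalization must be 'plate' or 'screen'")
    if contrast not in ("arm", "nc"):
        raise ValueError("contrast must be 'arm' or 'nc'")
    screen_cs: dict[str, ControlSummary] = {}
    if normalization == "screen":
        screen_cs = {arm: screen_control_summary(dataset, arm) for arm in dataset.arms_present}

    results: list[MimicResult] = []
    for pid, pm in dataset.plate_maps.items():
        cs = {
            arm: (screen_cs[arm] if normalization == "screen" else control_summary(dataset, pid, arm))
            for arm in ("vehicle", "drug")
        }
        nc_wells = pm.wells_with_role(WellRole.NEGATIVE_CONTROL)
        nc_viab_vehicle = dataset.signals(pid, "vehicle", nc_wells) / cs["vehicle"].mu_nc
        nc_viab_drug = dataset.signals(pid, "drug", nc_wells) / cs["drug"].mu_nc
        for well in pm.wells_with_role(WellRole.TEST):
            viab = {
                arm: dataset.signals(pid, arm, [well]) / cs[arm].mu_nc
                for arm in ("vehicle", "drug")
            }
            mu_v = float(viab["vehicle"].mean())
            mu_d = float(viab["drug"].mean())
            if contrast == "arm":
                t, df, p = pooled_t_test(viab["drug"], viab["vehicle"])
            else:
                t, df, p = pooled_t_test(viab["drug"], nc_viab_drug)
            results.append(
                MimicResult(
                    entity=pm.entities[well],
                    mu_vehicle=mu_v,
                    mu_drug=mu_d,
                    ratio=mu_d / mu_v,
                    vehicle_change=mu_v - 1.0,
                    t_stat=t,
                    df=df,
                    p_value=p,
                    vehicle_p=_welch_p(viab["vehicle"], nc_viab_vehicle),
                )
            )
    return results


def classify(
    results: list[MimicResult], cfg: HitCallConfig = HitCallConfig()
) -> list[MimicResult]:
    """Assign hit classes screen-wide (BH q-values, percentile gates)."""
    if len(results) < 40:
        warnings.warn(
            f"only {len(results)} entities: the {cfg.ratio_percentile} percentile "
            "gate is unreliable at this size"
        )
    p = np.array([r.p_value for r in results])
    qvals, _ = benjamini_hochberg(p, cfg.fdr_q)
    ratios = np.array([r.ratio for r in results])
    if not np.all(np.isfinite(ratios)):
        raise ValueError("non-finite ratios present; cannot classify")
    lo = float(np.percentile(ratios, cfg.ratio_percentile))  # linear interpolation
    hi = float(np.percentile(ratios, 100.0 - cfg.ratio_percentile))
    pct_rank = 100.0 * (stats.rankdata(ratios, method="average") - 0.5) / ratios.size

    out: list[MimicResult] = []
    for r, qv, pr in zip(results, qvals, pct_rank):
        if abs(r.vehicle_change) > cfg.neutral_threshold and r.vehicle_p < cfg.neutral_alpha:
            cls = "drug_neutral"
        elif (
            qv <= cfg.fdr_q
            and r.ratio <= lo
            and (1.0 - r.ratio) >= cfg.min_reduction
        ):
            cls = "sensitizer"
        elif cfg.mirror_desensitizer and qv <= cfg.fdr_q and r.ratio >= hi:
            cls = "desensitizer"
        else:
            cls = "no_effect"
        out.append(replace(r, q_value=float(qv), percentile_rank=float(pr), hit_class=cls))
    return out


def rank_sensitizers(results: list[MimicResult]) -> list[MimicResult]:
    """Sensitizers ordered by ascending ratio, ties broken by ascending q."""
    hits = [r for r in results if r.hit_class == "sensitizer"]
    return sorted(hits, key=lambda r: (r.ratio, r.q_value))


def class_counts(results: list[MimicResult]) -> dict[str, int]:
    counts = {c: 0 for c in HIT_CLASSES}
    for r in results:
        counts[r.hit_class] += 1
    return counts


def results_frame(results: list[MimicResult]) -> pd.DataFrame:
    """Results as a tidy DataFrame (one row per entity)."""
    from .screen_model import MIMIC_RESULT_COLUMNS

    return pd.DataFrame([{c: getattr(r, c) for c in MIMIC_RESULT_COLUMNS} for r in results])
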