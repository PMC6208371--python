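"""Per-plate normalization, SSMD quality control and control-drift reporting.

Normalization is anchored to each plate's negative-control (NC) wells,
separately per arm: z(w) = (x(w) - mu_NC)/sd_NC and viability(w) =
x(w)/mu_NC.  Anchoring per plate (rather than screen-wide) guards
against plate-to-plate baseline differences and makes "NC wells sit at
z = 0, viability = 1" exactly true on every plate.  A screen-wide mode
is available for comparison.

SSMD (strictly standardized mean difference) grades the separation of
positive from negative controls: (mu_NC - mu_PC)/sqrt(sd_NC^2 +
sd_PC^2), positive when NC (viable) exceeds PC (killed); a plate passes
at SSMD >= 3 by default, the conventional "very strong effect" cut.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    DegenerateNormalizationError,
    InsufficientControlsError,
    MissingArmError,
    UndefinedSSMDError,
)
from .screen_model import ScreenDataset, WellRole

DEFAULT_SSMD_THRESHOLD = 3.0


@dataclass(frozen=True)
class ControlSummary:
    """Pooled control statistics of one plate in one arm (n-1 denominators)."""

    plate_id: str
    arm: str
    mu_nc: float
    sd_nc: float
    mu_pc: float
    sd_pc: float
    n_nc: int
    n_pc: int


def control_summary(dataset: ScreenDataset, plate_id: str, arm: str) -> ControlSummary:
    """Mean and sample SD of NC and PC signals, pooled across replicates."""
    pm = dataset.plate_maps[plate_id]
    nc_wells = pm.wells_with_role(WellRole.NEGATIVE_CONTROL)
    pc_wells = pm.wells_with_role(WellRole.POSITIVE_CONTROL)
    if len(nc_wells) < 2 or len(pc_wells) < 2:
        raise InsufficientControlsError(
            f"plate {plate_id}: need >=2 NC and >=2 PC wells "
            f"(found {len(nc_wells)} NC, {len(pc_wells)} PC)"
        )
    nc = dataset.signals(plate_id, arm, nc_wells)
    pc = dataset.signals(plate_id, arm, pc_wells)
    if nc.size < 2 or pc.size < 2:
        raise InsufficientControlsError(
            f"plate {plate_id}, arm {arm}: <2 control measurements"
        )
    return ControlSummary(
        plate_id=plate_id,
        arm=arm,
        mu_nc=float(nc.mean()),
        sd_nc=float(nc.std(ddof=1)),
        mu_pc=float(pc.mean()),
        sd_pc=float(pc.std(ddof=1)),
        n_nc=int(nc.size),
        n_pc=int(pc.size),
    )


def ssmd(cs: ControlSummary) -> float:
    """SSMD of a plate's controls; +/-inf sentinel when both SDs are zero."""
    var = cs.sd_nc**2 + cs.sd_pc**2
    diff = cs.mu_nc - cs.mu_pc
    if var == 0.0:
        if diff == 0.0:
            raise UndefinedSSMDError(
                f"plate {cs.plate_id}, arm {cs.arm}: identical degenerate controls"
            )
        return math.copysign(math.inf, diff)
    return diff / math.sqrt(var)


@dataclass
class NormalizedPlate:
    """Z-scores and NC-relative viability of one plate in one arm."""

    plate_id: str
    arm: str
    data: pd.DataFrame  # columns: well, replicate, z, viability

    @property
    def z(self) -> dict[str, float]:
        """Per-well z-score (replicates averaged)."""
        return self.data.groupby("well")["z"].mean().to_dict()

    @property
    def viability(self) -> dict[str, float]:
        """Per-well fraction-of-NC viability (replicates averaged)."""
        return self.data.groupby("well")["viability"].mean().to_dict()


def normalize_plate(
    dataset: ScreenDataset,
    plate_id: str,
    arm: str,
    summary: ControlSummary | None = None,
) -> NormalizedPlate:
    """Normalize one plate/arm against its NC wells.

    An explicit ``summary`` (e.g. a screen-wide one) overrides the
    plate's own control statistics.  Raises
    :class:`DegenerateNormalizationError` when sd_NC = 0, since z is
    then undefined (viability would still be well-defined).
    """
    cs = summary if summary is not None else control_summary(dataset, plate_id, arm)
    if cs.sd_nc == 0.0:
        raise DegenerateNormalizationError(
            f"plate {plate_id}, arm {arm}: NC spread is zero, z undefined "
            f"(viability = signal/{cs.mu_nc} remains computable)"
        )
    df = dataset.measurements
    sel = (df["plate"] == plate_id) & (df["arm"] == arm)
    sub = df.loc[sel, ["well", "replicate", "signal"]].copy()
    sub["z"] = (sub["signal"] - cs.mu_nc) / cs.sd_nc
    sub["viability"] = sub["signal"] / cs.mu_nc
    return NormalizedPlate(plate_id, arm, sub[["well", "replicate", "z", "viability"]])


def screen_control_summary(dataset: ScreenDataset, arm: str) -> ControlSummary:
    """Control statistics pooled over every plate of the screen (one arm)."""
    nc_all, pc_all = [], []
    for pid, pm in dataset.plate_maps.items():
        nc_all.append(dataset.signals(pid, arm, pm.wells_with_role(WellRole.NEGATIVE_CONTROL)))
        pc_all.append(dataset.signals(pid, arm, pm.wells_with_role(WellRole.POSITIVE_CONTROL)))
    nc = np.concatenate(nc_all)
    pc = np.concatenate(pc_all)
    if nc.size < 2 or pc.size < 2:
        raise InsufficientControlsError(f"arm {arm}: <2 control measurements screen-wide")
    return ControlSummary(
        "__screen__", arm,
        float(nc.mean()), float(nc.std(ddof=1)),
        float(pc.mean()), float(pc.std(ddof=1)),
        int(nc.size), int(pc.size),
    )


def plate_qc(
    dataset: ScreenDataset, threshold: float = DEFAULT_SSMD_THRESHOLD
) -> pd.DataFrame:
    """Per-plate, per-arm SSMD table with pass flags.

    Columns: plate, arm, ssmd, n_nc, n_pc, pass.
    """
    rows = []
    for pid in dataset.plate_maps:
        for arm in sorted(dataset.arms_present):
            cs = control_summary(dataset, pid, arm)
            value = ssmd(cs)
            rows.append((pid, arm, value, cs.n_nc, cs.n_pc, value >= threshold))
    return pd.DataFrame(rows, columns=["plate", "arm", "ssmd", "n_nc", "n_pc", "pass"])


def screen_passes_qc(qc_table: pd.DataFrame, policy: str = "all") -> bool:
    """Screen-level QC verdict: 'all' plates must pass (default) or 'any'."""
    passes = qc_table["pass"]
    return bool(passes.all()) if policy == "all" else bool(passes.any())


@dataclass
class DriftReport:
    """NC viability loss in the drug arm, per plate and screen-level."""

    per_plate: pd.DataFrame  # columns: plate, nc_vehicle, nc_drug, drift
    mean_drift: float
    sd_drift: float


def control_drift(dataset: ScreenDataset) -> DriftReport:
    """Fractional NC-signal reduction in the drug arm vs the vehicle arm.

    drift(plate) = 1 - mean_NC(drug)/mean_NC(vehicle); a drug dosed at
    its IC20 is expected to sit near 0.20 screen-wide.
    """
    missing = {"vehicle", "drug"} - dataset.arms_present
    if missing:
        raise MissingArmError(f"arm(s) {sorted(missing)} absent from dataset")
    rows = []
    for pid, pm in dataset.plate_maps.items():
        nc_wells = pm.wells_with_role(WellRole.NEGATIVE_CONTROL)
        veh = dataset.signals(pid, "vehicle", nc_wells)
        drg = dataset.signals(pid, "drug", nc_wells)
        mv, md = float(veh.mean()), float(drg.mean())
        rows.append((pid, mv, md, 1.0 - md / mv))
    per_plate = pd.DataFrame(rows, columns=["plate", "nc_vehicle", "nc_drug", "drift"])
    drift = per_plate["drift"].to_numpy()
    sd = float(drift.std(ddof=1)) if drift.size > 1 else 0.0
    return DriftReport(per_plate, float(drift.mean()), sd)
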