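"""Data model and CSV I/O for arrayed-screen plates and follow-up assays.

The canonical interchange format is long (tidy) CSV: one row per
measurement for raw signals, one row per well for plate maps.  Well
coordinates follow the microtiter convention (row letter A-H, 1-based
column 1-12, e.g. ``"B7"``); nothing user-facing is 0-based.  Files
ending in ``.gz`` are transparently decompressed by pandas.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    CoordinateError,
    EmptyResultsError,
    LinkageError,
    SchemaError,
)

ROWS = "ABCDEFGH"
N_COLS = 12

_WELL_RE = re.compile(r"^([A-Ha-h])0?([1-9]|1[0-2])$")


class WellRole(str, Enum):
    """Role of a well on a screening plate."""

    TEST = "test"
    NEGATIVE_CONTROL = "negative_control"
    POSITIVE_CONTROL = "positive_control"
    EMPTY = "empty"


def normalize_well(well: str) -> str:
    """Normalize a well coordinate to uppercase letter + integer ("a07" -> "A7").

    Raises :class:`CoordinateError` for anything outside A1..H12.
    """
    m = _WELL_RE.match(str(well).strip())
    if m is None:
        raise CoordinateError(
            f"well {well!r} is outside the 96-well grid A1..H12"
        )
    return f"{m.group(1).upper()}{int(m.group(2))}"


def all_wells() -> list[str]:
    """The 96 well coordinates in row-major order (A1..A12, B1, ...)."""
    return [f"{r}{c}" for r in ROWS for c in range(1, N_COLS + 1)]


@dataclass
class PlateMap:
    """Layout of one 96-well plate: role per well and entity ID per test well."""

    plate_id: str
    roles: dict[str, WellRole]
    entities: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.roles = {normalize_well(w): WellRole(r) for w, r in self.roles.items()}
        self.entities = {normalize_well(w): e for w, e in self.entities.items()}
        for well, role in self.roles.items():
            if role is WellRole.TEST and well not in self.entities:
                raise SchemaError(
                    f"plate {self.plate_id}: test well {well} has no entity ID"
                )
        stray = set(self.entities) - {
            w for w, r in self.roles.items() if r is WellRole.TEST
        }
        if stray:
            raise SchemaError(
                f"plate {self.plate_id}: entity IDs on non-test wells {sorted(stray)}"
            )

    def wells_with_role(self, role: WellRole) -> list[str]:
        return [w for w, r in self.roles.items() if r is role]

    @property
    def n_negative_controls(self) -> int:
        return len(self.wells_with_role(WellRole.NEGATIVE_CONTROL))

    @property
    def n_positive_controls(self) -> int:
        return len(self.wells_with_role(WellRole.POSITIVE_CONTROL))


MEASUREMENT_COLUMNS = ["plate", "well", "arm", "replicate", "signal"]
PLATEMAP_COLUMNS = ["plate", "well", "role", "entity"]

ARMS = ("vehicle", "drug")


@dataclass
class ScreenDataset:
    """A full screen: plate maps plus a long table of raw well signals.

    ``measurements`` columns: plate, well, arm ('vehicle'|'drug'),
    replicate (1-based int), signal (non-negative float).
    """

    plate_maps: dict[str, PlateMap]
    measurements: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        missing = [c for c in MEASUREMENT_COLUMNS if c not in self.measurements.columns]
        if missing:
            raise SchemaError(f"measurement table missing column(s) {missing}")
        df = self.measurements
        bad_arm = set(df["arm"].unique()) - set(ARMS)
        if bad_arm:
            raise SchemaError(f"unknown arm value(s) {sorted(bad_arm)}")
        if (df["signal"] < 0).any():
            raise SchemaError("negative signals present")
        dup = df.duplicated(subset=["plate", "well", "arm", "replicate"])
        if dup.any():
            raise SchemaError(
                f"{int(dup.sum())} duplicate (plate, well, arm, replicate) rows"
            )
        offenders = []
        for plate, well in df[["plate", "well"]].drop_duplicates().itertuples(index=False):
            pm = self.plate_maps.get(plate)
            if pm is None or well not in pm.roles:
                offenders.append((plate, well))
        if offenders:
            raise LinkageError(
                f"measurements reference unmapped wells: {offenders[:10]}"
                + ("..." if len(offenders) > 10 else "")
            )

    @property
    def arms_present(self) -> set[str]:
        return set(self.measurements["arm"].unique())

    @property
    def n_replicates(self) -> int:
        return int(self.measurements["replicate"].nunique())

    def entity_wells(self) -> pd.DataFrame:
        """Long table (plate, well, entity) over all test wells."""
        rows = [
            (pid, w, pm.entities[w])
            for pid, pm in self.plate_maps.items()
            for w in pm.wells_with_role(WellRole.TEST)
        ]
        return pd.DataFrame(rows, columns=["plate", "well", "entity"])

    def signals(self, plate_id: str, arm: str, wells: Iterable[str]) -> np.ndarray:
        df = self.measurements
        sel = (
            (df["plate"] == plate_id)
            & (df["arm"] == arm)
            & (df["well"].isin(list(wells)))
        )
        return df.loc[sel, "signal"].to_numpy(dtype=float)


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required column(s) {missing}")


def read_plate_maps(path: str | Path) -> dict[str, PlateMap]:
    """Read long-format plate maps (plate, well, role, entity) into PlateMap objects."""
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, PLATEMAP_COLUMNS, f"plate map file {path}")
    maps: dict[str, PlateMap] = {}
    for plate_id, grp in df.groupby("plate", sort=False):
        roles = {}
        entities = {}
        for row in grp.itertuples(index=False):
            well = normalize_well(row.well)
            if well in roles:
                raise SchemaError(f"plate {plate_id}: duplicate well {well}")
            roles[well] = WellRole(row.role)
            if roles[well] is WellRole.TEST:
                if pd.isna(row.entity) or str(row.entity) == "":
                    raise SchemaError(
                        f"plate {plate_id}: test well {well} lacks an entity ID"
                    )
                entities[well] = str(row.entity)
        maps[str(plate_id)] = PlateMap(str(plate_id), roles, entities)
    return maps


def read_screen(signals_path: str | Path, platemaps_path: str | Path) -> ScreenDataset:
    """Read raw signals and plate maps into a validated :class:`ScreenDataset`."""
    df = pd.read_csv(signals_path)
    _require_columns(df, MEASUREMENT_COLUMNS, f"signal file {signals_path}")
    df = df.copy()
    df["plate"] = df["plate"].astype(str)
    df["well"] = df["well"].map(normalize_well)
    df["replicate"] = df["replicate"].astype(int)
    df["signal"] = df["signal"].astype(float)
    maps = read_plate_maps(platemaps_path)
    return ScreenDataset(maps, df[MEASUREMENT_COLUMNS])


def write_screen(
    dataset: ScreenDataset, signals_path: str | Path, platemaps_path: str | Path
) -> None:
    """Write a ScreenDataset back to the long CSV pair read by :func:`read_screen`."""
    dataset.measurements.to_csv(signals_path, index=False, float_format="%.12g")
    rows = []
    for pid, pm in dataset.plate_maps.items():
        for well, role in pm.roles.items():
            rows.append((pid, well, role.value, pm.entities.get(well, "")))
    pd.DataFrame(rows, columns=PLATEMAP_COLUMNS).to_csv(platemaps_path, index=False)


def read_plate_grid(path: str | Path, plate_id: str, arm: str, replicate: int) -> pd.DataFrame:
    """Convenience importer: an 8x12 wide grid CSV (rows A-H) to long form.

    The wide file has a header row of column numbers 1..12 and a leading
    row-letter column.  Returns a long measurement DataFrame.
    """
    wide = pd.read_csv(path, index_col=0)
    rows = []
    for r, series in wide.iterrows():
        for c, value in series.items():
            if pd.isna(value):
                continue
            rows.append((plate_id, normalize_well(f"{r}{int(c)}"), arm, replicate, float(value)))
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


# ---------------------------------------------------------------------------
# dose-response and combination tables
# ---------------------------------------------------------------------------

VIABILITY_SCALES = ("fraction", "percent")


@dataclass
class DoseResponseTable:
    """Single-agent viability vs dose, with an explicitly declared scale.

    Auto-detecting percent-vs-fraction is deliberately unsupported: the
    scale must be declared (silent 100x errors are worse than one extra
    argument).
    """

    agent: str
    data: pd.DataFrame  # columns: dose, replicate, viability
    scale: str = "fraction"
    dose_unit: str = "nM"

    def __post_init__(self) -> None:
        _require_columns(self.data, ["dose", "replicate", "viability"], "dose-response table")
        if self.scale not in VIABILITY_SCALES:
            raise SchemaError(
                f"viability scale must be one of {VIABILITY_SCALES}, got {self.scale!r}"
            )
        if (self.data["dose"] < 0).any():
            raise SchemaError("negative doses present")

    @property
    def doses(self) -> np.ndarray:
        return self.data["dose"].to_numpy(dtype=float)

    @property
    def viability_fraction(self) -> np.ndarray:
        v = self.data["viability"].to_numpy(dtype=float)
        return v / 100.0 if self.scale == "percent" else v

    @property
    def n_distinct_nonzero_doses(self) -> int:
        d = self.doses
        return int(np.unique(d[d > 0]).size)


def read_dose_response(path: str | Path, agent: str | None = None, scale: str | None = None) -> DoseResponseTable:
    """Read a dose-response CSV (dose, replicate, viability[, agent, scale])."""
    df = pd.read_csv(path)
    _require_columns(df, ["dose", "replicate", "viability"], f"dose-response file {path}")
    if agent is None:
        agent = str(df["agent"].iloc[0]) if "agent" in df.columns else Path(path).stem
    if scale is None:
        if "scale" in df.columns:
            scale = str(df["scale"].iloc[0])
        else:
            raise SchemaError(
                "viability scale not declared: pass scale= or add a 'scale' column"
            )
    return DoseResponseTable(agent, df[["dose", "replicate", "viability"]].copy(), scale)


@dataclass
class CombinationTable:
    """Two-agent combination responses: (dose_1, dose_2, fa) records."""

    data: pd.DataFrame  # columns: dose_1, dose_2, fa

    def __post_init__(self) -> None:
        _require_columns(self.data, ["dose_1", "dose_2", "fa"], "combination table")
        d = self.data
        if ((d["dose_1"] < 0) | (d["dose_2"] < 0)).any():
            raise SchemaError("negative doses present")
        if ((d["dose_1"] == 0) & (d["dose_2"] == 0)).any():
            raise SchemaError("combination rows with both doses zero")


def read_combination(path: str | Path) -> CombinationTable:
    df = pd.read_csv(path)
    _require_columns(df, ["dose_1", "dose_2", "fa"], f"combination file {path}")
    return CombinationTable(df[["dose_1", "dose_2", "fa"]].copy())


# ---------------------------------------------------------------------------
# per-mimic result serialization
# ---------------------------------------------------------------------------

MIMIC_RESULT_COLUMNS = [
    "entity",
    "mu_vehicle",
    "mu_drug",
    "ratio",
    "vehicle_change",
    "t_stat",
    "df",
    "p_value",
    "q_value",
    "vehicle_p",
    "percentile_rank",
    "hit_class",
]


def write_results(results: Sequence, path: str | Path) -> None:
    """Serialize per-mimic results to CSV, 12-significant-digit floats.

    NaN q-values (degenerate variance) are written as empty fields and
    flagged in a ``warnings`` column so the information is not lost
    silently.
    """
    if len(results) == 0:
        raise EmptyResultsError("refusing to write an empty result table")
    rows = []
    for r in results:
        rec = {c: getattr(r, c) for c in MIMIC_RESULT_COLUMNS}
        warns = []
        if isinstance(rec["q_value"], float) and np.isnan(rec["q_value"]):
            warns.append("nan_q_value")
        rec["warnings"] = ";".join(warns)
        rows.append(rec)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a results CSV written by :func:`write_results`."""
    df = pd.read_csv(path)
    _require_columns(df, MIMIC_RESULT_COLUMNS, f"results file {path}")
    return df
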