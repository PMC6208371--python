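"""Seeded synthetic-screen generator with known ground truth.

Emulates an arrayed miRNA-mimic chemosensitizer screen: a 1902-entry
library in 96-well plates (one mimic per well, default 84 test + 8
negative-control + 4 positive-control wells), measured in triplicate
under a vehicle arm and a drug arm dosed at a sub-lethal concentration
of the chemotherapeutic.

Signal model per well and replicate:

    vehicle:  S = B * v_m * eps
    drug:     S = B * v_m * g * s_m * eps

where B is a per-plate baseline (lognormal, drawn once per plate and
shared by both arms), v_m the mimic's vehicle-viability effect (1 for
null entries), g the surviving fraction of the drug alone on its 4PL
curve at the screening dose (defaults give g = 0.8, i.e. an IC20), s_m
the mimic's drug-interaction ratio (< 1 sensitizer, > 1 desensitizer,
1 null), and eps multiplicative lognormal noise with mean 1 and the
configured CV.  NC wells use v = s = 1; PC wells use the configured
kill-level viability.  Everything is reproducible from the seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .dose_response import four_pl
from .errors import SizingError
from .screen_model import (
    CombinationTable,
    DoseResponseTable,
    PlateMap,
    ScreenDataset,
    WellRole,
    all_wells,
)
from .synergy_ci import MedianEffectFit, dx

CLASSES = ("sensitizer", "desensitizer", "vehicle_toxic", "null")

NC_ENTITY = "miR-NC"  # non-targeting mimic (ath-miR-416 / cel-miR-243 class)
PC_ENTITY = "siPLK1"  # kill control


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of the emulated screen (all seeded)."""

    n_mimics: int = 1902
    n_test_wells: int = 84
    n_nc_wells: int = 8
    n_pc_wells: int = 4
    n_replicates: int = 3
    noise_cv: float = 0.05
    fractions: dict = field(
        default_factory=lambda: {
            "sensitizer": 0.02,
            "desensitizer": 0.01,
            "vehicle_toxic": 0.02,
            "null": 0.95,
        }
    )
    sensitizer_ratio: tuple = (0.5, 0.9)
    desensitizer_ratio: tuple = (1.2, 1.5)
    vehicle_toxic_low: tuple = (0.4, 0.7)
    vehicle_toxic_high: tuple = (1.3, 1.6)
    drug_curve: tuple = (0.0, 1.0, 8.0, 1.0)  # bottom, top, ic50 (nM), hill
    drug_dose: float = 2.0  # nM; the IC20 of the default curve
    pc_viability: float = 0.10
    baseline_mean: float = 1000.0
    baseline_cv: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.fractions.values()) - 1.0) > 1e-9:
            raise ValueError("class fractions must sum to 1")
        if set(self.fractions) != set(CLASSES):
            raise ValueError(f"fractions must cover exactly {CLASSES}")
        if self.noise_cv < 0 or self.drug_dose < 0:
            raise ValueError("noise_cv and drug_dose must be >= 0")
        total = self.n_test_wells + self.n_nc_wells + self.n_pc_wells
        if self.n_test_wells < 1 or total > 96:
            raise SizingError(
                f"layout {self.n_test_wells}+{self.n_nc_wells}+{self.n_pc_wells} "
                "does not fit a 96-well plate"
            )
        if self.n_nc_wells < 2 or self.n_pc_wells < 2:
            raise SizingError("need >=2 NC and >=2 PC wells per plate")

    @property
    def n_plates(self) -> int:
        return math.ceil(self.n_mimics / self.n_test_wells)

    @property
    def drug_surviving_fraction(self) -> float:
        """g: viability of the drug alone at the screening dose, vs dose 0."""
        bottom, top, ic50, hill = self.drug_curve
        return float(four_pl(np.array([self.drug_dose]), bottom, top, ic50, hill)[0] / top)


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with mean exactly 1 and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def _class_counts(cfg: GeneratorConfig) -> dict[str, int]:
    """Largest-remainder apportionment of n_mimics to classes."""
    exact = {c: cfg.fractions[c] * cfg.n_mimics for c in CLASSES}
    counts = {c: int(math.floor(v)) for c, v in exact.items()}
    short = cfg.n_mimics - sum(counts.values())
    for c in sorted(CLASSES, key=lambda c: exact[c] - counts[c], reverse=True)[:short]:
        counts[c] += 1
    return counts


def simulate_truth(cfg: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw class labels and true effects for every library entry."""
    counts = _class_counts(cfg)
    labels = np.repeat(list(counts.keys()), list(counts.values()))
    rng.shuffle(labels)
    v = np.ones(cfg.n_mimics)
    s = np.ones(cfg.n_mimics)
    for i, cls in enumerate(labels):
        if cls == "sensitizer":
            s[i] = rng.uniform(*cfg.sensitizer_ratio)
        elif cls == "desensitizer":
            s[i] = rng.uniform(*cfg.desensitizer_ratio)
        elif cls == "vehicle_toxic":
            rng_range = cfg.vehicle_toxic_low if rng.random() < 0.5 else cfg.vehicle_toxic_high
            v[i] = rng.uniform(*rng_range)
    return pd.DataFrame(
        {
            "entity": [f"mimic-{i + 1:04d}" for i in range(cfg.n_mimics)],
            "class": labels,
            "vehicle_effect": v,
            "drug_ratio": s,
        }
    )


def _build_plate_maps(cfg: GeneratorConfig, entities: list[str]) -> dict[str, PlateMap]:
    """Deterministic fill order: library order across plates, row-major wells."""
    wells = all_wells()
    n_ctrl = cfg.n_nc_wells + cfg.n_pc_wells
    test_slots = wells[: 96 - n_ctrl][: cfg.n_test_wells]
    pc_slots = wells[96 - n_ctrl : 96 - cfg.n_nc_wells]
    nc_slots = wells[96 - cfg.n_nc_wells :]
    maps: dict[str, PlateMap] = {}
    for p in range(cfg.n_plates):
        chunk = entities[p * cfg.n_test_wells : (p + 1) * cfg.n_test_wells]
        roles = {w: WellRole.EMPTY for w in wells}
        ents = {}
        for w, e in zip(test_slots, chunk):
            roles[w] = WellRole.TEST
            ents[w] = e
        for w in nc_slots:
            roles[w] = WellRole.NEGATIVE_CONTROL
        for w in pc_slots:
            roles[w] = WellRole.POSITIVE_CONTROL
        pid = f"P{p + 1:02d}"
        maps[pid] = PlateMap(pid, roles, ents)
    return maps


def simulate_screen(cfg: GeneratorConfig) -> tuple[ScreenDataset, pd.DataFrame]:
    """Generate a full screen and its ground truth, reproducibly from cfg.seed.

    Returns (dataset, truth); truth columns: entity, class,
    vehicle_effect, drug_ratio.
    """
    rng = np.random.default_rng(cfg.seed)
    truth = simulate_truth(cfg, rng)
    maps = _build_plate_maps(cfg, truth["entity"].tolist())
    g = cfg.drug_surviving_fraction
    effects_v = dict(zip(truth["entity"], truth["vehicle_effect"]))
    effects_s = dict(zip(truth["entity"], truth["drug_ratio"]))

    frames = []
    for pid, pm in maps.items():
        baseline = cfg.baseline_mean * _lognormal_noise(rng, cfg.baseline_cv, ())
        wells, v_fac, s_fac = [], [], []
        for w, role in pm.roles.items():
            if role is WellRole.EMPTY:
                continue
            wells.append(w)
            if role is WellRole.TEST:
                e = pm.entities[w]
                v_fac.append(effects_v[e])
                s_fac.append(effects_s[e])
            elif role is WellRole.NEGATIVE_CONTROL:
                v_fac.append(1.0)
                s_fac.append(1.0)
            else:  # positive control
                v_fac.append(cfg.pc_viability)
                s_fac.append(1.0)
        v_fac = np.array(v_fac)
        s_fac = np.array(s_fac)
        for arm in ("vehicle", "drug"):
            mean = baseline * v_fac * (g * s_fac if arm == "drug" else 1.0)
            for rep in range(1, cfg.n_replicates + 1):
                eps = _lognormal_noise(rng, cfg.noise_cv, len(wells))
                frames.append(
                    pd.DataFrame(
                        {
                            "plate": pid,
                            "well": wells,
                            "arm": arm,
                            "replicate": rep,
                            "signal": mean * eps,
                        }
                    )
                )
    measurements = pd.concat(frames, ignore_index=True)
    return ScreenDataset(maps, measurements), truth


def simulate_dose_response(
    params: tuple,
    doses: np.ndarray,
    n_replicates: int = 3,
    noise_cv: float = 0.10,
    seed: int = 0,
    agent: str = "agent",
) -> DoseResponseTable:
    """Viability = 4PL(D) * eps per replicate at each dose; seeded."""
    rng = np.random.default_rng(seed)
    doses = np.asarray(doses, dtype=float)
    bottom, top, ic50, hill = params
    rows = []
    for rep in range(1, n_replicates + 1):
        eps = _lognormal_noise(rng, noise_cv, doses.size)
        viab = four_pl(doses, bottom, top, ic50, hill) * eps
        rows.append(pd.DataFrame({"dose": doses, "replicate": rep, "viability": viab}))
    return DoseResponseTable(agent, pd.concat(rows, ignore_index=True), scale="fraction")


def half_log_doses(lo: float, n: int = 8) -> np.ndarray:
    """n doses spaced half a log10 apart starting at lo."""
    return lo * 10.0 ** (0.5 * np.arange(n))


def simulate_combination(
    params_1: tuple,
    params_2: tuple,
    dose_grid: list[tuple],
    mode: str = "additive",
    boost: float = 1.0,
    seed: int = 0,
) -> CombinationTable:
    """Combination responses under Loewe additivity, optionally potency-boosted.

    ``params_i`` are median-effect parameters (m, Dm).  Additive mode
    solves d1/Dx1(fa) + d2/Dx2(fa) = 1 for fa at every grid point;
    boost mode multiplies agent 1's effective contribution by
    ``boost`` (k > 1 models a potency gain in combination, so the
    downstream combination index comes out below 1).  Deterministic
    (the seed is reserved for future noisy modes).
    """
    if mode not in ("additive", "boost"):
        raise ValueError("mode must be 'additive' or 'boost'")
    k = boost if mode == "boost" else 1.0
    if k <= 0:
        raise ValueError("boost must be > 0")
    fit1 = MedianEffectFit("agent1", *params_1, r2=1.0, n_points=0)
    fit2 = MedianEffectFit("agent2", *params_2, r2=1.0, n_points=0)

    rows = []
    for d1, d2 in dose_grid:
        if d1 == 0 and d2 == 0:
            warnings.warn("grid point with both doses zero skipped")
            continue

        def excess(fa: float) -> float:
            tot = 0.0
            if d1 > 0:
                tot += k * d1 / dx(fit1, fa)
            if d2 > 0:
                tot += d2 / dx(fit2, fa)
            return tot - 1.0

        fa = optimize.brentq(excess, 1e-12, 1.0 - 1e-12, xtol=1e-15, rtol=1e-14)
        rows.append((float(d1), float(d2), float(fa)))
    return CombinationTable(pd.DataFrame(rows, columns=["dose_1", "dose_2", "fa"]))
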