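import numpy as np
import pandas as pd
import pytest

from sensiscreen.screen_model import PlateMap, ScreenDataset, WellRole
from sensiscreen.synthetic_data import GeneratorConfig, simulate_screen


def make_plate_map(plate_id="P01", n_test=4, n_nc=2, n_pc=2):
    """A tiny hand-rolled plate map: test wells in row A, controls in row H."""
    roles = {}
    entities = {}
    for i in range(n_test):
        w = f"A{i + 1}"
        roles[w] = WellRole.TEST
        entities[w] = f"{plate_id}-mimic-{i + 1}"
    for i in range(n_nc):
        roles[f"H{i + 1}"] = WellRole.NEGATIVE_CONTROL
    for i in range(n_pc):
        roles[f"H{i + 7}"] = WellRole.POSITIVE_CONTROL
    return PlateMap(plate_id, roles, entities)


def make_screen(signal_fn, plate_ids=("P01", "P02"), n_reps=2, **map_kw):
    """Build a ScreenDataset whose signal is signal_fn(plate, well, arm, rep)."""
    maps = {pid: make_plate_map(pid, **map_kw) for pid in plate_ids}
    rows = []
    for pid, pm in maps.items():
        for well in pm.roles:
            for arm in ("vehicle", "drug"):
                for rep in range(1, n_reps + 1):
                    rows.append((pid, well, arm, rep, signal_fn(pid, well, arm, rep)))
    df = pd.DataFrame(rows, columns=["plate", "well", "arm", "replicate", "signal"])
    return ScreenDataset(maps, df)


@pytest.fixture
def toy_screen():
    """Two 8-well plates, constant signals: NC 100, PC 10, test wells 80."""

    def signal(pid, well, arm, rep):
        if well.startswith("H") and int(well[1:]) <= 2:
            return 100.0
        if well.startswith("H"):
            return 10.0
        return 80.0

    return make_screen(signal)


@pytest.fixture
def small_noisy_screen():
    cfg = GeneratorConfig(n_mimics=120, seed=7)
    return simulate_screen(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
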