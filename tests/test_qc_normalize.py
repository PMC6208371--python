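import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sensiscreen.errors import (
    DegenerateNormalizationError,
    InsufficientControlsError,
    MissingArmError,
    UndefinedSSMDError,
)
from sensiscreen.qc_normalize import (
    ControlSummary,
    control_drift,
    control_summary,
    normalize_plate,
    plate_qc,
    screen_passes_qc,
    ssmd,
)
from sensiscreen.synthetic_data import GeneratorConfig, simulate_screen

from conftest import make_screen


def _cs(mu_nc, sd_nc, mu_pc, sd_pc):
    return ControlSummary("P", "vehicle", mu_nc, sd_nc, mu_pc, sd_pc, 3, 3)


class TestControlSummary:
    def test_constant_controls(self):
        def signal(pid, well, arm, rep):
            return {"H1": 10.0, "H2": 10.0, "H7": 1.0, "H8": 1.0}.get(well, 5.0)

        ds = make_screen(signal, plate_ids=("P01",), n_reps=1)
        cs = control_summary(ds, "P01", "vehicle")
        assert (cs.mu_nc, cs.sd_nc, cs.mu_pc, cs.sd_pc) == (10.0, 0.0, 1.0, 0.0)

    def test_hand_arithmetic_n_minus_1(self):
        """NC {9,10,11}, PC {1,2,3}: sample SDs use the n-1 denominator."""
        nc = {("H1", 1): 9.0, ("H2", 1): 10.0, ("H1", 2): 11.0}
        pc = {("H7", 1): 1.0, ("H8", 1): 2.0, ("H7", 2): 3.0}

        def signal(pid, well, arm, rep):
            return nc.get((well, rep), pc.get((well, rep), 5.0))

        ds = make_screen(signal, plate_ids=("P01",), n_reps=2)
        # drop one measurement per control pair so each group has exactly 3
        ds.measurements = ds.measurements[
            ~(
                ds.measurements["well"].isin(["H2", "H8"])
                & (ds.measurements["replicate"] == 2)
            )
        ]
        cs = control_summary(ds, "P01", "vehicle")
        assert cs.mu_nc == pytest.approx(10.0)
        assert cs.sd_nc == pytest.approx(1.0)
        assert cs.mu_pc == pytest.approx(2.0)
        assert cs.sd_pc == pytest.approx(1.0)

    def test_too_few_controls_rejected(self):
        def signal(pid, well, arm, rep):
            return 10.0

        ds = make_screen(signal, plate_ids=("P01",), n_pc=1)
        with pytest.raises(InsufficientControlsError):
            control_summary(ds, "P01", "vehicle")

    def test_generator_controls_recovered(self):
        """Configured NC level and CV show up in the pooled summary."""
        ds, _ = simulate_screen(GeneratorConfig(n_mimics=84, noise_cv=0.05, seed=2,
                                                baseline_mean=1000.0, baseline_cv=0.0))
        cs = control_summary(ds, "P01", "vehicle")
        assert cs.mu_nc == pytest.approx(1000.0, rel=0.05)
        assert cs.sd_nc / cs.mu_nc == pytest.approx(0.05, rel=0.5)
        assert cs.n_nc == 8 * 3


class TestSSMD:
    def test_no_separation_is_zero(self):
        assert ssmd(_cs(5.0, 0.3, 5.0, 0.3)) == 0.0

    def test_closed_form(self):
        assert ssmd(_cs(1.0, 0.1, 0.1, 0.1)) == pytest.approx(0.9 / math.sqrt(0.02))
        assert ssmd(_cs(1.0, 0.1, 0.1, 0.1)) == pytest.approx(6.3640, abs=1e-4)

    def test_degenerate_sentinel_and_error(self):
        assert ssmd(_cs(2.0, 0.0, 1.0, 0.0)) == math.inf
        assert ssmd(_cs(1.0, 0.0, 2.0, 0.0)) == -math.inf
        with pytest.raises(UndefinedSSMDError):
            ssmd(_cs(1.0, 0.0, 1.0, 0.0))

    @given(
        shift=st.floats(-50, 50),
        scale=st.floats(0.01, 100),
        mu_nc=st.floats(0.5, 10),
        mu_pc=st.floats(0.0, 0.4),
        sd=st.floats(0.01, 1),
    )
    @settings(deadline=None, max_examples=60)
    def test_invariance_under_affine_recalibration(self, shift, scale, mu_nc, mu_pc, sd):
        """Common additive shift and positive scaling leave SSMD unchanged."""
        base = ssmd(_cs(mu_nc, sd, mu_pc, sd))
        moved = ssmd(_cs(scale * mu_nc + shift, scale * sd, scale * mu_pc + shift, scale * sd))
        assert moved == pytest.approx(base, rel=1e-9)

    @given(extra=st.floats(0, 10))
    @settings(deadline=None, max_examples=40)
    def test_pass_monotone_in_control_separation(self, extra):
        """Widening the NC-PC gap at fixed spreads never flips pass -> fail."""
        base = ssmd(_cs(5.0, 0.5, 1.0, 0.5))
        wider = ssmd(_cs(5.0 + extra, 0.5, 1.0, 0.5))
        assert (base >= 3.0) <= (wider >= 3.0)

    def test_default_generator_plates_pass_qc(self):
        ds, _ = simulate_screen(GeneratorConfig(n_mimics=168, seed=4))
        table = plate_qc(ds, threshold=3.0)
        assert table["pass"].all()
        assert screen_passes_qc(table)


class TestNormalizePlate:
    def test_nc_wells_anchor_z_and_viability(self, small_noisy_screen):
        ds, _ = small_noisy_screen
        np_plate = normalize_plate(ds, "P01", "vehicle")
        pm = ds.plate_maps["P01"]
        from sensiscreen.screen_model import WellRole

        nc_wells = pm.wells_with_role(WellRole.NEGATIVE_CONTROL)
        nc = np_plate.data[np_plate.data["well"].isin(nc_wells)]
        assert nc["z"].mean() == pytest.approx(0.0, abs=1e-9)
        assert nc["z"].std(ddof=1) == pytest.approx(1.0, abs=1e-9)
        assert nc["viability"].mean() == pytest.approx(1.0, abs=1e-9)

    def test_hand_arithmetic(self):
        def signal(pid, well, arm, rep):
            if well in ("H1", "H2"):
                return {1: 0.9, 2: 1.1}[rep]  # mu_nc 1.0, sd_nc ~0.1155
            return 1.2

        ds = make_screen(signal, plate_ids=("P01",))
        cs = control_summary(ds, "P01", "vehicle")
        np_plate = normalize_plate(ds, "P01", "vehicle")
        row = np_plate.data[np_plate.data["well"] == "A1"].iloc[0]
        assert row["viability"] == pytest.approx(1.2)
        assert row["z"] == pytest.approx((1.2 - 1.0) / cs.sd_nc)

    def test_all_identical_signals_degenerate(self):
        ds = make_screen(lambda *a: 7.0, plate_ids=("P01",))
        with pytest.raises(DegenerateNormalizationError):
            normalize_plate(ds, "P01", "vehicle")

    def test_idempotent_on_normalized_viability(self, small_noisy_screen):
        """Re-normalizing NC-mean-1 viabilities changes nothing."""
        ds, _ = small_noisy_screen
        first = normalize_plate(ds, "P01", "vehicle")
        ds2_meas = ds.measurements.copy()
        sel = (ds2_meas["plate"] == "P01") & (ds2_meas["arm"] == "vehicle")
        merged = ds2_meas.loc[sel].merge(
            first.data, on=["well", "replicate"], suffixes=("", "_n")
        )
        ds2_meas.loc[sel, "signal"] = merged["viability"].to_numpy()
        from sensiscreen.screen_model import ScreenDataset

        ds2 = ScreenDataset(ds.plate_maps, ds2_meas)
        second = normalize_plate(ds2, "P01", "vehicle")
        np.testing.assert_allclose(
            second.data["viability"].to_numpy(), first.data["viability"].to_numpy(),
            rtol=1e-12,
        )


class TestControlDrift:
    def test_identical_arms_zero_drift(self, toy_screen):
        report = control_drift(toy_screen)
        assert report.mean_drift == pytest.approx(0.0, abs=1e-12)

    def test_twenty_percent_reduction(self):
        """NC vehicle mean 100, NC drug mean 80 -> drift 0.20."""

        def signal(pid, well, arm, rep):
            if well in ("H1", "H2"):
                return 100.0 if arm == "vehicle" else 80.0
            return 50.0

        report = control_drift(make_screen(signal, plate_ids=("P01",)))
        assert report.mean_drift == pytest.approx(0.20)

    def test_missing_arm_error(self, toy_screen):
        veh_only = toy_screen.measurements[toy_screen.measurements["arm"] == "vehicle"]
        from sensiscreen.screen_model import ScreenDataset

        ds = ScreenDataset(toy_screen.plate_maps, veh_only)
        with pytest.raises(MissingArmError):
            control_drift(ds)

    def test_ic20_dosing_gives_20pct_drift(self):
        """Drug at 2 nM on a (0, 1, 8 nM, 1) curve kills 20% of NC signal."""
        ds, _ = simulate_screen(GeneratorConfig(n_mimics=252, seed=9))
        report = control_drift(ds)
        assert report.mean_drift == pytest.approx(0.20, abs=0.02)
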