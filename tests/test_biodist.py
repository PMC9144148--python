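"""%ID quantification: autofluorescence correction and calibration."""

import numpy as np
import pandas as pd
import pytest

from renoperf import biodist as bd
from renoperf import synthetic as syn


def make_table(tre, area, group):
    organs = list(tre)
    df = pd.DataFrame(
        {"organ": organs, "tre": [tre[o] for o in organs], "area": [area[o] for o in organs]}
    )
    return syn.OrganFluorescenceTable(df, group)


class TestAutofluorescenceCorrection:
    organs = ("left kidney", "liver")

    def test_pure_autofluorescence_cancels(self):
        area = {"left kidney": 1.0, "liver": 3.0}
        ctrl_tre = {"left kidney": 10.0, "liver": 30.0}
        exp = make_table(ctrl_tre, area, "experimental")
        ctrl = make_table(ctrl_tre, area, "control")
        out = bd.correct_autofluorescence(exp, ctrl)
        np.testing.assert_allclose(out["corrected_tre"], 0.0, atol=1e-12)

    def test_zero_control_passes_tre_through(self):
        area = {"left kidney": 1.0, "liver": 3.0}
        exp = make_table({"left kidney": 5.0, "liver": 7.0}, area, "experimental")
        ctrl = make_table({"left kidney": 0.0, "liver": 0.0}, area, "control")
        out = bd.correct_autofluorescence(exp, ctrl).set_index("organ")
        assert out.loc["left kidney", "corrected_tre"] == 5.0
        assert out.loc["liver", "corrected_tre"] == 7.0

    def test_area_scaling_of_control_density(self):
        # experimental organ twice the control area -> subtract twice the TRE
        exp = make_table({"liver": 25.0}, {"liver": 6.0}, "experimental")
        ctrl = make_table({"liver": 10.0}, {"liver": 3.0}, "control")
        out = bd.correct_autofluorescence(exp, ctrl)
        assert out["corrected_tre"][0] == pytest.approx(25.0 - 20.0)

    def test_negative_correction_clamped_and_flagged(self):
        exp = make_table({"liver": 1.0}, {"liver": 3.0}, "experimental")
        ctrl = make_table({"liver": 10.0}, {"liver": 3.0}, "control")
        out = bd.correct_autofluorescence(exp, ctrl)
        assert out["corrected_tre"][0] == 0.0
        assert bool(out["clamped"][0])

    def test_known_signal_recovered(self):
        truth = {o: 0.0 for o in syn.ORGANS}
        truth["left kidney"] = 60.0
        truth["right kidney"] = 40.0
        exp, ctrl = syn.simulate_organ_tables(truth, noise_cv=0.0, seed=0)
        out = bd.correct_autofluorescence(exp, ctrl).set_index("organ")
        ratio = (
            out.loc["left kidney", "corrected_tre"]
            / out.loc["right kidney", "corrected_tre"]
        )
        assert ratio == pytest.approx(1.5, rel=1e-9)


class TestPercentID:
    def test_single_nonzero_organ_takes_100(self):
        corrected = pd.DataFrame(
            {"organ": ["left kidney", "liver"], "corrected_tre": [5.0, 0.0]}
        )
        pid = bd.percent_id_from_tre(corrected).set_index("organ")["percent_id"]
        assert pid["left kidney"] == 100.0
        assert pid["liver"] == 0.0

    def test_equal_tre_splits_evenly(self):
        corrected = pd.DataFrame(
            {"organ": ["left kidney", "right kidney"], "corrected_tre": [3.0, 3.0]}
        )
        pid = bd.percent_id_from_tre(corrected)["percent_id"]
        np.testing.assert_allclose(pid, 50.0)

    def test_rows_sum_to_100(self):
        rng = np.random.default_rng(2)
        corrected = pd.DataFrame(
            {"organ": list(syn.ORGANS), "corrected_tre": rng.uniform(0, 10, 9)}
        )
        pid = bd.percent_id_from_tre(corrected)
        assert pid["percent_id"].sum() == pytest.approx(100.0, abs=1e-6)

    def test_all_zero_table_rejected(self):
        corrected = pd.DataFrame(
            {"organ": ["left kidney"], "corrected_tre": [0.0]}
        )
        with pytest.raises(ValueError, match="undefined"):
            bd.percent_id_from_tre(corrected)

    def test_experimental_equal_to_scaled_control_fires_all_zero_error(self):
        # correction identity: exp tables that are exactly per-area-scaled
        # control tables leave nothing to normalise
        area = {"left kidney": 1.0, "liver": 2.0}
        ctrl_tre = {"left kidney": 4.0, "liver": 8.0}
        exp = make_table(ctrl_tre, area, "experimental")
        ctrl = make_table(ctrl_tre, area, "control")
        corrected = bd.correct_autofluorescence(exp, ctrl)
        with pytest.raises(ValueError, match="undefined"):
            bd.percent_id_from_tre(corrected)


class TestCalibration:
    def test_perfect_line(self):
        curve = bd.fit_calibration([0.0, 1.0, 2.0], [1.0, 3.0, 5.0])
        assert curve.slope == pytest.approx(2.0)
        assert curve.intercept == pytest.approx(1.0)
        assert curve.r_squared == pytest.approx(1.0)
        assert curve.wavelength_nm == 785.0

    def test_noiseless_plate_round_trip_is_exact(self):
        plate = syn.simulate_fluorimetry_plate(
            [0.0, 50.0, 100.0, 200.0], [25.0, 75.0],
            slope=100.0, intercept=50.0, noise_sd=0.0, seed=1,
        )
        curve = bd.calibration_from_plate(plate)
        assert curve.slope == pytest.approx(100.0, rel=1e-12)
        assert curve.intercept == pytest.approx(50.0, abs=1e-9)
        for name, true_mass in plate.samples.items():
            mass, clamped = bd.mass_from_plate(plate, name, curve)
            assert not clamped
            assert mass == pytest.approx(true_mass, rel=1e-9)

    def test_identical_masses_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            bd.fit_calibration([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])

    def test_mass_inversion_fixed_points(self):
        curve = bd.CalibrationCurve(slope=2.0, intercept=1.0, r_squared=1.0, n_standards=3)
        wl = np.arange(770.0, 841.0)
        spec_at = lambda v: np.where(wl == 785.0, v, 0.0)
        assert bd.mass_from_spectrum(wl, [spec_at(1.0)], curve) == (0.0, False)
        assert bd.mass_from_spectrum(wl, [spec_at(3.0)], curve)[0] == pytest.approx(1.0)

    def test_negative_mass_clamped_with_flag(self):
        curve = bd.CalibrationCurve(slope=2.0, intercept=1.0, r_squared=1.0, n_standards=3)
        wl = np.arange(770.0, 841.0)
        mass, clamped = bd.mass_from_spectrum(wl, [np.zeros(wl.size)], curve)
        assert mass == 0.0 and clamped

    def test_missing_785_rejected(self):
        curve = bd.CalibrationCurve(slope=2.0, intercept=1.0, r_squared=1.0, n_standards=3)
        wl = np.arange(700.0, 760.0)
        with pytest.raises(ValueError, match="785"):
            bd.mass_from_spectrum(wl, [np.zeros(wl.size)], curve)

    def test_noisy_sample_within_error_propagation_bound(self):
        slope, noise_sd = 100.0, 5.0
        recovered = []
        for seed in range(200):
            plate = syn.simulate_fluorimetry_plate(
                [0.0, 50.0, 100.0, 200.0], [60.0],
                slope=slope, intercept=50.0, noise_sd=noise_sd, seed=seed,
            )
            curve = bd.calibration_from_plate(plate)
            recovered.append(bd.mass_from_plate(plate, "S1", curve)[0])
        err = np.abs(np.array(recovered) - 60.0)
        # 3 sigma bound on the inverted intensity noise
        assert np.median(err) < 3 * noise_sd / slope * 3  # generous MC margin
        assert np.percentile(err, 90) < 3 * noise_sd / slope * 5


class TestPercentIDInjected:
    def test_fixed_points(self):
        assert bd.percent_id_injected(5.0, 5.0) == 100.0
        assert bd.percent_id_injected(0.0, 5.0) == 0.0
        assert bd.percent_id_injected(1.5, 5.0) == 30.0

    def test_zero_injected_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            bd.percent_id_injected(1.0, 0.0)

    def test_digest_route_recovers_retained_fraction(self):
        # 30 % of a 200-unit injection retained in the kidney digest
        injected, retained = 200.0, 60.0
        plate = syn.simulate_fluorimetry_plate(
            [0.0, 50.0, 100.0, 200.0], [retained], noise_sd=0.0, seed=4
        )
        curve = bd.calibration_from_plate(plate)
        mass, _ = bd.mass_from_plate(plate, "S1", curve)
        assert bd.percent_id_injected(mass, injected) == pytest.approx(30.0, rel=1e-9)


class TestKinetics:
    timepoints = ["1 min", "15 min", "1 h", "3 h", "6 h", "24 h"]

    def _pid(self, left, right):
        rest = 100.0 - left - right
        return pd.DataFrame(
            {
                "organ": ["left kidney", "right kidney", "liver"],
                "percent_id": [left, right, rest],
            }
        )

    def test_single_timepoint_passthrough(self):
        out = bd.assemble_timecourse({"1 min": self._pid(60, 10)}, "encapsulated")
        assert len(out) == 3
        assert set(out["timepoint"]) == {"1 min"}
        assert (out["form"] == "encapsulated").all()

    def test_six_timepoints_give_six_by_organs_rows(self):
        tables = {t: self._pid(60 - i, 10) for i, t in enumerate(self.timepoints)}
        out = bd.assemble_timecourse(tables, "free")
        assert len(out) == 6 * 3
        assert list(out["timepoint"].unique()) == self.timepoints

    def test_target_over_contralateral_kidney_ratio(self):
        tables = {"1 min": self._pid(60, 10), "24 h": self._pid(30, 10)}
        kin = bd.assemble_timecourse(tables, "encapsulated")
        ratios = bd.kidney_ratio(kin).set_index("timepoint")["left_over_right"]
        assert ratios["1 min"] == pytest.approx(6.0)
        assert ratios["24 h"] == pytest.approx(3.0)

    def test_unknown_form_rejected(self):
        with pytest.raises(ValueError, match="form"):
            bd.assemble_timecourse({"1 min": self._pid(60, 10)}, "gel")
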