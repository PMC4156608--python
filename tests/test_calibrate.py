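"""Calibration-curve fitting and the two concentration pathways."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import interior_mask, make_uniform_phantom
from lamap import calibrate as cal
from lamap import phantom as ph
from lamap import reconstruct as rec
from lamap import scan_io as sio
from lamap.errors import CalibrationError, DegenerateRangeError, RankError


class TestFitSlope:
    def test_two_point_line_hand_arithmetic(self):
        curve = cal.fit_slope([(0.0, 50.0), (10.0, 1050.0)], channel="Cu63")
        assert curve.slope == pytest.approx(100.0)
        assert curve.intercept == pytest.approx(50.0)

    def test_noiseless_standards_recover_instrument_exactly(self):
        inst = ph.InstrumentModel(noise_model="none")
        stds = ph.simulate_standards(ph.default_standard_spec(), inst, seed=1)
        curves = cal.fit_curves(stds, channels=["Cu63", "Zn64", "Mn55", "Fe57"])
        for ch, curve in curves.items():
            assert curve.slope == pytest.approx(inst.sensitivity[ch], rel=1e-12)
            assert curve.intercept == pytest.approx(inst.background[ch], abs=1e-8)
            assert curve.r_squared == pytest.approx(1.0)

    def test_poisson_slope_within_fitted_se(self):
        inst = ph.InstrumentModel(noise_model="poisson")
        spec = ph.StandardSpec(
            levels=[
                ph.StandardLevel(concentrations={}, n_lines=2),
                ph.StandardLevel(concentrations={"Cu": 10.0}, n_lines=2),
                ph.StandardLevel(concentrations={"Cu": 40.0}, n_lines=2),
                ph.StandardLevel(concentrations={"Cu": 80.0}, n_lines=2),
            ],
            cycles_per_line=100,
        )
        stds = ph.simulate_standards(spec, inst, seed=3)
        curve = cal.fit_slope(cal.standards_to_levels(stds, "Cu63"), channel="Cu63")
        assert abs(curve.slope - inst.sensitivity["Cu63"]) < 3 * curve.slope_se

    def test_identical_concentrations_rejected(self):
        with pytest.raises(RankError):
            cal.fit_slope([(5.0, 100.0), (5.0, 120.0)])

    def test_negative_slope_rejected(self):
        with pytest.raises(CalibrationError):
            cal.fit_slope([(0.0, 1000.0), (10.0, 100.0)])

    def test_curve_serialization_round_trip(self, tmp_path):
        curve = cal.fit_slope([(0.0, 50.0), (10.0, 1050.0)], channel="Cu63",
                              curve_id="std-C01-L")
        path = tmp_path / "curve.txt"
        cal.write_curve(curve, path)
        back = cal.read_curve(path)
        assert back.channel == curve.channel
        assert back.slope == pytest.approx(curve.slope)
        assert back.intercept == pytest.approx(curve.intercept)
        assert len(back.levels) == 2


class TestConcentrationPathways:
    def test_counts_at_background_give_zero(self):
        curve = cal.fit_slope([(0.0, 50.0), (10.0, 1050.0)], channel="Cu63")
        assert cal.concentration_from_counts(50.0, curve) == 0.0
        assert cal.concentration_from_counts(50.0 + 100.0 * 5, curve) == pytest.approx(5.0)

    def test_gray_formula_hand_arithmetic(self):
        value = cal.concentration_from_gray(
            gray=128, background_gray=8, max_counts=10_000, min_counts=0, slope=100
        )
        assert value == pytest.approx(10_000 * 120 / 25_500)
        assert cal.concentration_from_gray(8, 8, 10_000, 0, 100) == 0.0

    def test_degenerate_range_rejected(self):
        with pytest.raises(DegenerateRangeError):
            cal.concentration_from_gray(10, 0, 100.0, 100.0, 1.0)

    @given(seed=st.integers(0, 500))
    def test_gray_and_raw_pathways_agree_within_half_lsb(self, seed):
        rng = np.random.default_rng(seed)
        slope, background = rng.uniform(50, 2000), rng.uniform(0, 200)
        conc = rng.uniform(0, 80, (6, 9))
        counts = slope * conc + background
        lo, hi = 0.0, float(counts.max()) * 1.05
        img = sio.export_gray8(counts, stretch=(lo, hi))
        background_gray = 255.0 * (background - lo) / (hi - lo)
        gray_conc = cal.concentration_from_gray(img.data, background_gray, hi, lo, slope)
        raw_conc = np.maximum((counts - background) / slope, 0.0)
        bound = (hi - lo) / (510.0 * slope)
        assert np.max(np.abs(gray_conc - raw_conc)) <= bound + 1e-12


class TestCalibrateStack:
    def _run(self, inst, truth_conc, seed=1):
        phantom = make_uniform_phantom()
        truth = {r: {"Cu": truth_conc} for r in phantom.regions()}
        scan = ph.simulate_scan(phantom, truth, inst, seed=seed)
        return phantom, rec.rasterize(scan)

    def test_each_hemisphere_calibrated_with_own_standard(self):
        # two runs with 2× different sensitivity both recover the same truth
        conc = 6.5
        spec = ph.default_standard_spec()
        inst_a = ph.InstrumentModel(noise_model="none")
        inst_b = ph.InstrumentModel(
            noise_model="none",
            sensitivity={k: 2 * v for k, v in inst_a.sensitivity.items()},
        )
        for inst in (inst_a, inst_b):
            phantom, stack = self._run(inst, conc)
            curves = cal.fit_curves(
                ph.simulate_standards(spec, inst, seed=9), channels=["Cu63"]
            )
            out = cal.calibrate_stack(stack, curves, channels=["Cu63"])
            interior = interior_mask(phantom.label_map == 1)
            np.testing.assert_allclose(out.get("Cu63")[interior], conc, rtol=1e-9)
            assert out.units["Cu63"] == rec.UNITS_UGG

    def test_wrong_hemisphere_curve_biases_by_slope_ratio(self):
        conc = 6.5
        inst = ph.InstrumentModel(noise_model="none")
        inst2 = ph.InstrumentModel(
            noise_model="none",
            sensitivity={k: 2 * v for k, v in inst.sensitivity.items()},
            background={k: 0.0 for k in inst.background},
        )
        phantom, stack = self._run(
            ph.InstrumentModel(
                noise_model="none",
                sensitivity=inst2.sensitivity,
                background=inst2.background,
            ),
            conc,
        )
        wrong = cal.fit_curves(
            ph.simulate_standards(
                ph.StandardSpec(levels=[
                    ph.StandardLevel(concentrations={}),
                    ph.StandardLevel(concentrations={"Cu": 10.0}),
                ]),
                ph.InstrumentModel(
                    noise_model="none",
                    sensitivity=inst.sensitivity,
                    background={k: 0.0 for k in inst.background},
                ),
                seed=2,
            ),
            channels=["Cu63"],
        )
        out = cal.calibrate_stack(stack, wrong, channels=["Cu63"])
        interior = interior_mask(phantom.label_map == 1)
        np.testing.assert_allclose(out.get("Cu63")[interior], 2 * conc, rtol=1e-9)

    def test_blank_phantom_gives_zero_map(self):
        inst = ph.InstrumentModel(noise_model="none")
        phantom, stack = self._run(inst, 0.0)
        curves = cal.fit_curves(
            ph.simulate_standards(ph.default_standard_spec(), inst, seed=4),
            channels=["Cu63"],
        )
        out = cal.calibrate_stack(stack, curves, channels=["Cu63"])
        assert np.nanmax(out.get("Cu63")) == 0.0

    def test_missing_curve_rejected(self):
        inst = ph.InstrumentModel(noise_model="none")
        _, stack = self._run(inst, 1.0)
        with pytest.raises(CalibrationError):
            cal.calibrate_stack(stack, {}, channels=["Cu63"])
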