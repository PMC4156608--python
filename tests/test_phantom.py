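"""Phantom geometry, cohort sampling and the forward instrument model."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_uniform_phantom
from lamap import phantom as ph
from lamap import reference
from lamap.errors import (
    AlignmentError,
    LayoutError,
    ParameterError,
    ResolutionError,
)


class TestBuildPhantom:
    def test_single_region_yields_two_labels(self):
        p = make_uniform_phantom(name="cortex")
        assert sorted(np.unique(p.label_map)) == [0, 1]
        assert p.regions() == ["cortex"]

    def test_default_layout_covers_reference_regions(self, brain_phantom):
        regions = set(brain_phantom.regions())
        assert regions == set(reference.REGION_PARAMS)
        assert len(regions) >= 12
        ventricles = [r for r in regions if "ventricle" in r]
        assert len(ventricles) == 3

    def test_inner_region_pixel_count_by_enumeration(self):
        # 10×10 grid, 4×4 inner block: exhaustive count = 16
        p = ph.build_phantom([("inner", 3, 7, 3, 7)], (10, 10))
        assert int((p.label_map == 1).sum()) == 4 * 4

    def test_overlapping_regions_rejected(self):
        with pytest.raises(LayoutError):
            ph.build_phantom([("a", 1, 5, 1, 5), ("b", 3, 8, 3, 8)], (10, 10))

    def test_zero_pixel_region_rejected(self):
        with pytest.raises(ResolutionError):
            ph.build_phantom([("a", 4, 4, 1, 5)], (10, 10))

    def test_missing_glass_border_rejected(self):
        with pytest.raises(LayoutError):
            ph.build_phantom([("a", 0, 10, 0, 10)], (10, 10))


class TestSampleCohort:
    def test_zero_sd_reproduces_group_means(self, uniform_phantom):
        table = pd.DataFrame(
            [
                {"group": g, "region": "cortex", "element": "Cu", "mean": m, "sd": 0.0}
                for g, m in (("control", 2.7), ("wd", 5.5))
            ]
        )
        params = ph.GroupParams(table, n_control=3, n_wd=3)
        truth = ph.sample_cohort(params, uniform_phantom, seed=1)
        ctrl = truth.table[truth.table.group == "control"]["concentration"]
        wd = truth.table[truth.table.group == "wd"]["concentration"]
        assert (ctrl == 2.7).all() and (wd == 5.5).all()

    def test_draw_mean_matches_cortex_cu_parameters(self, uniform_phantom):
        # control cortex Cu 2.7 ± 0.7; 10 000 animals → mean within 3 SE
        table = pd.DataFrame(
            [
                {"group": "control", "region": "cortex", "element": "Cu",
                 "mean": 2.7, "sd": 0.7},
                {"group": "wd", "region": "cortex", "element": "Cu",
                 "mean": 5.5, "sd": 1.2},
            ]
        )
        params = ph.GroupParams(table, n_control=10_000, n_wd=2)
        truth = ph.sample_cohort(params, uniform_phantom, seed=42)
        ctrl = truth.table[
            (truth.table.group == "control") & (truth.table.hemisphere == "L")
        ]["concentration"]
        assert len(ctrl) == 10_000
        se = 0.7 / np.sqrt(10_000)
        assert abs(ctrl.mean() - 2.7) < 3 * se

    def test_determinism_and_seed_sensitivity(self, uniform_phantom, group_params):
        params = ph.GroupParams(group_params.table, n_control=2, n_wd=2)
        t1 = ph.sample_cohort(params, uniform_phantom, seed=7)
        t2 = ph.sample_cohort(params, uniform_phantom, seed=7)
        t3 = ph.sample_cohort(params, uniform_phantom, seed=8)
        pd.testing.assert_frame_equal(t1.table, t2.table)
        assert not t1.table["concentration"].equals(t3.table["concentration"])

    def test_hemispheres_share_truth(self, uniform_phantom, group_params):
        params = ph.GroupParams(group_params.table, n_control=2, n_wd=2)
        truth = ph.sample_cohort(params, uniform_phantom, seed=3)
        left = truth.animal_slice("C01", "L")
        right = truth.animal_slice("C01", "R")
        assert left == right

    def test_missing_parameter_raises(self, uniform_phantom):
        table = pd.DataFrame(
            [{"group": "control", "region": "cortex", "element": "Cu",
              "mean": 2.7, "sd": 0.7}]
        )
        params = ph.GroupParams(table, n_control=2, n_wd=2)
        with pytest.raises(ParameterError):
            ph.sample_cohort(params, uniform_phantom, seed=1)

    @given(st.integers(0, 2**31 - 1))
    def test_truncation_never_emits_negative(self, seed):
        phantom = make_uniform_phantom()
        table = pd.DataFrame(
            [
                {"group": g, "region": "cortex", "element": "Cu",
                 "mean": 0.5, "sd": 50.0}
                for g in ("control", "wd")
            ]
        )
        params = ph.GroupParams(table, n_control=2, n_wd=2)
        truth = ph.sample_cohort(params, phantom, seed=seed)
        assert (truth.table["concentration"] >= 0).all()


class TestSimulateScan:
    def _truth(self, phantom, conc):
        return {r: {"Cu": conc} for r in phantom.regions()}

    def test_blank_reads_background_exactly(self, uniform_phantom, noiseless_instrument):
        scan = ph.simulate_scan(
            uniform_phantom, self._truth(uniform_phantom, 0.0),
            noiseless_instrument, seed=1,
        )
        idx = scan.channel_index("Cu63")
        for line in scan.lines:
            assert np.all(line[:, idx] == noiseless_instrument.background["Cu63"])

    def test_uniform_region_interior_is_slope_c_plus_background(
        self, uniform_phantom, noiseless_instrument
    ):
        c = 4.25
        scan = ph.simulate_scan(
            uniform_phantom, self._truth(uniform_phantom, c),
            noiseless_instrument, seed=1,
        )
        idx = scan.channel_index("Cu63")
        inst = noiseless_instrument
        expected = inst.sensitivity["Cu63"] * c + inst.background["Cu63"]
        # interior columns of tissue rows (spot radius ≈ 1.26 px → skip 2)
        interior = np.array([line[6:-6, idx] for line in scan.lines[4:-4]])
        assert np.allclose(interior, expected, rtol=1e-12)

    def test_cycle_advance_matches_acquisition_metadata(self, noiseless_instrument):
        # 70 μm s⁻¹ × 0.341 s ≈ 24 μm per cycle
        assert noiseless_instrument.pixel_size_x == pytest.approx(23.87)
        assert round(noiseless_instrument.pixel_size_x) == 24

    def test_doubling_slope_doubles_net_counts(self, uniform_phantom):
        base = ph.InstrumentModel(noise_model="none")
        doubled = ph.InstrumentModel(
            noise_model="none",
            sensitivity={k: 2 * v for k, v in base.sensitivity.items()},
        )
        t = self._truth(uniform_phantom, 3.0)
        s1 = ph.simulate_scan(uniform_phantom, t, base, seed=1)
        s2 = ph.simulate_scan(uniform_phantom, t, doubled, seed=1)
        i = s1.channel_index("Cu63")
        bg = base.background["Cu63"]
        net1 = np.concatenate([l[:, i] for l in s1.lines]) - bg
        net2 = np.concatenate([l[:, i] for l in s2.lines]) - bg
        assert np.allclose(net2, 2 * net1, rtol=1e-12, atol=1e-9)

    def test_identical_seeds_bit_identical(self, uniform_phantom):
        inst = ph.InstrumentModel(noise_model="poisson")
        t = self._truth(uniform_phantom, 3.0)
        s1 = ph.simulate_scan(uniform_phantom, t, inst, seed=9)
        s2 = ph.simulate_scan(uniform_phantom, t, inst, seed=9)
        for l1, l2 in zip(s1.lines, s2.lines):
            assert np.array_equal(l1, l2)

    def test_geometry_mismatch_rejected(self, noiseless_instrument):
        p = ph.build_phantom([("cortex", 2, 6, 2, 10)], (8, 12), pixel_size_x=10.0)
        with pytest.raises(AlignmentError):
            ph.simulate_scan(p, self._truth(p, 1.0), noiseless_instrument, seed=1)

    def test_missing_region_truth_rejected(self, uniform_phantom, noiseless_instrument):
        with pytest.raises(ParameterError):
            ph.simulate_scan(uniform_phantom, {}, noiseless_instrument, seed=1)


class TestSimulateStandards:
    def test_blank_level_reads_background(self, noiseless_instrument):
        spec = ph.StandardSpec(levels=[ph.StandardLevel(concentrations={})])
        (std,) = ph.simulate_standards(spec, noiseless_instrument, seed=1)
        idx = std.scan.channel_index("Zn64")
        values = np.concatenate([l[:, idx] for l in std.scan.lines])
        assert np.all(values == noiseless_instrument.background["Zn64"])

    def test_two_level_count_difference_recovers_slope(self, noiseless_instrument):
        c1, c2 = 5.0, 25.0
        spec = ph.StandardSpec(
            levels=[
                ph.StandardLevel(concentrations={"Cu": c1}),
                ph.StandardLevel(concentrations={"Cu": c2}),
            ]
        )
        stds = ph.simulate_standards(spec, noiseless_instrument, seed=1)
        means = []
        for std in stds:
            idx = std.scan.channel_index("Cu63")
            means.append(np.concatenate([l[:, idx] for l in std.scan.lines]).mean())
        slope = (means[1] - means[0]) / (c2 - c1)
        assert slope == pytest.approx(noiseless_instrument.sensitivity["Cu63"], rel=1e-12)

    def test_poisson_level_means_within_counting_error(self):
        inst = ph.InstrumentModel(noise_model="poisson")
        spec = ph.StandardSpec(
            levels=[
                ph.StandardLevel(concentrations={"Cu": 10.0}, n_lines=2),
                ph.StandardLevel(concentrations={"Cu": 40.0}, n_lines=2),
            ],
            cycles_per_line=100,
        )
        stds = ph.simulate_standards(spec, inst, seed=5)
        for std, conc in zip(stds, (10.0, 40.0)):
            expected = inst.sensitivity["Cu63"] * conc + inst.background["Cu63"]
            idx = std.scan.channel_index("Cu63")
            values = np.concatenate([l[:, idx] for l in std.scan.lines])
            tol = 4.0 * np.sqrt(expected) / np.sqrt(values.size)
            assert abs(values.mean() - expected) < tol


class TestSpotAverage:
    def test_uniform_profile_is_invariant(self):
        profile = np.full((3, 30), 7.5)
        out = ph.spot_average(profile, spot_diameter=60.0, pixel_size_x=23.87)
        assert np.allclose(out, 7.5, rtol=1e-12)

    def test_step_edge_mass_is_conserved(self):
        # boxcar smearing redistributes but conserves the integral
        profile = np.zeros((1, 40))
        profile[0, 10:20] = 3.0
        out = ph.spot_average(profile, spot_diameter=60.0, pixel_size_x=23.87)
        assert out.sum() == pytest.approx(profile.sum(), rel=1e-9)
        assert out.max() <= 3.0 + 1e-12
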