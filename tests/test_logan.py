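"""Logan graphical VT, acquisition windows, voxel maps, time stability."""

import numpy as np
import pytest
from dataclasses import replace

from petquant import (
    AcquisitionWindow,
    CompartmentParams,
    LoganVT,
    TimeActivityCurve,
    ValidationError,
    apply_window,
    fit_logan,
    logan_transform,
    logan_vt,
    simulate_tissue,
    time_stability_table,
    voxelwise_logan,
)
from petquant.logan import LoganPoints
from petquant.simulate import (
    DEFAULT_KINETICS,
    REFERENCE_2TCM,
    generate_phantom,
    generate_test_retest,
    params_for_vt,
)

from conftest import SEED


class TestTransform:
    def test_equilibrium_identity(self, schedule):
        # constant tissue 5 and (near-)constant parent plasma 1: y = 5 x
        from test_kinetics import near_constant_input

        tac = TimeActivityCurve(schedule, np.full(schedule.n_frames, 5.0))
        pts = logan_transform(tac, near_constant_input(1.0))
        fit = fit_logan(pts, t_star=40.0)
        assert fit.vt == pytest.approx(5.0, rel=1e-6)
        # intercept offset bounded by the (0,0)-anchor ramp of the tissue
        # integral (half the first midpoint, in minutes)
        assert abs(fit.intercept) <= 0.15

    def test_noiseless_1tcm_slope_approaches_k1_over_k2(self, input_truth, schedule):
        tac = simulate_tissue(CompartmentParams("1tcm", 0.3, 0.1, vb=0.0), input_truth, schedule)
        fit = logan_vt(tac, input_truth, t_star=40.0)
        assert fit.vt == pytest.approx(3.0, rel=0.01)

    def test_all_negative_tac_rejected(self, input_truth, schedule):
        from petquant import DegenerateInputError

        tac = TimeActivityCurve(schedule, -np.ones(schedule.n_frames))
        with pytest.raises(DegenerateInputError):
            logan_transform(tac, input_truth)

    def test_slope_invariant_under_common_scaling(self, input_truth, schedule):
        params = replace(REFERENCE_2TCM, vb=0.0)
        tac = simulate_tissue(params, input_truth, schedule)
        fit = logan_vt(tac, input_truth, 40.0)
        from petquant.input_function import TriExpCurve

        c = 4.0
        scaled_inp = replace(
            input_truth,
            plasma=TriExpCurve(
                input_truth.plasma.peak_time,
                input_truth.plasma.amplitudes * c,
                input_truth.plasma.rates,
            ),
        )
        scaled_tac = TimeActivityCurve(schedule, tac.activity * c)
        fit2 = logan_vt(scaled_tac, scaled_inp, 40.0)
        assert fit2.vt == pytest.approx(fit.vt, rel=1e-10)


class TestFit:
    def test_exact_line(self):
        x = np.linspace(1, 10, 8)
        pts = LoganPoints(x=x, y=40.0 * x - 5.0, t_mid_s=np.linspace(2500, 7000, 8))
        fit = fit_logan(pts, t_star=40.0)
        assert fit.vt == pytest.approx(40.0, rel=1e-12)
        assert fit.intercept == pytest.approx(-5.0, rel=1e-10)
        assert fit.r_squared == pytest.approx(1.0)

    def test_noiseless_2tcm_within_2pct_of_true_vt(self, input_truth, schedule):
        tac = simulate_tissue(replace(REFERENCE_2TCM, vb=0.0), input_truth, schedule)
        fit = logan_vt(tac, input_truth, t_star=40.0)
        assert fit.vt == pytest.approx(7.0, rel=0.02)
        assert fit.vt <= 7.0  # graphical estimate approaches VT from below

    def test_underestimation_shrinks_with_t_star(self, input_truth, schedule):
        tac = simulate_tissue(replace(REFERENCE_2TCM, vb=0.0), input_truth, schedule)
        errs = [7.0 - logan_vt(tac, input_truth, ts).vt for ts in (40.0, 60.0, 80.0)]
        assert errs[0] >= errs[1] >= errs[2] >= 0

    def test_t_star_beyond_last_frame(self, input_truth, schedule):
        tac = simulate_tissue(REFERENCE_2TCM, input_truth, schedule)
        with pytest.raises(ValidationError):
            logan_vt(tac, input_truth, t_star=130.0)

    def test_estimator_interface(self, input_truth, schedule):
        tac = simulate_tissue(replace(REFERENCE_2TCM, vb=0.0), input_truth, schedule)
        est = LoganVT(t_star=40.0).fit(tac, input_truth)
        assert est.vt_ == pytest.approx(logan_vt(tac, input_truth, 40.0).vt)
        assert est.get_params() == {"t_star": 40.0}


class TestWindows:
    def test_full_window_is_identity(self, input_truth, schedule):
        tac = simulate_tissue(REFERENCE_2TCM, input_truth, schedule)
        out = apply_window(tac, AcquisitionWindow(((0.0, 120.0),)))
        np.testing.assert_array_equal(out.activity, tac.activity)

    def test_coffee_break_frame_count_from_schedule_arithmetic(self, schedule):
        # 6x15s+3x30s+3x60s+2x90s+2x180s+9x300s end exactly at 3600 s (25
        # frames); of the six 600-s frames, the last three lie in 90-120 min.
        tac = TimeActivityCurve(schedule, np.ones(schedule.n_frames))
        out = apply_window(tac, AcquisitionWindow.parse("0-60,90-120"))
        assert out.schedule.n_frames == 28
        assert out.schedule.start[25] == pytest.approx(5400.0)

    def test_truncation_biases_logan_low_noiselessly(self, input_truth, schedule):
        tac = simulate_tissue(replace(DEFAULT_KINETICS, vb=0.0), input_truth, schedule)
        vt_full = logan_vt(tac, input_truth, 40.0).vt
        vt_60 = logan_vt(
            apply_window(tac, AcquisitionWindow.parse("0-60")), input_truth, 40.0
        ).vt
        assert vt_60 < vt_full

    def test_coffee_break_within_1pct_of_full(self, input_truth, schedule):
        for vt_true in (26.9, 37.5, 50.4):
            tac = simulate_tissue(params_for_vt(vt_true), input_truth, schedule)
            vt_full = logan_vt(tac, input_truth, 40.0).vt
            vt_cb = logan_vt(
                apply_window(tac, AcquisitionWindow.parse("0-60,90-120")),
                input_truth,
                40.0,
            ).vt
            assert vt_cb == pytest.approx(vt_full, rel=0.01)

    def test_empty_window_rejected(self, input_truth, schedule):
        tac = simulate_tissue(REFERENCE_2TCM, input_truth, schedule)
        with pytest.raises(ValidationError):
            apply_window(tac, AcquisitionWindow(((130.0, 140.0),)))

    def test_window_parsing_and_validation(self):
        win = AcquisitionWindow.parse("0-60,90-120")
        assert win.segments == ((0.0, 60.0), (90.0, 120.0))
        assert win.label == "0-60/90-120"
        with pytest.raises(ValidationError):
            AcquisitionWindow(((0.0, 60.0), (50.0, 120.0)))


class TestVoxelwise:
    def test_noiseless_phantom_matches_region_vts(self, input_truth):
        phantom = generate_phantom(seed=SEED)
        vt_map, nan_frac = voxelwise_logan(phantom.volume, input_truth, 40.0)
        assert nan_frac == 0.0
        for label, name in phantom.region_map.items():
            region_vals = vt_map[phantom.labels == label]
            true_vt = phantom.truth[name].vt
            # single value per homogeneous region, within 2% of truth up to
            # the blood-volume scaling of the measured TAC
            expected = logan_vt(
                simulate_tissue(
                    phantom.truth[name].params, input_truth, phantom.volume.schedule
                ),
                input_truth,
                40.0,
            ).vt
            np.testing.assert_allclose(region_vals, expected, rtol=1e-10)
            assert abs(region_vals.mean() - true_vt) / true_vt < 0.07

    def test_all_zero_volume_gives_all_nan(self, input_truth, schedule):
        from petquant import DynamicVolume

        vol = DynamicVolume(np.zeros((3, 3, 3, schedule.n_frames)), schedule)
        vt_map, nan_frac = voxelwise_logan(vol, input_truth, 40.0)
        assert nan_frac == 1.0
        assert np.all(np.isnan(vt_map))

    def test_regional_mean_consistent_with_regional_tac_logan(self, input_truth):
        from petquant import extract_regional_tacs

        phantom = generate_phantom(seed=SEED)
        vt_map, _ = voxelwise_logan(phantom.volume, input_truth, 40.0)
        tacs, _ = extract_regional_tacs(phantom.volume, phantom.labels, phantom.region_map)
        for label, name in phantom.region_map.items():
            regional = logan_vt(tacs[name], input_truth, 40.0).vt
            assert np.nanmean(vt_map[phantom.labels == label]) == pytest.approx(
                regional, rel=0.01
            )


class TestTimeStability:
    @pytest.fixture(scope="class")
    def rendered_study(self):
        regions = ["composite_cortical", "temporal_cortex", "brainstem"]
        return generate_test_retest(seed=SEED, regions=regions, noise_level=0.05)

    def _sets(self, study):
        trt = [
            {
                "test": (rec["test"].tacs, rec["test"].input_function),
                "retest": (rec["retest"].tacs, rec["retest"].input_function),
            }
            for rec in study.scans
        ]
        cohort = [(rec["test"].tacs, rec["test"].input_function) for rec in study.scans]
        return trt, cohort

    def test_identical_test_retest_gives_zero_trv(self, rendered_study):
        trt, cohort = self._sets(rendered_study)
        same = [{"test": p["test"], "retest": p["test"]} for p in trt]
        table = time_stability_table(
            same, cohort, [AcquisitionWindow.parse("0-120")]
        )
        assert table.loc["0-120", "trv_mean"] == pytest.approx(0.0, abs=1e-10)

    def test_full_window_row_has_no_bias(self, rendered_study):
        trt, cohort = self._sets(rendered_study)
        table = time_stability_table(
            trt, cohort, [AcquisitionWindow.parse("0-120"), AcquisitionWindow.parse("0-90")]
        )
        assert np.isnan(table.loc["0-120", "bias_mean"])
        assert np.isfinite(table.loc["0-90", "bias_mean"])

    def test_coffee_break_more_stable_than_60min_truncation(self, rendered_study):
        trt, cohort = self._sets(rendered_study)
        table = time_stability_table(
            trt,
            cohort,
            [AcquisitionWindow.parse("0-60,90-120"), AcquisitionWindow.parse("0-60")],
        )
        cb, w60 = table.loc["0-60/90-120"], table.loc["0-60"]
        assert abs(cb["bias_mean"]) < abs(w60["bias_mean"])
        assert cb["trv_sd"] < w60["trv_sd"]
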