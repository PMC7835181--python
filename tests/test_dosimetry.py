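"""Organ curve fits, cumulated activities, ICRP-30 GI chain, dose assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad

from petquant import (
    F18_HALF_LIFE_MIN,
    FrameSchedule,
    GIModelParams,
    ICRP60_WEIGHTS,
    NCARecord,
    OrganCurveModel,
    StateError,
    TimeActivityCurve,
    ValidationError,
    effective_dose,
    fit_organ_curve,
    gi_tract_nca,
    nca_analytic,
    nca_trapezoid,
    organ_doses_from_nca,
    remainder_tac,
)
from petquant.dosimetry import LN2
from petquant.simulate import wb_schedule

DECAY_BOUND_H = F18_HALF_LIFE_MIN / 60.0 / LN2  # total-decay NCA bound


def physical_tac(schedule, values):
    return TimeActivityCurve(
        schedule, values, decay_corrected=False, units="fraction_injected"
    )


class TestOrganCurveFit:
    def test_biexp_noiseless_round_trip(self):
        truth = OrganCurveModel("biexp", 0.05, 0.02, tau_e1=0.5, tau_e2=3.0)
        sched = wb_schedule()
        tac = physical_tac(sched, truth.value(sched.midpoints / 3600.0))
        fit = fit_organ_curve(tac, "biexp")
        # components are unordered; match by half-time
        got = sorted([(fit.tau_e1, fit.a1), (fit.tau_e2, fit.a2)])
        want = sorted([(0.5, 0.05), (3.0, 0.02)])
        np.testing.assert_allclose(got, want, rtol=1e-6)

    def test_uptake_washout_round_trip(self):
        truth = OrganCurveModel(
            "uptake_washout", 0.07, 0.005, tau_u1=0.1, tau_e1=1.7, tau_e2=1.0
        )
        sched = wb_schedule()
        tac = physical_tac(sched, truth.value(sched.midpoints / 3600.0))
        fit = fit_organ_curve(tac, "uptake_washout")
        assert nca_analytic(fit).nca == pytest.approx(nca_analytic(truth).nca, rel=1e-6)

    def test_uptake_washout_with_instant_uptake_reduces_to_biexp(self):
        m = OrganCurveModel(
            "uptake_washout", 0.05, 0.02, tau_u1=1e-9, tau_e1=0.5, tau_e2=3.0
        )
        b = OrganCurveModel("biexp", 0.05, 0.02, tau_e1=0.5, tau_e2=3.0)
        t = np.linspace(0.01, 5, 50)
        np.testing.assert_allclose(m.value(t), b.value(t), rtol=1e-7)

    def test_negative_activity_rejected(self):
        sched = wb_schedule()
        vals = np.linspace(0.1, -0.01, sched.n_frames)
        with pytest.raises(ValidationError):
            fit_organ_curve(physical_tac(sched, vals), "biexp")

    def test_decay_corrected_input_rejected(self):
        sched = wb_schedule()
        tac = TimeActivityCurve(sched, np.ones(sched.n_frames), decay_corrected=True)
        with pytest.raises(StateError):
            fit_organ_curve(tac, "biexp")


class TestAnalyticNCA:
    def test_single_exponential_closed_form(self):
        # A tau / ln2 with tau equal to the F-18 half-life in hours
        m = OrganCurveModel("biexp", 0.1, 0.0, tau_e1=1.82952, tau_e2=1.0)
        assert nca_analytic(m).nca == pytest.approx(0.1 * 1.82952 / LN2, rel=1e-12)
        assert nca_analytic(m).nca == pytest.approx(0.26395, abs=5e-5)

    def test_zero_amplitudes_zero_nca(self):
        m = OrganCurveModel("biexp", 0.0, 0.0, tau_e1=1.0, tau_e2=2.0)
        assert nca_analytic(m).nca == 0.0

    def test_plateau_with_positive_a1_diverges(self):
        m = OrganCurveModel("uptake_plateau", 0.1, 0.0, tau_u1=0.5, tau_e2=1.0)
        with pytest.raises(ValidationError):
            nca_analytic(m)

    @given(
        st.floats(min_value=1e-4, max_value=0.3),
        st.floats(min_value=1e-4, max_value=0.3),
        st.floats(min_value=0.05, max_value=2.5),
        st.floats(min_value=0.02, max_value=1.5),
        st.floats(min_value=0.02, max_value=0.8),
    )
    def test_matches_quadrature_over_random_models(self, a1, a2, te1, te2, tu):
        for form in ("biexp", "uptake_washout"):
            kwargs = {"tau_e1": te1, "tau_e2": te2}
            if form == "uptake_washout":
                kwargs["tau_u1"] = tu
            m = OrganCurveModel(form, a1, a2, **kwargs)
            num, _ = quad(m.value, 0.0, np.inf, limit=600)
            assert nca_analytic(m).nca == pytest.approx(num, rel=5e-3)


class TestTrapezoidNCA:
    def test_pure_decay_close_to_decay_bound(self):
        edges = np.linspace(0.0, 10 * 3600.0, 400)
        sched = FrameSchedule(edges[:-1], edges[1:])
        t_h = sched.midpoints / 3600.0
        tac = physical_tac(sched, np.exp(-LN2 * t_h / (F18_HALF_LIFE_MIN / 60.0)))
        assert nca_trapezoid(tac).nca == pytest.approx(DECAY_BOUND_H, rel=0.01)

    def test_zero_tac(self):
        sched = wb_schedule()
        assert nca_trapezoid(physical_tac(sched, np.zeros(sched.n_frames))).nca == 0.0

    def test_close_to_analytic_at_study_sampling(self):
        # slow component at the physical half-life, so the physical-decay
        # tail assumption is exact and only sampling error remains
        m = OrganCurveModel(
            "biexp", 0.02, 0.01, tau_e1=F18_HALF_LIFE_MIN / 60.0, tau_e2=0.3
        )
        sched = wb_schedule()  # 13 points to 270 min
        tac = physical_tac(sched, m.value(sched.midpoints / 3600.0))
        assert nca_trapezoid(tac).nca == pytest.approx(nca_analytic(m).nca, rel=0.02)

    def test_decay_corrected_input_rejected(self):
        sched = wb_schedule()
        tac = TimeActivityCurve(sched, np.ones(sched.n_frames))
        with pytest.raises(StateError):
            nca_trapezoid(tac)


class TestGIModel:
    def test_mean_fraction_reproduces_small_intestine_row(self):
        out = gi_tract_nca(0.6175)
        assert out["small_intestine"].nca == pytest.approx(0.982, abs=5e-4)

    def test_lowest_fraction_subject(self):
        assert gi_tract_nca(0.49)["small_intestine"].nca == pytest.approx(0.779, abs=5e-4)

    def test_zero_fraction_all_zero(self):
        out = gi_tract_nca(0.0)
        assert all(rec.nca == 0.0 for rec in out.values())

    def test_linear_in_f_si(self):
        a = gi_tract_nca(0.2)
        b = gi_tract_nca(0.6)
        for organ in a:
            assert b[organ].nca == pytest.approx(3.0 * a[organ].nca, rel=1e-12)

    def test_chain_ordering_and_decay_bound(self):
        out = gi_tract_nca(1.0)
        si, uli, lli = (
            out["small_intestine"].nca,
            out["upper_large_intestine"].nca,
            out["lower_large_intestine"].nca,
        )
        assert si > uli > lli > 0
        assert si <= DECAY_BOUND_H

    def test_fast_decay_sends_ncas_to_zero(self):
        slow = gi_tract_nca(GIModelParams(0.6, half_life_min=F18_HALF_LIFE_MIN))
        fast = gi_tract_nca(GIModelParams(0.6, half_life_min=1.0))
        for organ in slow:
            assert fast[organ].nca < slow[organ].nca

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValidationError):
            gi_tract_nca(1.2)


class TestRemainderAndDoses:
    def test_conservation(self):
        sched = wb_schedule()
        total = physical_tac(sched, np.full(sched.n_frames, 1.0))
        a = physical_tac(sched, np.full(sched.n_frames, 0.3))
        b = physical_tac(sched, np.full(sched.n_frames, 0.7))
        rem = remainder_tac(total, {"a": a, "b": b})
        np.testing.assert_allclose(rem.activity, 0.0, atol=1e-15)

    def test_single_source(self):
        sched = wb_schedule()
        total = physical_tac(sched, np.ones(sched.n_frames))
        rem = remainder_tac(total, {"a": physical_tac(sched, np.full(sched.n_frames, 0.3))})
        np.testing.assert_allclose(rem.activity, 0.7)

    def test_negative_residual_floored_with_warning(self):
        sched = wb_schedule()
        total = physical_tac(sched, np.full(sched.n_frames, 0.2))
        src = physical_tac(sched, np.full(sched.n_frames, 0.3))
        with pytest.warns(UserWarning):
            rem = remainder_tac(total, {"a": src})
        assert np.all(rem.activity == 0.0)

    def test_weights_sum_to_one_and_uniform_dose(self):
        assert sum(ICRP60_WEIGHTS.values()) == pytest.approx(1.0)
        doses = {tissue: 10.0 for tissue in ICRP60_WEIGHTS}
        assert effective_dose(doses) == pytest.approx(10.0)
        assert effective_dose({t: 0.0 for t in ICRP60_WEIGHTS}) == 0.0

    def test_effective_dose_linearity_and_gaps(self):
        doses = {tissue: 5.0 + i for i, tissue in enumerate(ICRP60_WEIGHTS)}
        assert effective_dose({k: 2 * v for k, v in doses.items()}) == pytest.approx(
            2 * effective_dose(doses)
        )
        with pytest.raises(ValidationError):
            effective_dose({"liver": 3.0})
        # remainder fallback fills gaps
        assert effective_dose({"remainder": 4.0}) == pytest.approx(4.0)

    def test_s_matrix_contraction_hand_product(self):
        s = pd.DataFrame(
            {"src1": [1.0, 0.5], "src2": [2.0, 0.25]}, index=["t1", "t2"]
        )
        ncas = {"src1": NCARecord("src1", 0.4, "analytic"), "src2": 0.1}
        doses = organ_doses_from_nca(ncas, s)
        assert doses["t1"] == pytest.approx(0.4 * 1.0 + 0.1 * 2.0)
        assert doses["t2"] == pytest.approx(0.4 * 0.5 + 0.1 * 0.25)

    def test_identity_s_matrix_returns_ncas(self):
        s = pd.DataFrame(np.eye(2), index=["a", "b"], columns=["a", "b"])
        doses = organ_doses_from_nca({"a": 0.3, "b": 0.7}, s)
        assert doses["a"] == pytest.approx(0.3) and doses["b"] == pytest.approx(0.7)

    def test_missing_source_column(self):
        s = pd.DataFrame({"a": [1.0]}, index=["t"])
        with pytest.raises(ValidationError):
            organ_doses_from_nca({"a": 0.1, "zz": 0.2}, s)
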