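"""Two-compartment infusion kinetics: closed form vs independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

from tigepk.pk_core import (
    DoseEvent,
    Regimen,
    StructuralParams,
    auc_ss_24h,
    cmin_ss,
    cmin_ss_closed_form,
    concentration,
)


def ode_concentration(times, doses, p, rtol=1e-11):
    """Stiff-ODE oracle for the two-compartment infusion model."""

    def rhs(t, x):
        rate = sum(
            d.amount / d.infusion_duration
            for d in doses
            if d.start_time <= t < d.start_time + d.infusion_duration
        )
        k10, k12, k21 = p.cl / p.vc, p.q / p.vc, p.q / p.vp
        return [rate - (k10 + k12) * x[0] + k21 * x[1], k12 * x[0] - k21 * x[1]]

    sol = integrate.solve_ivp(rhs, (0.0, float(np.max(times))), [0.0, 0.0],
                              t_eval=np.sort(times), rtol=rtol, atol=1e-13,
                              max_step=0.25, method="LSODA")
    return sol.y[0] / p.vc


class TestConcentration:
    def test_zero_before_first_dose(self, params):
        doses = [DoseEvent(5.0, 100.0)]
        assert concentration(2.0, doses, params) == 0.0
        assert concentration(0.0, doses, params) == 0.0

    def test_one_compartment_limit_end_of_infusion(self):
        """With Q -> 0 the end-of-infusion value equals the one-compartment
        closed form (Rate/CL)(1 - exp(-k10 * T))."""
        p = StructuralParams(cl=8.6, vc=80.0, q=1e-9, vp=250.0)
        c = concentration(0.5, [DoseEvent(0.0, 100.0, 0.5)], p)
        rate, k10 = 100.0 / 0.5, p.cl / p.vc
        expected = (rate / p.cl) * (1.0 - np.exp(-k10 * 0.5))
        assert c == pytest.approx(expected, rel=1e-6)

    @pytest.mark.parametrize("p", [
        StructuralParams(8.6, 80.0, 60.0, 250.0),
        StructuralParams(22.1, 150.0, 80.0, 400.0),
        StructuralParams(2.0, 20.0, 1.5, 500.0),
    ])
    def test_matches_ode_oracle_multidose(self, p):
        doses = Regimen().doses(5)
        times = np.linspace(0.1, 55.0, 37)
        ana = concentration(times, doses, p)
        ode = ode_concentration(times, doses, p)
        assert np.max(np.abs(ana - ode) / ode) < 1e-6

    @settings(max_examples=15, deadline=None)
    @given(
        cl=st.floats(1.0, 40.0), vc=st.floats(20.0, 300.0),
        q=st.floats(0.5, 150.0), vp=st.floats(50.0, 800.0),
    )
    def test_property_sampled_params_match_ode(self, cl, vc, q, vp):
        p = StructuralParams(cl, vc, q, vp)
        doses = [DoseEvent(0.0, 100.0, 0.5), DoseEvent(12.0, 50.0, 0.5)]
        times = np.array([0.4, 1.0, 6.0, 12.4, 20.0])
        ana = concentration(times, doses, p)
        ode = ode_concentration(times, doses, p)
        assert np.max(np.abs(ana - ode) / ode) < 1e-6

    def test_superposition_and_dose_proportionality(self, params):
        d1, d2 = DoseEvent(0.0, 100.0), DoseEvent(12.0, 50.0)
        t = np.linspace(0.2, 40.0, 23)
        both = concentration(t, [d1, d2], params)
        split = concentration(t, [d1], params) + concentration(t, [d2], params)
        np.testing.assert_allclose(both, split, rtol=0, atol=1e-10)
        scaled = concentration(
            t, [DoseEvent(0.0, 300.0), DoseEvent(12.0, 150.0)], params)
        np.testing.assert_allclose(scaled, 3.0 * both, rtol=1e-12)

    @settings(max_examples=25, deadline=None)
    @given(
        cl=st.floats(1.0, 40.0), vc=st.floats(20.0, 300.0),
        q=st.floats(0.5, 150.0), vp=st.floats(50.0, 800.0),
    )
    def test_single_dose_auc_is_dose_over_cl(self, cl, vc, q, vp):
        """AUC from 0 to infinity of a single dose equals D/CL (adaptive
        quadrature against the closed form)."""
        p = StructuralParams(cl, vc, q, vp)
        dose = [DoseEvent(0.0, 100.0, 0.5)]
        f = lambda t: concentration(t, dose, p)
        head, _ = integrate.quad(f, 0.0, 200.0, points=[0.5, 5.0, 50.0], limit=400)
        tail, _ = integrate.quad(f, 200.0, np.inf, limit=400)
        assert head + tail == pytest.approx(100.0 / cl, rel=5e-4)

    def test_rejects_negative_time_and_bad_params(self, params):
        with pytest.raises(ValueError):
            concentration(-1.0, [DoseEvent(0.0, 100.0)], params)
        with pytest.raises(ValueError):
            StructuralParams(cl=-1.0, vc=80.0, q=60.0, vp=250.0)
        with pytest.raises(ValueError):
            StructuralParams(cl=np.inf, vc=80.0, q=60.0, vp=250.0)
        with pytest.raises(ValueError):
            DoseEvent(-1.0, 100.0)


class TestSteadyStateExposure:
    def test_auc_analytic_values(self, params, standard_regimen):
        assert auc_ss_24h(params, standard_regimen) == pytest.approx(100.0 / 8.6, rel=1e-12)
        p10 = StructuralParams(10.0, 80.0, 60.0, 250.0)
        high = Regimen(loading_dose=100.0, maintenance_dose=100.0)
        assert auc_ss_24h(p10, high) == pytest.approx(20.0, rel=1e-12)

    def test_numeric_auc_matches_analytic(self, standard_regimen):
        rng = np.random.default_rng(7)
        for _ in range(50):
            p = StructuralParams(*np.exp(rng.uniform(
                np.log([2, 30, 5, 80]), np.log([30, 200, 120, 600]))))
            ana = auc_ss_24h(p, standard_regimen)
            num = auc_ss_24h(p, standard_regimen, method="numeric")
            assert abs(num - ana) / ana < 5e-3

    def test_cmin_one_compartment_geometric_series(self):
        """In the Q -> 0 limit the trough equals the one-compartment
        geometric-series steady state of repeated infusions."""
        p = StructuralParams(cl=8.6, vc=80.0, q=1e-10, vp=250.0)
        reg = Regimen(loading_dose=50.0, maintenance_dose=50.0)
        k, tau, tinf = p.cl / p.vc, reg.interval, reg.infusion_duration
        rate = reg.maintenance_dose / tinf
        c_end_unit = (rate / p.cl) * (1 - np.exp(-k * tinf))
        expected = c_end_unit * np.exp(-k * (tau - tinf)) / (1 - np.exp(-k * tau))
        assert cmin_ss(p, reg) == pytest.approx(expected, rel=2e-3)

    def test_cmin_increases_when_cl_halves(self, params, standard_regimen):
        half = StructuralParams(params.cl / 2, params.vc, params.q, params.vp)
        assert cmin_ss(half, standard_regimen) > cmin_ss(params, standard_regimen)

    def test_cmin_zero_maintenance_washes_out(self, params):
        reg = Regimen(loading_dose=100.0, maintenance_dose=0.0)
        assert cmin_ss(params, reg) == 0.0

    def test_closed_form_trough_matches_operational(self, params, standard_regimen):
        op = cmin_ss(params, standard_regimen)
        cf = cmin_ss_closed_form(params.cl, params.vc, params.q, params.vp,
                                 standard_regimen.maintenance_dose)
        assert cf == pytest.approx(op, rel=5e-3)

    def test_auc_rejects_unknown_method(self, params, standard_regimen):
        with pytest.raises(ValueError):
            auc_ss_24h(params, standard_regimen, method="magic")

    def test_regimen_expansion_is_deterministic(self, standard_regimen):
        doses = standard_regimen.doses(4)
        assert [d.start_time for d in doses] == [0.0, 12.0, 24.0, 36.0]
        assert [d.amount for d in doses] == [100.0, 50.0, 50.0, 50.0]
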