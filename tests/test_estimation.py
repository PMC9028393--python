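"""Marginal-likelihood machinery: OFV vs quadrature, EBEs, shrinkage, LRT, fits."""

import numpy as np
import pytest
from scipy import stats

from tigepk.estimation import (
    StudyDataset,
    Subject,
    _InnerProblem,
    _Packed,
    ebe,
    fit,
    lrt,
    ofv,
    shrinkage,
)
from tigepk.pk_core import DoseEvent, Regimen, StructuralParams, concentration
from tigepk.popmodel import ModelSpec, PopulationParams

from conftest import ONE_ETA_FIX, make_one_eta_spec, simulate_one_eta_dataset


def gauss_hermite_ofv(dataset, spec, n_nodes=64):
    """Independent adaptive Gauss-Hermite oracle for diagonal-omega models.

    Integrates the (2*pi-free) conditional likelihood against the normal
    random-effect density on a tensor grid centred at the conditional mode
    and scaled by the curvature there; returns the total OFV.
    """
    packed = _Packed(dataset)
    prob = _InnerProblem(packed, spec)
    modes, _ = prob.solve_modes()
    hess = prob.hess(modes) * 0.5
    x, w = np.polynomial.hermite.hermgauss(n_nodes)
    om = spec.population.omega2_vector()[prob.support]
    total = 0.0
    for i, sub in enumerate(dataset.subjects):
        k = prob.support.size
        scales = 1.0 / np.sqrt(np.diag(hess[i]))
        grids = [modes[i, j] + np.sqrt(2.0) * scales[j] * x for j in range(k)]
        mesh = np.meshgrid(*grids, indexing="ij")
        wmesh = np.ones_like(mesh[0])
        for j in range(k):
            shape = [1] * k
            shape[j] = n_nodes
            wmesh = wmesh * (w * np.exp(x**2)).reshape(shape)
        integrand = np.zeros_like(mesh[0])
        it = np.nditer(mesh[0], flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            eta = np.zeros(3)
            eta[prob.support] = [m[idx] for m in mesh]
            p = StructuralParams(
                prob.cl_tv[i] * np.exp(eta[0]), prob.vc_tv[i] * np.exp(eta[1]),
                prob.q, prob.vp_tv[i] * np.exp(eta[2]))
            f = concentration(sub.times, list(sub.doses), p)
            v = prob.sig2p * f**2 + prob.sig2a
            r = sub.dv - f
            q_lik = np.exp(-0.5 * np.sum(np.log(v) + r * r / v))
            prior = np.prod(stats.norm.pdf(eta[prob.support], 0.0, np.sqrt(om)))
            integrand[idx] = q_lik * prior
        integral = np.sum(wmesh * integrand) * np.prod(np.sqrt(2.0) * scales)
        total += -2.0 * np.log(integral)
    return total


def _toy_dataset(rng, n_subjects, spec, n_eta, times=(36.3, 38.0, 41.0, 47.5)):
    """Simulate a small dataset with random effects on the first n_eta of
    (cl, vc, vp)."""
    reg = Regimen()
    times = np.asarray(times)
    doses = reg.doses(int(times.max() // reg.interval) + 1)
    pop = spec.population
    om = np.sqrt(pop.omega2_vector())
    subs = []
    for i in range(n_subjects):
        eta = rng.standard_normal(3) * om
        p = StructuralParams(pop.theta.cl * np.exp(eta[0]),
                             pop.theta.vc * np.exp(eta[1]),
                             pop.theta.q, pop.theta.vp * np.exp(eta[2]))
        f = concentration(times, doses, p)
        y = np.abs(f * (1.0 + pop.sigma_prop * rng.standard_normal(times.size)))
        subs.append(Subject(id=f"S{i}", doses=doses, times=times, dv=y))
    return StudyDataset(subs)


class TestOfv:
    def test_perfect_additive_prediction_contributes_zero(self, params):
        """One observation matching the model exactly, additive error SD 1,
        no IIV: the subject contributes log(1) + 0 = 0."""
        doses = Regimen().doses(2)
        t = np.array([14.0])
        f = concentration(t, doses, params)
        spec = ModelSpec(
            population=PopulationParams(theta=params, omega2={}, sigma_prop=0.0,
                                        sigma_add=1.0),
            error_model="additive")
        ds = StudyDataset([Subject(id="a", doses=doses, times=t, dv=f)])
        assert ofv(ds, spec) == pytest.approx(0.0, abs=1e-10)

    def test_matches_quadrature_oracle_one_eta(self):
        rng = np.random.default_rng(3)
        spec = make_one_eta_spec()
        ds = _toy_dataset(rng, 3, spec, 1)
        assert ofv(ds, spec) == pytest.approx(gauss_hermite_ofv(ds, spec), abs=0.1)

    def test_matches_quadrature_oracle_two_eta(self):
        rng = np.random.default_rng(4)
        spec = ModelSpec(population=PopulationParams(
            theta=StructuralParams(8.6, 80, 60, 250),
            omega2={"cl": 0.2, "vc": 0.4}, sigma_prop=0.124))
        times = tuple(36.0 + np.array(
            [0.3, 0.6, 1.0, 1.5, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0, 10.0, 11.5]))
        ds = _toy_dataset(rng, 3, spec, 2, times=times)
        assert ofv(ds, spec) == pytest.approx(gauss_hermite_ofv(ds, spec), abs=0.1)

    def test_zero_iiv_reduces_to_wls_deviance(self, params):
        rng = np.random.default_rng(5)
        spec = make_one_eta_spec(omega2_cl=0.0)
        spec = ModelSpec(population=PopulationParams(
            theta=params, omega2={}, sigma_prop=0.124))
        ds = _toy_dataset(rng, 4, spec, 0)
        manual = 0.0
        for s in ds.subjects:
            f = concentration(s.times, list(s.doses), params)
            v = (0.124 * f) ** 2
            manual += np.sum(np.log(v) + (s.dv - f) ** 2 / v)
        assert ofv(ds, spec) == pytest.approx(manual, rel=1e-10)


class TestEbeAndShrinkage:
    def test_no_observations_gives_prior_mode(self, params):
        sub = Subject(id="empty", doses=[DoseEvent(0.0, 100.0)],
                      times=np.array([]), dv=np.array([]))
        np.testing.assert_array_equal(ebe(sub, make_one_eta_spec()), np.zeros(3))

    def test_mode_matches_dense_grid_search(self):
        rng = np.random.default_rng(6)
        spec = make_one_eta_spec()
        ds = _toy_dataset(rng, 1, spec, 1)
        eta_hat = ebe(ds.subjects[0], spec)[0]
        packed = _Packed(ds)
        prob = _InnerProblem(packed, spec)
        grid = np.linspace(-2.0, 2.0, 4001)
        gvals = [prob.g(np.array([[e]]))[0] for e in grid]
        assert eta_hat == pytest.approx(grid[int(np.argmin(gvals))], abs=2e-3)

    def test_rich_subject_ebe_near_generating_eta(self):
        rng = np.random.default_rng(7)
        spec = make_one_eta_spec(sigma_prop=0.05)
        true_eta = 0.35
        reg = Regimen()
        times = 36.0 + np.linspace(0.3, 11.5, 12)
        doses = reg.doses(4)
        p = StructuralParams(8.6 * np.exp(true_eta), 80, 60, 250)
        f = concentration(times, doses, p)
        y = f * (1 + 0.05 * rng.standard_normal(12))
        sub = Subject(id="rich", doses=doses, times=times, dv=y)
        assert ebe(sub, spec)[0] == pytest.approx(true_eta, abs=0.08)

    def test_shrinkage_formula_instances(self):
        om2 = 0.25
        spread = np.array([1.0, -1.0, 0.5, -0.5])
        ebes = spread * np.sqrt(om2) / spread.std(ddof=1)
        assert shrinkage(ebes, om2) == pytest.approx(0.0, abs=1e-10)
        assert shrinkage(np.zeros(10), om2) == pytest.approx(100.0)
        # the sparse-data volume eta of the study: SD = 0.87 omega -> 13%
        assert shrinkage(ebes * 0.87, om2) == pytest.approx(13.0)

    def test_shrinkage_undefined_without_iiv(self):
        with pytest.raises(ValueError):
            shrinkage(np.array([0.1, -0.1]), 0.0)


class TestLrt:
    @pytest.mark.parametrize("dofv,expected", [
        (3.94, 0.047), (2.60, 0.107), (9.0, 0.003), (6.51, 0.011),
    ])
    def test_chi2_upper_tail_values(self, dofv, expected):
        """Forward-inclusion dOFV drops map to the published p-values."""
        assert round(lrt(dofv, 1), 3) == expected

    def test_zero_and_negative_dofv(self):
        assert lrt(0.0, 1) == 1.0
        assert lrt(-5.0, 3) == 1.0

    def test_strictly_decreasing_in_dofv(self):
        ps = [lrt(d, 1) for d in (0.5, 1.0, 2.0, 4.0, 8.0)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_rejects_bad_df(self):
        with pytest.raises(ValueError):
            lrt(3.0, 0)


class TestFit:
    def test_aic_identity_and_determinism(self):
        rng = np.random.default_rng(8)
        spec = make_one_eta_spec()
        ds = simulate_one_eta_dataset(spec, 20, rng)
        inits = dict(cl=12.0, omega2_cl=0.1, sigma_prop=0.2)
        fr1 = fit(ds, spec, inits=inits, fix=ONE_ETA_FIX)
        fr2 = fit(ds, spec, inits=inits, fix=ONE_ETA_FIX)
        assert fr1.aic == fr1.ofv + 2 * fr1.n_params
        assert fr1.ofv == fr2.ofv
        assert fr1.spec.population.theta.cl == fr2.spec.population.theta.cl

    def test_nested_models_ordered_by_ofv(self):
        rng = np.random.default_rng(9)
        spec = make_one_eta_spec()
        covs = [{"bilirubin_tot": float(b)} for b in
                np.exp(rng.normal(np.log(2.64), 0.9, 30))]
        ds = simulate_one_eta_dataset(spec, 30, rng, covariates=covs)
        reduced = fit(ds, spec, fix=ONE_ETA_FIX)
        from tigepk.popmodel import CovariateEffect
        from dataclasses import replace
        full_spec = replace(spec, effects=(
            CovariateEffect("cl", "bilirubin_tot", "power", 0.0, 2.64),))
        full = fit(ds, full_spec, fix=ONE_ETA_FIX)
        assert full.ofv <= reduced.ofv + 1e-3

    def test_no_iiv_data_estimates_omega_near_zero(self):
        rng = np.random.default_rng(10)
        truth = make_one_eta_spec(omega2_cl=0.0)
        ds = simulate_one_eta_dataset(truth, 25, rng)
        fitted = fit(ds, make_one_eta_spec(omega2_cl=0.04), fix=ONE_ETA_FIX)
        assert fitted.spec.population.omega2["cl"] < 5e-3
        assert fitted.spec.population.theta.cl == pytest.approx(8.6, rel=0.1)
        assert "cl" in fitted.at_boundary or fitted.spec.population.omega2["cl"] < 5e-3

    def test_simulation_estimation_round_trip(self):
        """Parameters simulated from a fitted model are re-recovered."""
        rng = np.random.default_rng(12)
        truth = make_one_eta_spec(cl=10.0, omega2_cl=0.15, sigma_prop=0.1)
        ds = simulate_one_eta_dataset(truth, 60, rng,
                                      times=np.linspace(36.3, 47.5, 8))
        first = fit(ds, truth, inits=dict(cl=15.0, omega2_cl=0.05,
                                          sigma_prop=0.2), fix=ONE_ETA_FIX)
        ds2 = simulate_one_eta_dataset(first.spec, 60, rng,
                                       times=np.linspace(36.3, 47.5, 8))
        second = fit(ds2, first.spec, fix=ONE_ETA_FIX)
        p1, p2 = first.spec.population, second.spec.population
        assert p2.theta.cl == pytest.approx(p1.theta.cl, rel=0.15)
        assert p2.sigma_prop == pytest.approx(p1.sigma_prop, rel=0.25)

    def test_nonfinite_subject_flagged_with_id(self, params):
        # observation far below any achievable prediction still fits; a
        # malformed dataset (zero DV) is rejected at construction instead
        with pytest.raises(ValueError, match="S0"):
            Subject(id="S0", doses=[DoseEvent(0.0, 100.0)],
                    times=np.array([1.0]), dv=np.array([0.0]))
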