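"""Monte Carlo dosing simulation, cutoff search and PTA analysis."""

import numpy as np
import pytest
from dataclasses import replace

from tigepk.cohort import CohortDesign, covariate_pool, generate_cohort
from tigepk.dosing import (
    REFERENCE_HIGH_DOSE_NON_ICU,
    DoseAdjustmentRule,
    PTACurve,
    ReferenceRange,
    evaluate_adjustment,
    find_cutoff,
    pta90_mic,
    pta_curve,
    simulate_cohort,
)
from tigepk.pk_core import Regimen, StructuralParams
from tigepk.popmodel import CovariateEffect, ModelSpec, PopulationParams, base_model, model_a

STANDARD = Regimen(loading_dose=100.0, maintenance_dose=50.0)
REDUCED = Regimen(loading_dose=100.0, maintenance_dose=25.0)


def _no_iiv_spec(effects=()):
    return ModelSpec(population=PopulationParams(
        theta=StructuralParams(8.6, 80, 60, 250), omega2={}, sigma_prop=0.124),
        effects=effects)


class TestSimulateCohort:
    def test_degenerate_no_iiv_single_covariate(self):
        spec = _no_iiv_spec(effects=(
            CovariateEffect("cl", "cps", "categorical", -0.501, "C"),))
        pool = [{"cps": "C"}]
        s = simulate_cohort(spec, pool, STANDARD, n=50, seed=0)
        np.testing.assert_allclose(s.auc, 100.0 / (8.6 * 0.499), rtol=1e-12)

    def test_median_auc_near_daily_dose_over_typical_cl(self):
        pool = covariate_pool(generate_cohort(CohortDesign(), seed=1))
        s = simulate_cohort(base_model(), pool, STANDARD, n=4000, seed=2)
        assert np.median(s.auc) == pytest.approx(100.0 / 8.6, rel=0.05)

    def test_cps_c_to_ab_median_ratio_is_inverse_of_reduction(self):
        """With only the Child-Pugh effect active, median exposure in class C
        is 1/0.499 times class A/B (same seed, identical etas)."""
        spec = replace(model_a(), effects=(
            CovariateEffect("cl", "cps", "categorical", -0.501, "C"),))
        s_c = simulate_cohort(spec, [{"cps": "C"}], STANDARD, n=500, seed=3)
        s_ab = simulate_cohort(spec, [{"cps": "A"}], STANDARD, n=500, seed=3)
        ratio = np.median(s_c.auc) / np.median(s_ab.auc)
        assert ratio == pytest.approx(1.0 / 0.499, rel=1e-9)

    def test_dose_proportionality_under_common_random_numbers(self):
        pool = covariate_pool(generate_cohort(CohortDesign(), seed=4))
        s50 = simulate_cohort(base_model(), pool, STANDARD, n=300, seed=5)
        s25 = simulate_cohort(base_model(), pool, REDUCED, n=300, seed=5)
        np.testing.assert_allclose(s25.auc, s50.auc / 2.0, rtol=1e-12)

    def test_empty_pool_and_bad_n(self):
        with pytest.raises(ValueError):
            simulate_cohort(base_model(), [], STANDARD, n=10, seed=0)
        with pytest.raises(ValueError):
            simulate_cohort(base_model(), [{}], STANDARD, n=0, seed=0)

    def test_missing_rule_covariate_named(self):
        rule = DoseAdjustmentRule("meld", 30.0, "ge")
        with pytest.raises(KeyError, match="meld"):
            simulate_cohort(base_model(), [{"weight": 80.0}], rule, n=5, seed=0)


class TestEvaluateAdjustment:
    def test_rule_that_never_triggers_equals_plain_simulation(self):
        pool = covariate_pool(generate_cohort(CohortDesign(), seed=6))
        rule = DoseAdjustmentRule("bilirubin_tot", 1e9, "ge")
        rep = evaluate_adjustment(rule, base_model(), pool, n=400, seed=7)
        assert rep["n_triggered"] == 0
        np.testing.assert_allclose(rep["adjusted"].auc, rep["unadjusted"].auc)

    def test_cps_guided_adjustment_improves_reference_alignment(self):
        """Mirrors the study's central claim: reducing the maintenance dose
        for Child-Pugh C patients moves more of the population into the
        high-dose non-ICU reference exposure range."""
        pool = ([{"cps": "C", "weight": 80.0}] * 3
                + [{"cps": "A", "weight": 80.0}] * 6
                + [{"cps": "B", "weight": 80.0}] * 4)
        rule = DoseAdjustmentRule("cps", "C", "class-equals")
        rep = evaluate_adjustment(rule, model_a(), pool, n=3000, seed=8)
        assert (rep["fraction_in_reference_adjusted"]
                >= rep["fraction_in_reference_unadjusted"])
        trig = rep["groups"]["triggered"]
        untrig = rep["groups"]["triggered_without_adjustment"]
        assert trig["median"] == pytest.approx(untrig["median"] / 2.0, rel=1e-9)


class TestFindCutoff:
    def test_single_candidate_returned_with_scores(self):
        pool = covariate_pool(generate_cohort(CohortDesign(), seed=9))
        rule, table = find_cutoff("meld", [30.0], base_model(), pool, n=200, seed=10)
        assert rule.cutoff == 30.0 and len(table) == 1
        assert {"fraction_in_reference", "median_auc"} <= set(table.columns)

    def test_inert_covariate_prefers_no_adjustment(self):
        """When the covariate has no effect in the model, adjusting anyone
        only pushes exposure below the reference, so the plain simulation
        scores at least as well as any cutoff (up to Monte Carlo error)."""
        pool = covariate_pool(generate_cohort(CohortDesign(), seed=11))
        spec = base_model()
        plain = simulate_cohort(spec, pool, STANDARD, n=2000, seed=12,
                                reference=REFERENCE_HIGH_DOSE_NON_ICU)
        _, table = find_cutoff("meld", [10.0, 20.0, 30.0], spec, pool,
                               n=2000, seed=12)
        assert plain.fraction_in_reference >= table["fraction_in_reference"].max() - 2.0

    def test_recovers_exposure_doubling_cutoff(self):
        """Constructed scenario: CL proportional to 1/bilirubin, so exposure
        crosses the reference ceiling near bilirubin 4 mg/dL; the search
        should choose the cutoff at that point rather than far above/below."""
        spec = ModelSpec(population=PopulationParams(
            theta=StructuralParams(8.6, 80, 60, 250),
            omega2={"cl": 0.01}, sigma_prop=0.124),
            effects=(CovariateEffect("cl", "bilirubin_tot", "power", -1.0, 2.64),))
        rng = np.random.default_rng(13)
        pool = [{"bilirubin_tot": float(b)}
                for b in np.exp(rng.normal(np.log(2.64), 0.9, 200))]
        rule, table = find_cutoff("bilirubin_tot", [1.0, 2.0, 4.0, 8.0, 14.0],
                                  spec, pool, n=3000, seed=14)
        assert rule.cutoff == 4.0


class TestPta:
    def test_high_exposure_attains_target(self):
        curve = pta_curve([20.0] * 10, 6.96, [0.5])
        assert curve.pta == (1.0,)

    def test_extreme_mic_fails_target(self):
        curve = pta_curve([20.0] * 10, 6.96, [1e6])
        assert curve.pta == (0.0,)

    def test_monotone_non_increasing_over_grid(self):
        rng = np.random.default_rng(15)
        auc = np.exp(rng.normal(np.log(11.6), 0.45, 1000))
        curve = pta_curve(auc, 6.96)
        assert all(a >= b for a, b in zip(curve.pta, curve.pta[1:]))

    def test_pta90_mic_selection(self):
        curve = PTACurve(mic_grid=(0.25, 0.5, 1.0), pta=(0.95, 0.92, 0.60),
                         target_ratio=6.96)
        assert pta90_mic(curve) == 0.5
        low = PTACurve(mic_grid=(0.25, 0.5), pta=(0.6, 0.4), target_ratio=17.9)
        assert pta90_mic(low) is None

    def test_rejects_empty_and_nonpositive(self):
        with pytest.raises(ValueError):
            pta_curve([], 6.96)
        with pytest.raises(ValueError):
            pta_curve([10.0], 6.96, [0.0])


def test_reference_range_validation():
    with pytest.raises(ValueError):
        ReferenceRange(median=5.0, lower=6.0, upper=10.0)
    r = REFERENCE_HIGH_DOSE_NON_ICU
    assert r.lower < r.median < r.upper
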