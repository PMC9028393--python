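import numpy as np
import pytest

from tigepk.estimation import StudyDataset, Subject
from tigepk.pk_core import Regimen, StructuralParams
from tigepk.popmodel import ModelSpec, PopulationParams


@pytest.fixture
def params():
    """Typical ICU liver-impaired structural parameters."""
    return StructuralParams(cl=8.6, vc=80.0, q=60.0, vp=250.0)


@pytest.fixture
def standard_regimen():
    return Regimen(loading_dose=100.0, maintenance_dose=50.0)


def make_one_eta_spec(cl=8.6, omega2_cl=0.2, sigma_prop=0.124, name="toy"):
    """Base model with IIV on CL only (fast 1-eta estimation scenarios)."""
    return ModelSpec(
        population=PopulationParams(
            theta=StructuralParams(cl=cl, vc=80.0, q=60.0, vp=250.0),
            omega2={"cl": omega2_cl},
            sigma_prop=sigma_prop,
        ),
        name=name,
    )


def simulate_one_eta_dataset(spec, n_subjects, rng, times=None, covariates=None):
    """Sparse dataset simulated from a 1-eta spec (cl random effect only)."""
    from tigepk.pk_core import concentration
    from tigepk.popmodel import apply_covariates

    reg = Regimen()
    times = np.asarray(times if times is not None else [36.3, 38.0, 41.0, 47.5])
    doses = reg.doses(int(times.max() // reg.interval) + 1)
    pop = spec.population
    om = np.sqrt(pop.omega2.get("cl", 0.0))
    subjects = []
    for i in range(n_subjects):
        cov = covariates[i] if covariates is not None else {}
        cl_tv = apply_covariates(pop.theta.cl, spec.effects_on("cl"), cov)
        cl_i = cl_tv * np.exp(om * rng.standard_normal())
        p_i = StructuralParams(cl_i, pop.theta.vc, pop.theta.q, pop.theta.vp)
        f = concentration(times, doses, p_i)
        y = f * (1.0 + pop.sigma_prop * rng.standard_normal(times.size))
        while np.any(y <= 0):
            bad = y <= 0
            y[bad] = f[bad] * (1.0 + pop.sigma_prop * rng.standard_normal(int(bad.sum())))
        subjects.append(Subject(id=f"S{i}", doses=doses, times=times, dv=y,
                                covariates=cov))
    return StudyDataset(subjects=subjects)


#: Free-parameter freeze used by the fast 1-eta scenarios: only CL, IIV_CL
#: and the residual SD (plus any covariate coefficient) are estimated.
ONE_ETA_FIX = ("vc", "q", "vp")
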