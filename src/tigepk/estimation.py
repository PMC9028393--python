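"""Nonlinear mixed-effects estimation for the two-compartment model.

The marginal likelihood of each subject's concentration data is approximated
by the Laplace method at the conditional mode of the subject's random
effects, with the residual variance evaluated at the *individual* prediction
(the "interaction" convention of FOCE-I).  Writing, per subject,

    g(eta) = sum_j [ log v_j(eta) + (y_j - f_j(eta))^2 / v_j(eta) ]
             + eta' Omega^-1 eta + log det Omega,

the objective function value (OFV) contribution is

    OFV_i = g(eta_hat) + log det( (1/2) Hess g(eta_hat) ),

which is -2 times the approximate marginal log-likelihood with the
n·log(2·pi) data constant omitted (the NONMEM convention, so differences in
OFV between nested models are chi-square distributed under the null and
directly comparable with published dOFV tables).

The inner (eta) problem is solved by a damped Newton iteration vectorized
across subjects; gradients use complex-step differentiation of the
closed-form concentration model (machine precision, no step-size tuning) and
Hessians are finite differences of those gradients.  The outer problem
optimizes log-transformed theta/omega/sigma (covariate coefficients
untransformed) with L-BFGS-B and a Nelder-Mead fallback.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .pk_core import StructuralParams, _conc_grid
from .popmodel import (
    ETA_NAMES,
    CovariateEffect,
    InvalidEffectError,
    ModelSpec,
    PopulationParams,
    apply_covariates,
    iiv_percent_from_omega2,
)

__all__ = [
    "Subject",
    "StudyDataset",
    "FitResult",
    "ScmStep",
    "ScmTrace",
    "ofv",
    "fit",
    "ebe",
    "shrinkage",
    "lrt",
    "stepwise_scm",
    "pc_vpc",
    "bootstrap_ci",
]

INNER_GTOL = 1e-8  # inner Newton: max |grad g| at the conditional mode
OUTER_FTOL = 1e-9  # outer L-BFGS-B relative ftol
_PENALTY_OFV = 1e10
_CSTEP = 1e-20  # complex-step size
_HSTEP = 1e-5  # FD step for the eta Hessian


# ---------------------------------------------------------------------------
# dataset containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Subject:
    """One subject: dosing history, timed observations, covariates."""

    id: str
    doses: tuple
    times: np.ndarray  # h since first dose
    dv: np.ndarray  # observed concentration, mg/L
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "doses", tuple(self.doses))
        object.__setattr__(self, "times", np.atleast_1d(np.asarray(self.times, dtype=float)))
        object.__setattr__(self, "dv", np.atleast_1d(np.asarray(self.dv, dtype=float)))
        if len(self.doses) < 1:
            raise ValueError(f"subject {self.id}: needs at least one dose event")
        if self.times.shape != self.dv.shape:
            raise ValueError(f"subject {self.id}: times/dv must be equal length")
        first = min(d.start_time for d in self.doses)
        if np.any(self.times <= first):
            raise ValueError(
                f"subject {self.id}: observation times must be strictly after the "
                f"first dose start ({first} h)"
            )
        if np.any(self.dv <= 0):
            raise ValueError(
                f"subject {self.id}: non-positive concentrations are not supported "
                "under the proportional error model"
            )


@dataclass(frozen=True)
class StudyDataset:
    """The unit of estimation: a list of subjects."""

    subjects: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "subjects", tuple(self.subjects))
        if len(self.subjects) == 0:
            raise ValueError("dataset must contain at least one subject")
        ids = [s.id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate subject ids in dataset")
        empty = [s.id for s in self.subjects if s.times.size == 0]
        if empty:
            raise ValueError(f"subjects without observations: {empty}")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_observations(self) -> int:
        return int(sum(s.times.size for s in self.subjects))

    def covariate_column(self, name: str) -> np.ndarray:
        vals = []
        for s in self.subjects:
            if name not in s.covariates:
                raise KeyError(f"covariate {name!r} missing for subject {s.id}")
            vals.append(s.covariates[name])
        return np.asarray(vals)

    def resample(self, rng: np.random.Generator) -> "StudyDataset":
        """Nonparametric bootstrap resample of whole subjects (with new ids)."""
        idx = rng.integers(0, self.n_subjects, size=self.n_subjects)
        subs = [replace(self.subjects[i], id=f"b{k}") for k, i in enumerate(idx)]
        return StudyDataset(subjects=subs)


@dataclass
class FitResult:
    """Estimates and diagnostics of one maximum-likelihood fit."""

    spec: ModelSpec
    ofv: float
    n_params: int
    ebes: np.ndarray  # (n_subjects, 3) eta-hat in (cl, vc, vp) order
    shrinkage: dict  # eta name -> percent, only where omega2 > 0
    converged: bool
    n_function_evals: int
    message: str = ""
    at_boundary: tuple = ()

    @property
    def aic(self) -> float:
        return self.ofv + 2.0 * self.n_params

    def to_report(self) -> dict:
        p = self.spec.population
        return {
            "model": self.spec.name,
            "ofv": self.ofv,
            "aic": self.aic,
            "n_params": self.n_params,
            "converged": self.converged,
            "theta": {
                "cl": p.theta.cl, "vc": p.theta.vc, "q": p.theta.q, "vp": p.theta.vp,
            },
            "iiv_percent": {
                k: iiv_percent_from_omega2(v) for k, v in p.omega2.items() if v > 0
            },
            "sigma_prop": p.sigma_prop,
            "sigma_add": p.sigma_add,
            "effects": [
                {"target": e.target, "covariate": e.covariate, "form": e.form,
                 "coefficient": e.coefficient, "reference": e.reference}
                for e in self.spec.effects
            ],
            "shrinkage_percent": self.shrinkage,
            "at_boundary": list(self.at_boundary),
            "message": self.message,
        }


# ---------------------------------------------------------------------------
# packed (padded) arrays for vectorized likelihood evaluation
# ---------------------------------------------------------------------------


class _Packed:
    def __init__(self, dataset: StudyDataset):
        subs = dataset.subjects
        n = len(subs)
        jmax = max(s.times.size for s in subs)
        dmax = max(len(s.doses) for s in subs)
        self.n = n
        self.times = np.zeros((n, jmax))
        self.y = np.ones((n, jmax))
        self.mask = np.zeros((n, jmax))
        self.d_start = np.zeros((n, dmax))
        self.d_rate = np.zeros((n, dmax))
        self.d_dur = np.ones((n, dmax))
        for i, s in enumerate(subs):
            j = s.times.size
            self.times[i, :j] = s.times
            self.times[i, j:] = s.times[0]  # benign padding (masked out)
            self.y[i, :j] = s.dv
            self.mask[i, :j] = 1.0
            for k, d in enumerate(s.doses):
                self.d_start[i, k] = d.start_time
                self.d_rate[i, k] = d.amount / d.infusion_duration
                self.d_dur[i, k] = d.infusion_duration
        self.covariates = {}
        all_keys = set().union(*(s.covariates.keys() for s in subs)) if subs else set()
        for key in all_keys:
            if all(key in s.covariates for s in subs):
                self.covariates[key] = np.asarray([s.covariates[key] for s in subs])
        self.n_obs = int(self.mask.sum())

    def conc(self, cl, vc, q, vp):
        """Concentration matrix (n, jmax); parameter arrays shaped (n,) or
        (n,1) broadcast; complex dtype supported."""
        cl, vc, q, vp = (np.asarray(a)[..., None, None] for a in (cl, vc, q, vp))
        per_dose = _conc_grid(
            self.times[:, None, :], self.d_start[:, :, None],
            self.d_rate[:, :, None], self.d_dur[:, :, None],
            cl, vc, q, vp,
        )
        return per_dose.sum(axis=-2)


# ---------------------------------------------------------------------------
# numeric parameter vector <-> ModelSpec
# ---------------------------------------------------------------------------

_THETA_NAMES = ("cl", "vc", "q", "vp")


class _ParamMap:
    """Mapping between the outer optimizer's vector and a ModelSpec.

    Structural parameters, omega2 and sigma are log-transformed; covariate
    coefficients are untransformed.  Names in ``fix`` stay at their values in
    the template spec.
    """

    def __init__(self, spec: ModelSpec, fix=()):
        self.template = spec
        self.fix = set(fix)
        self.names: list[str] = []
        for nm in _THETA_NAMES:
            if nm not in self.fix:
                self.names.append(f"log_{nm}")
        for k, e in enumerate(spec.effects):
            nm = f"effect:{e.covariate}:{e.target}:{k}"
            if nm not in self.fix and f"effect:{e.covariate}:{e.target}" not in self.fix:
                self.names.append(nm)
        for nm in ETA_NAMES:
            if spec.population.omega2.get(nm, 0.0) > 0 and f"omega2_{nm}" not in self.fix:
                self.names.append(f"log_omega2_{nm}")
        if spec.error_model in ("proportional", "combined") and "sigma_prop" not in self.fix:
            self.names.append("log_sigma_prop")
        if spec.error_model in ("additive", "combined") and "sigma_add" not in self.fix:
            self.names.append("log_sigma_add")

    @property
    def n_free(self) -> int:
        return len(self.names)

    def x0(self) -> np.ndarray:
        p = self.template.population
        vals = []
        for nm in self.names:
            if nm.startswith("log_omega2_"):
                vals.append(np.log(p.omega2[nm.removeprefix("log_omega2_")]))
            elif nm == "log_sigma_prop":
                vals.append(np.log(p.sigma_prop))
            elif nm == "log_sigma_add":
                vals.append(np.log(p.sigma_add))
            elif nm.startswith("log_"):
                vals.append(np.log(getattr(p.theta, nm.removeprefix("log_"))))
            else:  # effect coefficient
                k = int(nm.rsplit(":", 1)[1])
                vals.append(self.template.effects[k].coefficient)
        return np.asarray(vals, dtype=float)

    def bounds(self):
        out = []
        for nm in self.names:
            if nm.startswith("log_omega2_"):
                out.append((np.log(1e-6), np.log(16.0)))
            elif nm.startswith("log_sigma"):
                out.append((np.log(1e-4), np.log(10.0)))
            elif nm.startswith("log_"):
                out.append((np.log(1e-3), np.log(1e5)))
            else:
                out.append((-100.0, 100.0))
        return out

    def unpack(self, x: np.ndarray) -> ModelSpec:
        p = self.template.population
        theta = {nm: getattr(p.theta, nm) for nm in _THETA_NAMES}
        omega2 = dict(p.omega2)
        sig = {"sigma_prop": p.sigma_prop, "sigma_add": p.sigma_add}
        effects = list(self.template.effects)
        for nm, v in zip(self.names, x):
            if nm.startswith("log_omega2_"):
                omega2[nm.removeprefix("log_omega2_")] = float(np.exp(v))
            elif nm.startswith("log_sigma"):
                sig[nm.removeprefix("log_")] = float(np.exp(v))
            elif nm.startswith("log_"):
                theta[nm.removeprefix("log_")] = float(np.exp(v))
            else:
                k = int(nm.rsplit(":", 1)[1])
                effects[k] = replace(effects[k], coefficient=float(v))
        pop = PopulationParams(
            theta=StructuralParams(**theta), omega2=omega2,
            sigma_prop=sig["sigma_prop"], sigma_add=sig["sigma_add"],
        )
        return replace(self.template, population=pop, effects=tuple(effects))


# ---------------------------------------------------------------------------
# inner problem: conditional eta modes, vectorized across subjects
# ---------------------------------------------------------------------------


class _InnerProblem:
    """g(eta) and its derivatives for all subjects at fixed population values."""

    def __init__(self, packed: _Packed, spec: ModelSpec):
        self.p = packed
        self.spec = spec
        pop = spec.population
        # covariate-adjusted typical values per subject (may raise
        # MissingCovariateError / InvalidEffectError -> caught by outer)
        self.cl_tv = np.broadcast_to(
            apply_covariates(pop.theta.cl, spec.effects_on("cl"), packed.covariates),
            (packed.n,)).astype(float)
        self.vc_tv = np.broadcast_to(
            apply_covariates(pop.theta.vc, spec.effects_on("vc"), packed.covariates),
            (packed.n,)).astype(float)
        self.q = pop.theta.q
        self.vp_tv = np.full(packed.n, pop.theta.vp)
        om = pop.omega2_vector()
        self.support = np.flatnonzero(om > 0)  # indices into (cl, vc, vp)
        self.om_inv = 1.0 / om[self.support] if self.support.size else np.empty(0)
        self.logdet_om = float(np.sum(np.log(om[self.support]))) if self.support.size else 0.0
        self.sig2p = pop.sigma_prop**2 if spec.error_model in ("proportional", "combined") else 0.0
        self.sig2a = pop.sigma_add**2 if spec.error_model in ("additive", "combined") else 0.0

    def _expand(self, eta_s):
        """(n, k) support etas -> full (cl, vc, vp) eta columns."""
        full = np.zeros((self.p.n, 3), dtype=eta_s.dtype)
        if self.support.size:
            full[:, self.support] = eta_s
        return full

    def g(self, eta_s):
        """Vector of g_i; complex-safe in eta."""
        full = self._expand(np.atleast_2d(eta_s))
        cl = self.cl_tv * np.exp(full[:, 0])
        vc = self.vc_tv * np.exp(full[:, 1])
        vp = self.vp_tv * np.exp(full[:, 2])
        f = self.p.conc(cl, vc, self.q, vp)
        v = self.sig2p * f * f + self.sig2a
        r = self.y_minus(f)
        loglik = ((np.log(v) + r * r / v) * self.p.mask).sum(axis=1)
        prior = 0.0
        if self.support.size:
            es = np.atleast_2d(eta_s)
            prior = (es * es * self.om_inv).sum(axis=1) + self.logdet_om
        return loglik + prior

    def y_minus(self, f):
        return self.p.y - f

    def grad(self, eta_s):
        """Complex-step gradient of g, shape (n, k)."""
        k = self.support.size
        out = np.empty((self.p.n, k))
        for j in range(k):
            pert = eta_s.astype(complex)
            pert[:, j] += 1j * _CSTEP
            out[:, j] = np.imag(self.g(pert)) / _CSTEP
        return out

    def hess(self, eta_s):
        """FD-of-complex-step-gradient Hessian of g, shape (n, k, k)."""
        k = self.support.size
        g0 = self.grad(eta_s)
        out = np.empty((self.p.n, k, k))
        for j in range(k):
            pert = eta_s.copy()
            pert[:, j] += _HSTEP
            out[:, :, j] = (self.grad(pert) - g0) / _HSTEP
        return 0.5 * (out + np.swapaxes(out, 1, 2))

    def solve_modes(self, eta0=None, gtol=INNER_GTOL, max_iter=60):
        """Damped-Newton conditional modes for all subjects at once.

        Converged subjects drop out of the iteration; steps are trust-region
        capped (norm <= 3 on the log scale) and backtracked until g does not
        increase beyond rounding.
        """
        k = self.support.size
        if k == 0:
            return np.zeros((self.p.n, 0)), True
        eta = np.zeros((self.p.n, k)) if eta0 is None else np.nan_to_num(eta0.copy())
        with np.errstate(all="ignore"):
            gval = np.where(np.isfinite(gv := self.g(eta)), gv, np.inf)
            bad = ~np.isfinite(gval)
            if bad.any():  # fall back to the prior mode where warm start broke
                eta[bad] = 0.0
                gval[bad] = self.g(eta)[bad]
            for _ in range(max_iter):
                gr = self.grad(eta)
                live = np.max(np.abs(gr), axis=1) >= gtol
                if not live.any():
                    break
                hs = self.hess(eta)
                w, vmat = np.linalg.eigh(hs)
                w = np.maximum(w, 1e-6)
                step = -np.einsum("nij,nj,nkj,nk->ni", vmat, 1.0 / w, vmat, gr)
                norm = np.linalg.norm(step, axis=1, keepdims=True)
                step = np.where(norm > 3.0, step * (3.0 / norm), step)
                step[~live] = 0.0
                tstep = np.ones(self.p.n)
                active = live.copy()
                for _ls in range(30):
                    trial = eta + tstep[:, None] * step
                    gtrial = self.g(trial)
                    better = np.isfinite(gtrial) & (
                        gtrial <= gval + 1e-10 * (1.0 + np.abs(gval)))
                    accept = better & active
                    eta[accept] = trial[accept]
                    gval[accept] = gtrial[accept]
                    active &= ~better
                    if not active.any():
                        break
                    tstep[active] *= 0.5
                if active.any() and not (live & ~active).any():
                    break  # no subject improved: at numerical precision
            ok = bool(np.max(np.abs(self.grad(eta))) < 1e-3)
        return eta, ok

    def ofv_terms(self, eta_s):
        """Per-subject OFV contributions at the conditional modes."""
        gval = np.real(self.g(eta_s))
        if self.support.size == 0:
            return gval
        hs = self.hess(eta_s)
        half_h = 0.5 * hs
        sign, logdet = np.linalg.slogdet(half_h)
        if np.any(sign <= 0):
            # non-PD curvature at the mode: ridge just enough to evaluate
            w = np.linalg.eigvalsh(half_h)
            ridge = np.maximum(1e-8 - w.min(axis=1), 0.0)
            half_h = half_h + ridge[:, None, None] * np.eye(self.support.size)
            sign, logdet = np.linalg.slogdet(half_h)
        return gval + logdet


def _ofv_packed(packed: _Packed, spec: ModelSpec, eta0=None):
    prob = _InnerProblem(packed, spec)
    with np.errstate(all="ignore"):
        eta, ok = prob.solve_modes(eta0=eta0)
        terms = prob.ofv_terms(eta)
    return float(terms.sum()), eta, prob, ok


def ofv(dataset: StudyDataset, spec: ModelSpec) -> float:
    """FOCE-I/Laplace objective function value (NONMEM convention).

    Sum over subjects of the -2 log approximate marginal likelihood with the
    n·log(2·pi) constant omitted.  With all omega2 = 0 this reduces to the
    fixed-effects weighted-least-squares deviance.
    """
    packed = _Packed(dataset)
    prob = _InnerProblem(packed, spec)
    with np.errstate(all="ignore"):
        eta, _ = prob.solve_modes()
        terms = prob.ofv_terms(eta)
    bad = ~np.isfinite(terms)
    if bad.any():
        ids = [dataset.subjects[i].id for i in np.flatnonzero(bad)]
        raise RuntimeError(
            f"non-finite OFV contribution for subject(s) {ids} at the "
            "supplied parameters")
    return float(terms.sum())


# ---------------------------------------------------------------------------
# outer problem
# ---------------------------------------------------------------------------


def fit(
    dataset: StudyDataset,
    spec: ModelSpec,
    inits: dict | None = None,
    fix=(),
    maxiter: int = 400,
) -> FitResult:
    """Maximum (approximate marginal) likelihood fit of a population model.

    ``spec`` supplies the model structure and the initial values; ``inits``
    may override individual entries (keys like ``"cl"``, ``"omega2_cl"``,
    ``"sigma_prop"`` or ``"effect:<covariate>:<target>"``).  ``fix`` freezes
    named parameters at their initial values.  Deterministic given dataset,
    inits and tolerances; non-convergence is flagged on the result, not
    raised.
    """
    template = spec
    if inits:
        template = _apply_inits(spec, inits)
    pm = _ParamMap(template, fix=fix)
    packed = _Packed(dataset)
    state = {"eta": None, "nfev": 0}

    def objective(x):
        state["nfev"] += 1
        try:
            cand = pm.unpack(x)
        except (ValueError, InvalidEffectError):
            return _PENALTY_OFV
        try:
            val, eta, _, ok = _ofv_packed(packed, cand, eta0=state["eta"])
        except (InvalidEffectError, FloatingPointError, np.linalg.LinAlgError):
            return _PENALTY_OFV
        if not np.isfinite(val):
            return _PENALTY_OFV
        if state["eta"] is None or eta.shape == np.shape(state["eta"]):
            state["eta"] = eta
        return val

    x0 = pm.x0()
    bounds = pm.bounds()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = optimize.minimize(
            objective, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": maxiter, "ftol": OUTER_FTOL, "gtol": 1e-5,
                     "eps": 1e-5},
        )
        converged = bool(res.success) and res.fun < _PENALTY_OFV / 2
        if not converged:
            res2 = optimize.minimize(
                objective, res.x if np.isfinite(res.fun) else x0,
                method="Nelder-Mead",
                options={"maxiter": 200 * max(pm.n_free, 1), "fatol": 1e-6,
                         "xatol": 1e-6},
            )
            if res2.fun <= res.fun:
                res = res2
            converged = bool(res.fun < _PENALTY_OFV / 2 and res.success)

    fitted = pm.unpack(res.x)
    value, eta_s, prob, _ = _ofv_packed(packed, fitted, eta0=state["eta"])
    ebes = prob._expand(eta_s)
    at_boundary = tuple(
        nm.removeprefix("log_") for nm, xv, (lo, hi) in zip(pm.names, res.x, bounds)
        if nm.startswith("log_omega2_") and xv <= lo + 1e-6
    )
    shr = {}
    for j, nm in enumerate(ETA_NAMES):
        om = fitted.population.omega2.get(nm, 0.0)
        if om > 0 and nm not in at_boundary and dataset.n_subjects > 1:
            shr[nm] = shrinkage(ebes[:, j], om)
    return FitResult(
        spec=fitted, ofv=value, n_params=pm.n_free, ebes=ebes, shrinkage=shr,
        converged=converged, n_function_evals=state["nfev"],
        message=str(getattr(res, "message", "")), at_boundary=at_boundary,
    )


def _apply_inits(spec: ModelSpec, inits: dict) -> ModelSpec:
    p = spec.population
    theta = {nm: getattr(p.theta, nm) for nm in _THETA_NAMES}
    omega2 = dict(p.omega2)
    sigp, siga = p.sigma_prop, p.sigma_add
    effects = list(spec.effects)
    for key, val in inits.items():
        if key in _THETA_NAMES:
            theta[key] = val
        elif key.startswith("omega2_"):
            omega2[key.removeprefix("omega2_")] = val
        elif key == "sigma_prop":
            sigp = val
        elif key == "sigma_add":
            siga = val
        elif key.startswith("effect:"):
            _, cov, tgt = key.split(":")
            hit = [k for k, e in enumerate(effects)
                   if e.covariate == cov and e.target == tgt]
            if not hit:
                raise KeyError(f"no effect matching {key!r} in spec")
            for k in hit:
                effects[k] = replace(effects[k], coefficient=val)
        else:
            raise KeyError(f"unknown init key {key!r}")
    pop = PopulationParams(theta=StructuralParams(**theta), omega2=omega2,
                           sigma_prop=sigp, sigma_add=siga)
    return replace(spec, population=pop, effects=tuple(effects))


# ---------------------------------------------------------------------------
# empirical Bayes estimates and shrinkage
# ---------------------------------------------------------------------------


def ebe(subject: Subject, spec: ModelSpec) -> np.ndarray:
    """Conditional (posterior-mode) eta for one subject, (cl, vc, vp) order.

    A subject contributing no observations returns the prior mode 0.
    """
    if subject.times.size == 0:
        return np.zeros(3)
    packed = _Packed(StudyDataset(subjects=(subject,)))
    prob = _InnerProblem(packed, spec)
    eta, ok = prob.solve_modes()
    if not ok:
        warnings.warn(f"eta optimization did not fully converge for subject {subject.id}")
    return prob._expand(eta)[0]


def shrinkage(ebes_one_eta: np.ndarray, omega2: float) -> float:
    """Eta-shrinkage in percent: 100·(1 − SD(eta-hats)/sqrt(omega2)).

    SD uses the n−1 denominator.  May be negative; undefined at omega2 = 0.
    """
    if omega2 <= 0:
        raise ValueError("shrinkage is undefined for omega2 = 0")
    sd = float(np.std(np.asarray(ebes_one_eta, dtype=float), ddof=1))
    return 100.0 * (1.0 - sd / np.sqrt(omega2))


def lrt(dofv: float, df: int) -> float:
    """Likelihood-ratio test p-value: upper-tail chi2(df) at max(dofv, 0)."""
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(stats.chi2.sf(max(float(dofv), 0.0), df))


# ---------------------------------------------------------------------------
# stepwise covariate modeling
# ---------------------------------------------------------------------------


@dataclass
class ScmStep:
    phase: str  # "forward" or "backward"
    covariate: str
    parameter: str
    form: str
    dofv: float
    p_value: float
    included: bool
    iiv_before: dict
    iiv_after: dict
    strong_iiv_reduction: bool  # >10 percentage-point IIV_CL drop


@dataclass
class ScmTrace:
    steps: list = field(default_factory=list)
    skipped: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{
                "phase": s.phase, "covariate": s.covariate, "parameter": s.parameter,
                "form": s.form, "dofv": s.dofv, "p_value": s.p_value,
                "included": s.included,
                "iiv_cl_before": s.iiv_before.get("cl", np.nan),
                "iiv_cl_after": s.iiv_after.get("cl", np.nan),
                "iiv_vc_before": s.iiv_before.get("vc", np.nan),
                "iiv_vc_after": s.iiv_after.get("vc", np.nan),
                "strong_iiv_reduction": s.strong_iiv_reduction,
            } for s in self.steps]
        )


def _iiv_map(fitres: FitResult) -> dict:
    return {k: iiv_percent_from_omega2(v)
            for k, v in fitres.spec.population.omega2.items() if v > 0}


def _candidate_effect(candidate, dataset: StudyDataset) -> CovariateEffect:
    covariate, parameter, form = candidate
    if form == "categorical":
        ref = "C" if covariate == "cps" else 1
        return CovariateEffect(parameter, covariate, form, 0.0, ref)
    ref = float(np.median(dataset.covariate_column(covariate).astype(float)))
    return CovariateEffect(parameter, covariate, form, 0.0, ref)


def stepwise_scm(
    dataset: StudyDataset,
    base: ModelSpec,
    candidates,
    forward_alpha: float = 0.05,
    backward_alpha: float = 0.01,
    maxiter: int = 400,
    fix=(),
):
    """Forward-inclusion / backward-elimination covariate search.

    ``candidates`` is a list of ``(covariate, parameter, form)`` triples.
    Forward: at each round every remaining candidate is fitted on top of the
    current model and the lowest-p candidate enters if p < ``forward_alpha``
    (ties broken by larger dOFV, then list order).  Backward: starting from
    the forward model, the highest-p retained effect is removed until all
    retained effects have p < ``backward_alpha``.  The trace records the
    IIV before/after each step and flags effects cutting IIV on CL by more
    than 10 percentage points (candidates for guiding dose adjustment).
    Non-converged candidate fits are skipped and logged.

    Returns ``(trace, final_spec)``.
    """
    trace = ScmTrace()
    current_fit = fit(dataset, base, maxiter=maxiter, fix=fix)
    current_spec = current_fit.spec
    remaining = list(candidates)
    included: list[tuple] = []

    while remaining:
        rows = []
        for cand in remaining:
            eff = _candidate_effect(cand, dataset)
            try:
                trial_spec = replace(current_spec, effects=current_spec.effects + (eff,))
                trial = fit(dataset, trial_spec, maxiter=maxiter, fix=fix)
            except Exception as exc:  # candidate must never be fatal
                trace.skipped.append((cand, f"error: {exc}"))
                continue
            if not trial.converged and not np.isfinite(trial.ofv):
                trace.skipped.append((cand, "non-converged"))
                continue
            dofv = current_fit.ofv - trial.ofv
            rows.append((cand, trial, dofv, lrt(dofv, 1)))
        if not rows:
            break
        # lowest p, ties by larger dofv, then candidate order
        order = sorted(range(len(rows)), key=lambda i: (rows[i][3], -rows[i][2], i))
        cand, trial, dofv, p = rows[order[0]]
        iiv_before, iiv_after = _iiv_map(current_fit), _iiv_map(trial)
        strong = iiv_before.get("cl", np.nan) - iiv_after.get("cl", np.nan) > 10.0
        include = p < forward_alpha
        trace.steps.append(ScmStep("forward", cand[0], cand[1], cand[2], dofv, p,
                                   include, iiv_before, iiv_after, bool(strong)))
        if not include:
            break
        current_fit, current_spec = trial, trial.spec
        included.append(cand)
        remaining = [c for c in remaining if c != cand]

    # backward elimination
    while included:
        rows = []
        for cand in included:
            keep = tuple(
                e for e in current_spec.effects
                if not (e.covariate == cand[0] and e.target == cand[1] and e.form == cand[2])
            )
            reduced_spec = replace(current_spec, effects=keep)
            try:
                reduced = fit(dataset, reduced_spec, maxiter=maxiter, fix=fix)
            except Exception as exc:
                trace.skipped.append((cand, f"backward error: {exc}"))
                continue
            dofv = reduced.ofv - current_fit.ofv  # rise on removal
            rows.append((cand, reduced, dofv, lrt(dofv, 1)))
        if not rows:
            break
        order = sorted(range(len(rows)), key=lambda i: (-rows[i][3], rows[i][2], i))
        cand, reduced, dofv, p = rows[order[0]]
        if p < backward_alpha:  # weakest effect still significant: stop
            break
        iiv_before, iiv_after = _iiv_map(current_fit), _iiv_map(reduced)
        trace.steps.append(ScmStep("backward", cand[0], cand[1], cand[2], dofv, p,
                                   False, iiv_before, iiv_after, False))
        current_fit, current_spec = reduced, reduced.spec
        included = [c for c in included if c != cand]

    return trace, current_spec


# ---------------------------------------------------------------------------
# prediction-corrected visual predictive check
# ---------------------------------------------------------------------------


def pc_vpc(
    dataset: StudyDataset,
    spec: ModelSpec,
    n_sim: int = 500,
    bins: int = 5,
    seed: int = 0,
    percentiles=(5.0, 50.0, 95.0),
):
    """Prediction-corrected VPC percentile table.

    Observations and simulated values are scaled by (bin median population
    prediction / subject-time population prediction), binned on time after
    the most recent dose with equal-count bins, and summarised as the 5th /
    50th / 95th percentiles with a 95% simulation band for each.
    Returns a DataFrame with one row per (bin, percentile).
    """
    packed = _Packed(dataset)
    prob = _InnerProblem(packed, spec)
    f_pred = packed.conc(prob.cl_tv, prob.vc_tv, prob.q, prob.vp_tv)
    mask = packed.mask.astype(bool)
    # time after the most recent dose at or before each observation
    tad = np.empty_like(packed.times)
    for i in range(packed.n):
        starts = packed.d_start[i][packed.d_rate[i] > 0]
        for j, t in enumerate(packed.times[i]):
            prior = starts[starts <= t]
            tad[i, j] = t - (prior.max() if prior.size else 0.0)
    obs = packed.y[mask]
    pred_obs = f_pred[mask]
    tad_obs = tad[mask]
    keep = pred_obs > 0
    if not np.all(keep):
        warnings.warn(f"excluding {np.sum(~keep)} records with zero population prediction")
    obs, pred_obs, tad_obs = obs[keep], pred_obs[keep], tad_obs[keep]
    # equal-count bins on time after dose
    edges = np.quantile(tad_obs, np.linspace(0, 1, bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    bin_idx = np.clip(np.searchsorted(edges, tad_obs, side="right") - 1, 0, bins - 1)
    bin_median_pred = np.array([np.median(pred_obs[bin_idx == b]) if np.any(bin_idx == b)
                                else np.nan for b in range(bins)])
    pc_obs = obs * bin_median_pred[bin_idx] / pred_obs

    rng = np.random.default_rng(seed)
    om = spec.population.omega2_vector()
    sim_pcts = np.empty((n_sim, bins, len(percentiles)))
    for r in range(n_sim):
        eta = rng.standard_normal((packed.n, 3)) * np.sqrt(om)
        cl = prob.cl_tv * np.exp(eta[:, 0])
        vc = prob.vc_tv * np.exp(eta[:, 1])
        vp = prob.vp_tv * np.exp(eta[:, 2])
        f_ind = packed.conc(cl, vc, prob.q, vp)
        v = prob.sig2p * f_ind**2 + prob.sig2a
        y_sim = (f_ind + np.sqrt(v) * rng.standard_normal(f_ind.shape))[mask][keep]
        pc_sim = y_sim * bin_median_pred[bin_idx] / pred_obs
        for b in range(bins):
            sel = bin_idx == b
            sim_pcts[r, b] = (np.percentile(pc_sim[sel], percentiles)
                              if sel.any() else np.nan)
    rows = []
    for b in range(bins):
        sel = bin_idx == b
        if not sel.any():
            continue
        for k, pct in enumerate(percentiles):
            rows.append({
                "bin": b,
                "tad_median": float(np.median(tad_obs[sel])),
                "n_obs": int(sel.sum()),
                "percentile": pct,
                "observed": float(np.percentile(pc_obs[sel], pct)),
                "simulated_median": float(np.median(sim_pcts[:, b, k])),
                "sim_lower": float(np.percentile(sim_pcts[:, b, k], 2.5)),
                "sim_upper": float(np.percentile(sim_pcts[:, b, k], 97.5)),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# bootstrap uncertainty
# ---------------------------------------------------------------------------


def bootstrap_ci(
    dataset: StudyDataset,
    spec: ModelSpec,
    n_boot: int = 200,
    seed: int = 0,
    fix=(),
    maxiter: int = 400,
):
    """Nonparametric (subject-resampling) bootstrap percentile intervals.

    Refits ``spec`` to ``n_boot`` resampled datasets and reports the 2.5th /
    50th / 97.5th percentiles of every free parameter; fully reproducible
    under a fixed seed.  Returns a dict with a per-parameter table and an
    ``unreliable`` flag raised when more than 20% of replicates fail to
    converge.
    """
    if n_boot < 50:
        raise ValueError("n_boot must be >= 50 for percentile intervals")
    rng = np.random.default_rng(seed)
    pm = _ParamMap(spec, fix=fix)
    draws, n_fail = [], 0
    for _ in range(n_boot):
        bds = dataset.resample(rng)
        try:
            fr = fit(bds, spec, fix=fix, maxiter=maxiter)
        except Exception:
            n_fail += 1
            continue
        if not np.isfinite(fr.ofv):
            n_fail += 1
            continue
        if not fr.converged:
            n_fail += 1
        row = {}
        p = fr.spec.population
        for nm in pm.names:
            if nm.startswith("log_omega2_"):
                key = nm.removeprefix("log_")
                row[key] = p.omega2[nm.removeprefix("log_omega2_")]
            elif nm.startswith("log_sigma"):
                key = nm.removeprefix("log_")
                row[key] = getattr(p, key)
            elif nm.startswith("log_"):
                key = nm.removeprefix("log_")
                row[key] = getattr(p.theta, key)
            else:
                k = int(nm.rsplit(":", 1)[1])
                e = fr.spec.effects[k]
                row[f"effect:{e.covariate}:{e.target}"] = e.coefficient
        draws.append(row)
    if not draws:
        raise RuntimeError("all bootstrap replicates failed")
    table = pd.DataFrame(draws)
    summary = table.quantile([0.025, 0.5, 0.975]).T
    summary.columns = ["ci_lower", "median", "ci_upper"]
    return {
        "intervals": summary,
        "replicates": table,
        "n_boot": n_boot,
        "n_failed": n_fail,
        "unreliable": n_fail > 0.2 * n_boot,
    }
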