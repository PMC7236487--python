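"""Mathematical core of the joint model.

Longitudinal submodels are linear mixed models over age

    y_ki(t) = x_ki(t)' beta_k + z_ki(t)' b_ki + eps_ki(t),

with natural cubic splines in age inside ``x`` and correlated random
effects ``b_i = (b_1i, ..., b_Ki)`` drawn from one multivariate normal. The
event submodel is a proportional-hazards model on the age scale whose
linear predictor carries the *error-free* current biomarker values:

    h_i(t) = h0(t) * exp( gamma' w_i(t) + sum_k a_k (m_ki(t) - c_k) ),

so exp(a_k) is the hazard ratio per one-unit increase in biomarker k. The
optional centring constants ``c_k`` only shift the baseline hazard and are
0 by default; non-zero values improve the conditioning of the posterior
without changing any hazard ratio.

Cumulative hazards are computed with fixed-order Gauss-Legendre quadrature
applied piecewise between the ages at which acquired covariates switch on,
so the integrand is smooth on every piece.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import multivariate_normal

from .cohort import CohortData, PatientEventRecord
from .design import (fixed_design, fixed_design_columns, random_design,
                     random_design_dim)
from .errors import DimensionError, NumericalError, ParameterError
from .splines import LogHazardBasis, SplineBasisSpec

__all__ = [
    "LongitudinalSubmodelSpec", "JointModelSpec", "ParameterVector", "Params",
    "SplineLogHazard", "WeibullLogHazard",
    "longitudinal_mean", "hazard", "cumulative_hazard", "survival_probability",
    "complete_data_log_likelihood", "marginal_log_likelihood",
    "GaussHermiteControl",
]

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(15)


# --------------------------------------------------------------------------
# baseline hazards
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SplineLogHazard:
    """log h0(t) = B(t)' theta with a cubic B-spline basis B."""

    basis: LogHazardBasis = field(default_factory=LogHazardBasis)

    @property
    def n_par(self) -> int:
        return self.basis.n_basis

    @property
    def names(self) -> list[str]:
        return [f"event.loghaz.{j}" for j in range(self.n_par)]

    def log_h0(self, t, coef) -> np.ndarray:
        return self.basis.design(t) @ np.asarray(coef)

    def design(self, t) -> np.ndarray:
        return self.basis.design(t)


@dataclass(frozen=True)
class WeibullLogHazard:
    """Weibull baseline, parameterised by (log shape, log scale).

    h0(t) = (k / s) * (t / s)^(k - 1); closed-form cumulative hazard makes
    this the natural choice for simulation oracles.
    """

    n_par: int = 2

    @property
    def names(self) -> list[str]:
        return ["event.loghaz.log_shape", "event.loghaz.log_scale"]

    def log_h0(self, t, coef) -> np.ndarray:
        log_k, log_s = coef
        k = np.exp(log_k)
        t = np.maximum(np.asarray(t, dtype=float), 1e-12)
        return log_k - log_s + (k - 1.0) * (np.log(t) - log_s)

    def cumulative(self, t, coef) -> np.ndarray:
        log_k, log_s = coef
        k, s = np.exp(log_k), np.exp(log_s)
        return (np.asarray(t, dtype=float) / s) ** k


# --------------------------------------------------------------------------
# specs
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LongitudinalSubmodelSpec:
    """Design recipe for one longitudinal outcome.

    ``covariates`` and ``interactions`` are names resolved by
    :mod:`cfjoint.design`; interactions multiply a covariate into every age
    spline column. ``residual_sd`` is an optional generating/initial value;
    the fitted residual SD lives in the parameter vector.
    """

    outcome_name: str
    spline: SplineBasisSpec = field(default_factory=lambda: SplineBasisSpec(3))
    covariates: tuple[str, ...] = ()
    interactions: tuple[str, ...] = ()
    random_structure: str = "intercept_slope"
    residual_sd: float | None = None

    def __post_init__(self) -> None:
        if self.residual_sd is not None and not self.residual_sd > 0:
            raise ParameterError("residual_sd must be > 0")

    @property
    def fixed_columns(self) -> list[str]:
        return fixed_design_columns(self.spline, self.covariates, self.interactions)

    @property
    def n_fixed(self) -> int:
        return len(self.fixed_columns)

    @property
    def n_random(self) -> int:
        return random_design_dim(self.random_structure)

    def fixed_row(self, patient: PatientEventRecord, ages, encounter_ages=None):
        return fixed_design(patient, ages, self.spline, self.covariates,
                            self.interactions, encounter_ages)

    def random_row(self, ages):
        return random_design(ages, self.random_structure)


@dataclass(frozen=True)
class JointModelSpec:
    """Complete model definition: submodels, event design, association."""

    submodels: tuple[LongitudinalSubmodelSpec, ...]
    event_covariates: tuple[str, ...] = ()
    association_centers: tuple[float, ...] | None = None
    baseline: SplineLogHazard | WeibullLogHazard = field(default_factory=SplineLogHazard)

    def __post_init__(self) -> None:
        if not 1 <= len(self.submodels) <= 3:
            raise ParameterError("1 to 3 longitudinal submodels supported")
        if self.association_centers is not None and \
                len(self.association_centers) != len(self.submodels):
            raise ParameterError("one association centre per submodel required")

    @property
    def outcomes(self) -> tuple[str, ...]:
        return tuple(s.outcome_name for s in self.submodels)

    @property
    def centers(self) -> np.ndarray:
        if self.association_centers is None:
            return np.zeros(len(self.submodels))
        return np.asarray(self.association_centers, dtype=float)

    @property
    def b_slices(self) -> list[slice]:
        out, off = [], 0
        for s in self.submodels:
            out.append(slice(off, off + s.n_random))
            off += s.n_random
        return out

    @property
    def n_random_total(self) -> int:
        return sum(s.n_random for s in self.submodels)

    def resolve(self, cohort: CohortData) -> "JointModelSpec":
        """Fill in data-dependent knots (age quantiles; exit-time quantiles)."""
        obs = cohort.observations_frame()
        subs = []
        for s in self.submodels:
            ages = obs.loc[obs["outcome"] == s.outcome_name, "age"].to_numpy()
            subs.append(replace(s, spline=s.spline.resolve(ages)))
        baseline = self.baseline
        if isinstance(baseline, SplineLogHazard) and \
                baseline.basis.interior_knots is None:
            exits = np.array([p.exit_age for p in cohort.patients])
            baseline = SplineLogHazard(LogHazardBasis.from_times(
                exits, baseline.basis.n_basis, baseline.basis.boundary))
        return replace(self, submodels=tuple(subs), baseline=baseline)

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "submodels": [
                {
                    "outcome": s.outcome_name,
                    "df": s.spline.degrees_of_freedom,
                    "boundary_knots": list(s.spline.boundary_knots),
                    "interior_knots": (None if s.spline.interior_knots is None
                                       else list(s.spline.interior_knots)),
                    "covariates": list(s.covariates),
                    "interactions": list(s.interactions),
                    "random_structure": s.random_structure,
                    "residual_sd": s.residual_sd,
                }
                for s in self.submodels
            ],
            "event_covariates": list(self.event_covariates),
            "association_centers": (None if self.association_centers is None
                                    else list(self.association_centers)),
        }
        if isinstance(self.baseline, WeibullLogHazard):
            d["baseline"] = {"family": "weibull"}
        else:
            b = self.baseline.basis
            d["baseline"] = {
                "family": "logspline", "n_basis": b.n_basis,
                "boundary": list(b.boundary),
                "interior_knots": list(b.interior_knots),
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "JointModelSpec":
        subs = tuple(
            LongitudinalSubmodelSpec(
                outcome_name=s["outcome"],
                spline=SplineBasisSpec(
                    s["df"], tuple(s["boundary_knots"]),
                    None if s.get("interior_knots") is None
                    else tuple(s["interior_knots"])),
                covariates=tuple(s.get("covariates", ())),
                interactions=tuple(s.get("interactions", ())),
                random_structure=s.get("random_structure", "intercept_slope"),
                residual_sd=s.get("residual_sd"),
            )
            for s in d["submodels"]
        )
        bd = d.get("baseline", {"family": "logspline"})
        if bd["family"] == "weibull":
            baseline = WeibullLogHazard()
        else:
            baseline = SplineLogHazard(LogHazardBasis(
                bd.get("n_basis", 5), tuple(bd.get("boundary", (6.0, 20.0))),
                None if bd.get("interior_knots") is None
                else tuple(bd["interior_knots"])))
        ac = d.get("association_centers")
        return cls(submodels=subs,
                   event_covariates=tuple(d.get("event_covariates", ())),
                   association_centers=None if ac is None else tuple(ac),
                   baseline=baseline)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "JointModelSpec":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# --------------------------------------------------------------------------
# parameters
# --------------------------------------------------------------------------

@dataclass
class Params:
    """Structured view of one parameter point."""

    betas: list[np.ndarray]       # per submodel
    sigmas: np.ndarray            # residual SDs, per submodel
    re_cov: np.ndarray            # (q_total, q_total) random-effects covariance
    gamma: np.ndarray             # event covariate coefficients
    assoc: np.ndarray             # a_k, per submodel
    baseline_coef: np.ndarray


def parameter_names(spec: JointModelSpec) -> list[str]:
    names: list[str] = []
    for s in spec.submodels:
        names += [f"{s.outcome_name}.beta.{c}" for c in s.fixed_columns]
        names.append(f"{s.outcome_name}.sigma")
    q = spec.n_random_total
    names += [f"re_cov[{i},{j}]" for i in range(q) for j in range(i + 1)]
    names += [f"event.gamma.{c}" for c in spec.event_covariates]
    names += [f"event.assoc.{s.outcome_name}" for s in spec.submodels]
    names += spec.baseline.names
    return names


@dataclass
class ParameterVector:
    """Flat named parameter vector, bijective with :class:`Params` slots."""

    names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != self.values.size:
            raise DimensionError("names and values must have equal length")

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])

    def as_series(self):
        import pandas as pd
        return pd.Series(self.values, index=self.names)

    @classmethod
    def pack(cls, spec: JointModelSpec, params: Params) -> "ParameterVector":
        vals: list[float] = []
        for s, beta, sigma in zip(spec.submodels, params.betas, params.sigmas):
            if len(beta) != s.n_fixed:
                raise DimensionError(
                    f"{s.outcome_name}: beta length {len(beta)} != {s.n_fixed}")
            vals += list(np.asarray(beta, dtype=float))
            vals.append(float(sigma))
        q = spec.n_random_total
        cov = np.asarray(params.re_cov, dtype=float)
        if cov.shape != (q, q):
            raise DimensionError("re_cov has the wrong shape")
        vals += [cov[i, j] for i in range(q) for j in range(i + 1)]
        if len(params.gamma) != len(spec.event_covariates):
            raise DimensionError("gamma length mismatch")
        vals += list(np.asarray(params.gamma, dtype=float))
        if len(params.assoc) != len(spec.submodels):
            raise DimensionError("one association coefficient per submodel")
        vals += list(np.asarray(params.assoc, dtype=float))
        if len(params.baseline_coef) != spec.baseline.n_par:
            raise DimensionError("baseline coefficient length mismatch")
        vals += list(np.asarray(params.baseline_coef, dtype=float))
        return cls(parameter_names(spec), np.array(vals))

    def unpack(self, spec: JointModelSpec) -> Params:
        v = self.values
        off = 0
        betas, sigmas = [], []
        for s in spec.submodels:
            betas.append(v[off:off + s.n_fixed].copy())
            off += s.n_fixed
            sigmas.append(v[off])
            off += 1
        q = spec.n_random_total
        cov = np.zeros((q, q))
        for i in range(q):
            for j in range(i + 1):
                cov[i, j] = cov[j, i] = v[off]
                off += 1
        ng = len(spec.event_covariates)
        gamma = v[off:off + ng].copy()
        off += ng
        nk = len(spec.submodels)
        assoc = v[off:off + nk].copy()
        off += nk
        baseline = v[off:off + spec.baseline.n_par].copy()
        off += spec.baseline.n_par
        assert off == v.size
        return Params(betas, np.array(sigmas), cov, gamma, assoc, baseline)


# --------------------------------------------------------------------------
# model functions (reference path; the sampler uses a vectorised assembly)
# --------------------------------------------------------------------------

def longitudinal_mean(submodel: LongitudinalSubmodelSpec, beta, b_k, t,
                      patient: PatientEventRecord, encounter_ages=None):
    """Error-free mean m_ki(t) = x(t)'beta + z(t)'b for one outcome."""
    beta = np.asarray(beta, dtype=float)
    b_k = np.asarray(b_k, dtype=float)
    if beta.size != submodel.n_fixed:
        raise DimensionError(
            f"beta has {beta.size} entries, design has {submodel.n_fixed}")
    if b_k.size != submodel.n_random:
        raise DimensionError(
            f"b has {b_k.size} entries, random design has {submodel.n_random}")
    X = submodel.fixed_row(patient, t, encounter_ages)
    Z = submodel.random_row(t)
    out = X @ beta + Z @ b_k
    return float(out[0]) if np.isscalar(t) else out


def _linear_predictor(spec: JointModelSpec, params: Params, b_i, t,
                      patient: PatientEventRecord, encounter_ages=None):
    """log h_i(t) at (vector of) ages t."""
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    b_i = np.asarray(b_i, dtype=float)
    eta = spec.baseline.log_h0(t_arr, params.baseline_coef).copy()
    if spec.event_covariates:
        from .design import covariate_matrix
        W = covariate_matrix(patient, spec.event_covariates, t_arr, encounter_ages)
        eta = eta + W @ params.gamma
    centers = spec.centers
    for k, (s, sl) in enumerate(zip(spec.submodels, spec.b_slices)):
        m = longitudinal_mean(s, params.betas[k], b_i[sl], t_arr, patient,
                              encounter_ages)
        if not np.all(np.isfinite(m)):
            bad = t_arr[~np.isfinite(np.atleast_1d(m))][0]
            raise NumericalError(
                f"non-finite {s.outcome_name} mean at age {bad}")
        eta = eta + params.assoc[k] * (np.atleast_1d(m) - centers[k])
    return eta


def hazard(spec: JointModelSpec, params: Params, b_i, t,
           patient: PatientEventRecord, encounter_ages=None):
    """Instantaneous event hazard h_i(t) (events per year); always > 0."""
    eta = _linear_predictor(spec, params, b_i, t, patient, encounter_ages)
    out = np.exp(eta)
    return float(out[0]) if np.isscalar(t) else out


def _switch_breakpoints(patient: PatientEventRecord, t0: float, t1: float,
                        max_piece: float = 2.0):
    """Quadrature piece edges: covariate switch ages, then subdivision of
    long pieces so no piece exceeds ``max_piece`` years."""
    pts = [a for a in patient.covariate_switch_ages.values()
           if a is not None and t0 < a < t1]
    edges = sorted({t0, t1, *pts})
    out = []
    for a, b in zip(edges[:-1], edges[1:]):
        n_sub = max(1, int(np.ceil((b - a) / max_piece)))
        out.extend(a + (b - a) * np.arange(n_sub) / n_sub)
    out.append(edges[-1])
    return np.array(out)


def cumulative_hazard(spec: JointModelSpec, params: Params, b_i,
                      t0: float, t1: float, patient: PatientEventRecord,
                      encounter_ages=None) -> float:
    """Integral of the hazard over [t0, t1] by piecewise Gauss-Legendre.

    The integration interval is split at covariate switch ages so the
    integrand is smooth on every piece; 15-node quadrature per piece.
    """
    if t0 > t1:
        raise ParameterError("t0 must be <= t1")
    if t0 == t1:
        return 0.0
    edges = _switch_breakpoints(patient, t0, t1)
    total = 0.0
    for a, b in zip(edges[:-1], edges[1:]):
        half = 0.5 * (b - a)
        nodes = a + half * (_GL_NODES + 1.0)
        h = hazard(spec, params, b_i, nodes, patient, encounter_ages)
        total += half * float(_GL_WEIGHTS @ h)
    return total


def survival_probability(spec: JointModelSpec, params: Params, b_i,
                         t0: float, t1: float, patient: PatientEventRecord,
                         encounter_ages=None) -> float:
    """S_i(t1 | t0) = exp(-integral of hazard); 1 when t0 == t1."""
    return float(np.exp(-cumulative_hazard(spec, params, b_i, t0, t1,
                                           patient, encounter_ages)))


def _patient_tables(cohort: CohortData):
    """Group observations by (patient, outcome) once."""
    obs: dict[str, dict[str, list[tuple[float, float]]]] = {}
    for o in cohort.observations:
        obs.setdefault(o.patient_id, {}).setdefault(o.outcome_name, []).append(
            (o.age, o.value))
    enc = {pid: np.array(sorted({a for per in byout.values() for a, _ in per}))
           for pid, byout in obs.items()}
    return obs, enc


def _patient_complete_loglik(spec, params, b_i, patient, obs_by_outcome,
                             encounter_ages, include_re_prior=True) -> float:
    ll = 0.0
    for k, (s, sl) in enumerate(zip(spec.submodels, spec.b_slices)):
        pairs = obs_by_outcome.get(s.outcome_name, [])
        if pairs:
            ages = np.array([a for a, _ in pairs])
            y = np.array([v for _, v in pairs])
            m = longitudinal_mean(s, params.betas[k], b_i[sl], ages, patient,
                                  encounter_ages)
            sig = params.sigmas[k]
            ll += float(np.sum(-0.5 * np.log(2 * np.pi) - np.log(sig)
                               - 0.5 * ((y - m) / sig) ** 2))
    eta_T = _linear_predictor(spec, params, b_i, patient.exit_age, patient,
                              encounter_ages)[0]
    ll += patient.event * float(eta_T)
    ll -= cumulative_hazard(spec, params, b_i, patient.entry_age,
                            patient.exit_age, patient, encounter_ages)
    if include_re_prior:
        ll += multivariate_normal.logpdf(b_i, mean=np.zeros(spec.n_random_total),
                                         cov=params.re_cov)
    return ll


def complete_data_log_likelihood(spec: JointModelSpec, params: Params,
                                 b: np.ndarray, cohort: CohortData) -> float:
    """Joint log density of data and random effects.

    ``b`` is an ``(n_patients, q_total)`` array aligned with
    ``cohort.patients``. The value is the sum over patients of the
    longitudinal normal terms, the event term ``delta * log h_i(T) -
    Lambda_i(entry, T)`` (delayed entry: integration starts at entry), and
    the multivariate-normal random-effects density.
    """
    b = np.atleast_2d(np.asarray(b, dtype=float))
    eigmin = np.linalg.eigvalsh(params.re_cov).min()
    if eigmin <= 0:
        raise ParameterError("random-effects covariance must be positive definite")
    obs, enc = _patient_tables(cohort)
    total = 0.0
    for i, p in enumerate(cohort.patients):
        total += _patient_complete_loglik(
            spec, params, b[i], p, obs.get(p.patient_id, {}),
            enc.get(p.patient_id, np.empty(0)))
    return total


@dataclass(frozen=True)
class GaussHermiteControl:
    """Settings for the adaptive Gauss-Hermite marginalisation."""

    order: int = 9

    def __post_init__(self) -> None:
        if self.order < 2:
            raise ParameterError("quadrature order must be >= 2")


def marginal_log_likelihood(spec: JointModelSpec, params: Params,
                            cohort: CohortData,
                            control: GaussHermiteControl | None = None) -> float:
    """Observed-data log likelihood with random effects integrated out.

    Per patient, the integrand is recentred at the conditional mode of the
    random effects and rescaled by the inverse Hessian there (adaptive
    Gauss-Hermite with a product rule); practical up to ~6 random-effect
    dimensions.
    """
    control = control or GaussHermiteControl()
    q = spec.n_random_total
    nodes1, weights1 = np.polynomial.hermite_e.hermegauss(control.order)
    # probabilists' nodes: integral f(x) exp(-x^2/2) dx = sum w f(x)
    grids = np.meshgrid(*([nodes1] * q), indexing="ij")
    xi = np.column_stack([g.ravel() for g in grids])          # (n_nodes, q)
    logw = np.sum(np.log(np.meshgrid(*([weights1] * q), indexing="ij")),
                  axis=0).ravel()
    obs, enc = _patient_tables(cohort)
    total = 0.0
    for p in cohort.patients:
        byout = obs.get(p.patient_id, {})
        eages = enc.get(p.patient_id, np.empty(0))

        def negf(b):
            return -_patient_complete_loglik(spec, params, b, p, byout, eages)

        res = minimize(negf, np.zeros(q), method="Nelder-Mead",
                       options={"xatol": 1e-5, "fatol": 1e-7, "maxiter": 2000})
        res = minimize(negf, res.x, method="BFGS",
                       options={"gtol": 1e-6, "maxiter": 200})
        mode = res.x
        H = _numerical_hessian(negf, mode)
        # guard against non-PD numerical Hessians
        evals, evecs = np.linalg.eigh(H)
        evals = np.maximum(evals, 1e-6)
        H = evecs @ np.diag(evals) @ evecs.T
        L = np.linalg.cholesky(np.linalg.inv(H))
        pts = mode + xi @ L.T
        fvals = np.array([-negf(b) for b in pts])
        # int e^{f} db = |L| * sum_j w_j e^{f(mode + L xi_j) + |xi_j|^2 / 2}
        total += logsumexp(fvals + 0.5 * np.sum(xi ** 2, axis=1) + logw) \
            + np.log(np.abs(np.linalg.det(L)))
    return float(total)


def _numerical_hessian(f, x, eps: float = 1e-4) -> np.ndarray:
    q = x.size
    H = np.zeros((q, q))
    f0 = f(x)
    for i in range(q):
        for j in range(i + 1):
            ei = np.zeros(q); ei[i] = eps
            ej = np.zeros(q); ej[j] = eps
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * eps ** 2)
    return H
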