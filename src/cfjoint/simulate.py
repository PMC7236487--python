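"""Synthetic registry generator.

Emulates the statistical structure of a paediatric CF registry cohort
followed from age 6 to 20: irregular clinical encounters, declining FEV1
(% predicted) with large between- and within-patient variability, growth
percentiles in [0, 100], acquired binary covariates that switch on and stay
on (MRSA, Pa, CFRD, pancreatic enzymes), baseline covariate frequencies
near published registry values, and first-exacerbation times drawn from the
joint model's own hazard by inverse-transform sampling.

Ground-truth parameters are returned in exactly the layout the estimation
module uses, so parameter-recovery studies compare like with like. Default
trajectory levels are anchored to the registry's baseline medians (FEV1
~90% predicted, BMIp ~49th percentile at entry); rates of decline are free
parameters of the generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .cohort import (BIRTH_COHORTS, GENOTYPES, CohortData,
                     LongitudinalObservation, PatientEventRecord)
from .errors import NumericalError, ParameterError
from .model import (JointModelSpec, LongitudinalSubmodelSpec, ParameterVector,
                    Params, SplineLogHazard, WeibullLogHazard)
from .splines import LogHazardBasis, SplineBasisSpec, build_spline_basis

__all__ = [
    "OutcomeSimConfig", "SimulationConfig", "default_config",
    "simulate_cohort", "simulate_event_time", "simulate_visit_schedule",
]

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(15)

#: Table-1-style baseline covariate frequencies (overall column).
DEFAULT_BASELINE_FREQUENCIES = {
    "male": 0.516,
    "hispanic": 0.087,
    "low_ses": 0.498,
    "genotype": {"homozygous": 0.481, "heterozygous": 0.382,
                 "none_unknown": 0.137},
    "birth_cohort": {"<1981": 0.188, "1981-1989": 0.253, "1990-1994": 0.166,
                     "1995-1999": 0.261, ">1999": 0.132},
}

#: probability the covariate is already on at entry, and yearly onset rate
DEFAULT_SWITCH = {
    "mrsa": (0.074, 0.020),
    "pa": (0.196, 0.040),
    "cfrd": (0.039, 0.015),
    "enzymes": (0.390, 0.050),
}

DEFAULT_EVENT_EFFECTS = {
    "sex": 0.15, "ses": 0.10, "mrsa": 0.25, "pa": 0.20,
    "cfrd": 0.30, "enzymes": 0.20,
}

_DEFAULT_CURVES = {
    "FEV1": ((6.0, 97.0), (10.0, 93.0), (14.0, 86.0), (20.0, 74.0)),
    "BMIp": ((6.0, 52.0), (13.0, 49.0), (20.0, 45.0)),
    "WFA": ((6.0, 40.0), (13.0, 36.0), (20.0, 32.0)),
    "HFA": ((6.0, 34.0), (13.0, 31.0), (20.0, 28.0)),
}
_DEFAULT_OUTCOME_NUMBERS = {
    # sd_intercept, sd_slope, residual_sd
    "FEV1": (13.0, 1.2, 7.0),
    "BMIp": (24.0, 1.5, 9.0),
    "WFA": (24.0, 1.5, 8.0),
    "HFA": (24.0, 1.2, 8.0),
}
_DEFAULT_COV_EFFECTS = {
    "FEV1": {"sex": -1.0, "enzymes": -3.0},
    "BMIp": {"enzymes": -4.0},
    "WFA": {"enzymes": -4.0},
    "HFA": {"enzymes": -2.0},
}
_DEFAULT_CENTERS = {"FEV1": 90.0, "BMIp": 50.0, "WFA": 50.0, "HFA": 50.0}


@dataclass(frozen=True)
class OutcomeSimConfig:
    """Generator settings for one longitudinal outcome.

    The population mean trajectory is given as (age, value) control points
    and projected onto the model's own natural-spline basis, so generator
    and fitter share a single basis code path.
    """

    name: str
    mean_curve: tuple[tuple[float, float], ...]
    covariate_effects: dict = field(default_factory=dict)
    sd_intercept: float = 12.0
    sd_slope: float = 1.0
    intercept_slope_corr: float = -0.2
    residual_sd: float = 7.0

    def __post_init__(self) -> None:
        if self.sd_intercept < 0 or self.sd_slope < 0 or self.residual_sd < 0:
            raise ParameterError("standard deviations must be >= 0")
        if not -1.0 < self.intercept_slope_corr < 1.0:
            raise ParameterError("correlation must lie in (-1, 1)")


@dataclass(frozen=True)
class SimulationConfig:
    """Full generator configuration; see the methods note for rationale."""

    n_patients: int = 300
    outcomes: tuple[OutcomeSimConfig, ...] = ()
    eligibility_window: tuple[float, float] = (6.0, 20.0)
    visit_rate: float = 4.0
    baseline_frequencies: dict = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_FREQUENCIES))
    switch_processes: dict = field(default_factory=lambda: dict(DEFAULT_SWITCH))
    event_effects: dict = field(default_factory=lambda: dict(DEFAULT_EVENT_EFFECTS))
    association: dict = field(default_factory=lambda: {"FEV1": -0.03})
    association_centers: dict = field(default_factory=lambda: dict(_DEFAULT_CENTERS))
    cross_intercept_corr: float = 0.35
    #: family is "weibull" (shape, scale) or "logspline" (coefficients)
    #: default calibrated so ~1/3 of patients have an observed event
    baseline_hazard: tuple = ("weibull", 3.5, 18.0)
    dropout_rate: float = 0.25
    spline_df: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ParameterError("n_patients must be >= 1")
        if self.visit_rate <= 0:
            raise ParameterError("visit_rate must be > 0")
        if self.dropout_rate < 0:
            raise ParameterError("dropout_rate must be >= 0")
        for key in ("male", "hispanic", "low_ses"):
            p = self.baseline_frequencies[key]
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"frequency {key!r} outside [0, 1]")
        for name, (p0, rate) in self.switch_processes.items():
            if not 0.0 <= p0 <= 1.0 or rate < 0:
                raise ParameterError(f"invalid switch process for {name!r}")

    # -- derived model objects ---------------------------------------------
    def spline_spec(self) -> SplineBasisSpec:
        lo, hi = self.eligibility_window
        n_int = self.spline_df - 1
        interior = tuple(lo + (hi - lo) * np.arange(1, n_int + 1) / (n_int + 1))
        return SplineBasisSpec(self.spline_df, (lo, hi), interior)

    def model_spec(self) -> JointModelSpec:
        """The joint-model specification this generator realises."""
        spline = self.spline_spec()
        subs = tuple(
            LongitudinalSubmodelSpec(
                outcome_name=o.name, spline=spline,
                covariates=tuple(o.covariate_effects.keys()),
                random_structure="intercept_slope",
                residual_sd=o.residual_sd or None)
            for o in self.outcomes
        )
        if self.baseline_hazard[0] == "weibull":
            baseline = WeibullLogHazard()
        else:
            baseline = SplineLogHazard(LogHazardBasis(
                n_basis=len(self.baseline_hazard) - 1,
                boundary=self.eligibility_window))
        centers = tuple(self.association_centers.get(o.name, 0.0)
                        for o in self.outcomes)
        return JointModelSpec(
            submodels=subs,
            event_covariates=tuple(self.event_effects.keys()),
            association_centers=centers,
            baseline=baseline,
        )

    def random_effects_covariance(self) -> np.ndarray:
        blocks = []
        for o in self.outcomes:
            c = o.intercept_slope_corr * o.sd_intercept * o.sd_slope
            blocks.append(np.array([[o.sd_intercept ** 2, c],
                                    [c, o.sd_slope ** 2]]))
        q = 2 * len(self.outcomes)
        cov = np.zeros((q, q))
        for k, blk in enumerate(blocks):
            cov[2 * k:2 * k + 2, 2 * k:2 * k + 2] = blk
        for k in range(len(self.outcomes)):
            for j in range(k):
                c = (self.cross_intercept_corr
                     * self.outcomes[k].sd_intercept
                     * self.outcomes[j].sd_intercept)
                cov[2 * k, 2 * j] = cov[2 * j, 2 * k] = c
        if np.linalg.eigvalsh(cov).min() < -1e-9:
            raise ParameterError("random-effects covariance is not PSD")
        return cov

    def true_parameters(self) -> tuple[JointModelSpec, ParameterVector]:
        spec = self.model_spec()
        lo, hi = self.eligibility_window
        grid = np.linspace(lo, hi, 200)
        X = np.column_stack([np.ones(grid.size),
                             build_spline_basis(grid, self.spline_spec())])
        betas = []
        for o, sub in zip(self.outcomes, spec.submodels):
            ages = np.array([a for a, _ in o.mean_curve])
            vals = np.array([v for _, v in o.mean_curve])
            target = np.interp(grid, ages, vals)
            curve_coef, *_ = np.linalg.lstsq(X, target, rcond=None)
            eff = np.array([o.covariate_effects[c] for c in sub.covariates])
            betas.append(np.concatenate([curve_coef, eff]))
        sigmas = np.array([max(o.residual_sd, 1e-8) for o in self.outcomes])
        cov = self.random_effects_covariance()
        # keep the packed covariance strictly PD for downstream validation
        cov = cov + 1e-10 * np.eye(cov.shape[0])
        gamma = np.array([self.event_effects[c] for c in spec.event_covariates])
        assoc = np.array([self.association.get(o.name, 0.0)
                          for o in self.outcomes])
        if self.baseline_hazard[0] == "weibull":
            shape, scale = self.baseline_hazard[1:]
            baseline_coef = np.array([np.log(shape), np.log(scale)])
        else:
            baseline_coef = np.asarray(self.baseline_hazard[1:], dtype=float)
        params = Params(betas, sigmas, cov, gamma, assoc, baseline_coef)
        return spec, ParameterVector.pack(spec, params)


def default_config(n_patients: int = 300,
                   outcomes: tuple[str, ...] = ("FEV1", "BMIp"),
                   seed: int = 0, **overrides) -> SimulationConfig:
    """Study-condition defaults for the named outcomes."""
    out = tuple(
        OutcomeSimConfig(
            name=name, mean_curve=_DEFAULT_CURVES[name],
            covariate_effects=dict(_DEFAULT_COV_EFFECTS[name]),
            sd_intercept=_DEFAULT_OUTCOME_NUMBERS[name][0],
            sd_slope=_DEFAULT_OUTCOME_NUMBERS[name][1],
            residual_sd=_DEFAULT_OUTCOME_NUMBERS[name][2],
        )
        for name in outcomes
    )
    assoc = {"FEV1": -0.03}
    return SimulationConfig(n_patients=n_patients, outcomes=out,
                            association=overrides.pop("association", assoc),
                            seed=seed, **overrides)


# --------------------------------------------------------------------------
# event-time sampling
# --------------------------------------------------------------------------

def simulate_event_time(hazard_fn, entry_age: float, max_age: float, rng,
                        breakpoints=()) -> tuple[float, int]:
    """Inverse-transform event time for one subject.

    Draws ``E ~ Exponential(1)`` and solves ``Lambda(T) - Lambda(entry) = E``
    on the cumulative hazard computed by piecewise Gauss-Legendre
    quadrature (pieces split at ``breakpoints`` and yearly). Returns
    ``(max_age, 0)`` when no solution exists below ``max_age``.
    """
    if max_age <= entry_age:
        return max_age, 0
    target = rng.exponential(1.0)
    inner = sorted(b for b in breakpoints if entry_age < b < max_age)

    def piece(a, b):
        half = 0.5 * (b - a)
        nodes = a + half * (_GL_NODES + 1.0)
        h = np.asarray(hazard_fn(nodes), dtype=float)
        if not np.all(np.isfinite(h)):
            bad = nodes[~np.isfinite(h)][0]
            raise NumericalError(f"non-finite hazard at age {bad}")
        return half * float(_GL_WEIGHTS @ h)

    # walk yearly segments (split further at breakpoints) without
    # materialising a grid: max_age may be effectively infinite
    cum, a = 0.0, entry_age
    bp_iter = iter(inner + [np.inf])
    next_bp = next(bp_iter)
    while a < max_age:
        b = min(a + 1.0, max_age)
        while next_bp <= a:
            next_bp = next(bp_iter)
        if next_bp < b:
            b = next_bp
        inc = piece(a, b)
        if cum + inc >= target:
            resid = target - cum
            if piece(a, a + 1e-9) >= resid:      # event essentially at a
                return float(a + 1e-9), 1
            t = brentq(lambda u: piece(a, u) - resid, a + 1e-12, b,
                       xtol=1e-10)
            return float(t), 1
        cum += inc
        a = b
    return float(max_age), 0


def simulate_visit_schedule(entry_age: float, exit_age: float,
                            visit_rate: float, rng) -> np.ndarray:
    """Encounter ages: first at entry, then exponential gaps (renewal)."""
    if exit_age <= entry_age:
        raise ParameterError("exit_age must exceed entry_age")
    if visit_rate <= 0:
        raise ParameterError("visit_rate must be > 0")
    ages = [entry_age]
    t = entry_age
    while True:
        t = t + rng.exponential(1.0 / visit_rate)
        if t > exit_age:
            break
        ages.append(t)
    return np.array(ages)


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------

def _draw_category(rng, table: dict) -> str:
    names = list(table.keys())
    probs = np.array([table[n] for n in names], dtype=float)
    probs = probs / probs.sum()
    return names[rng.choice(len(names), p=probs)]


def simulate_cohort(config: SimulationConfig,
                    seed: int | None = None) -> tuple[CohortData, ParameterVector]:
    """Generate a cohort and the ground truth that produced it.

    Per patient: draw baseline covariates and an entry age, acquire the
    switch covariates, draw correlated random effects, sample the first
    exacerbation age from the model's own hazard (delayed entry respected),
    censor at dropout or the upper eligibility age, and record noisy
    biomarker values at an irregular visit schedule starting at entry.
    """
    if not config.outcomes:
        raise ParameterError("at least one outcome must be configured")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    spec, truth = config.true_parameters()
    params = truth.unpack(spec)
    lo, hi = config.eligibility_window
    freqs = config.baseline_frequencies

    patients: list[PatientEventRecord] = []
    observations: list[LongitudinalObservation] = []
    n_digits = len(str(config.n_patients))

    for i in range(config.n_patients):
        pid = f"P{i:0{n_digits}d}"
        base = {
            "sex": int(rng.random() < freqs["male"]),
            "hispanic": int(rng.random() < freqs["hispanic"]),
            "ses": int(rng.random() < freqs["low_ses"]),
            "genotype": _draw_category(rng, freqs["genotype"]),
            "birth_cohort": _draw_category(rng, freqs["birth_cohort"]),
        }
        entry = lo + (hi - 1.0 - lo) * rng.beta(0.7, 2.2)
        censor = hi if config.dropout_rate == 0 else min(
            hi, entry + 0.05 + rng.exponential(1.0 / config.dropout_rate))

        switch = {}
        for name, (p0, rate) in config.switch_processes.items():
            if rng.random() < p0:
                switch[name] = float(entry)
            elif rate > 0:
                onset = entry + rng.exponential(1.0 / rate)
                if onset < hi:
                    switch[name] = float(onset)

        record = PatientEventRecord(pid, entry, max(censor, entry + 0.05), 0,
                                    base, switch)
        b_i = rng.multivariate_normal(np.zeros(params.re_cov.shape[0]),
                                      params.re_cov,
                                      method="cholesky")

        from .model import _linear_predictor  # shared hazard code path

        def hazard_fn(ages, _rec=record, _b=b_i):
            return np.exp(_linear_predictor(spec, params, _b, ages, _rec))

        event_age, delta = simulate_event_time(
            hazard_fn, entry, censor, rng,
            breakpoints=tuple(switch.values()))
        exit_age = max(event_age, entry + 0.02)
        record = PatientEventRecord(pid, entry, exit_age, delta, base, switch)

        visits = simulate_visit_schedule(entry, exit_age, config.visit_rate, rng)
        for k, (o, sub, sl) in enumerate(zip(config.outcomes, spec.submodels,
                                             spec.b_slices)):
            X = sub.fixed_row(record, visits)
            Z = sub.random_row(visits)
            m = X @ params.betas[k] + Z @ b_i[sl]
            y = m if o.residual_sd == 0 else m + rng.normal(
                0.0, o.residual_sd, size=visits.size)
            if o.name == "FEV1":
                y = np.maximum(y, 1.0)
            else:
                y = np.clip(y, 0.0, 100.0)
            observations.extend(
                LongitudinalObservation(pid, float(t), o.name, float(v))
                for t, v in zip(visits, y))
        patients.append(record)

    return CohortData(observations=observations, patients=patients), truth
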