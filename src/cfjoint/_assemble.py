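"""Vectorised data assembly for the MCMC sampler.

The sampler never touches :class:`CohortData` directly: this module turns a
cohort plus a resolved :class:`JointModelSpec` into flat arrays — stacked
longitudinal designs with per-patient cross-products, and stacked
Gauss-Legendre quadrature nodes for every patient's at-risk interval
(pieces split at covariate switch ages) — so each Gibbs sweep is a handful
of matrix products.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import CohortData
from .design import covariate_matrix
from .model import (JointModelSpec, SplineLogHazard, WeibullLogHazard,
                    _switch_breakpoints)

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(15)


@dataclass
class OutcomeBlock:
    name: str
    y: np.ndarray          # (n_obs,)
    X: np.ndarray          # (n_obs, p)
    Z: np.ndarray          # (n_obs, q_k)
    pat: np.ndarray        # (n_obs,) patient index
    XtX: np.ndarray        # (p, p)
    ZtZ: np.ndarray        # (N, q_k, q_k)
    ZtX: np.ndarray        # (N, q_k, p)
    Zty: np.ndarray        # (N, q_k)
    Xnod: np.ndarray       # (M, p)  design at survival quadrature nodes
    Znod: np.ndarray       # (M, q_k)
    Xexit: np.ndarray      # (N, p)  design at exit age
    Zexit: np.ndarray      # (N, q_k)


@dataclass
class SurvBlock:
    pat_nod: np.ndarray    # (M,)
    w_nod: np.ndarray      # (M,) quadrature weights (already scaled)
    age_nod: np.ndarray    # (M,)
    W_nod: np.ndarray      # (M, n_gamma) event-covariate design at nodes
    W_exit: np.ndarray     # (N, n_gamma)
    B_nod: np.ndarray | None   # (M, nb) spline baseline design (None: Weibull)
    B_exit: np.ndarray | None
    delta: np.ndarray      # (N,)
    entry: np.ndarray
    exit: np.ndarray


@dataclass
class FitData:
    spec: JointModelSpec
    patient_ids: list[str]
    outcomes: list[OutcomeBlock]
    surv: SurvBlock
    N: int

    def log_h0_nodes(self, coef) -> np.ndarray:
        if self.surv.B_nod is not None:
            return self.surv.B_nod @ coef
        return self.spec.baseline.log_h0(self.surv.age_nod, coef)

    def log_h0_exit(self, coef) -> np.ndarray:
        if self.surv.B_exit is not None:
            return self.surv.B_exit @ coef
        return self.spec.baseline.log_h0(self.surv.exit, coef)


def assemble(cohort: CohortData, spec: JointModelSpec) -> FitData:
    spec = spec.resolve(cohort)
    patients = cohort.patients
    N = len(patients)
    index = {p.patient_id: i for i, p in enumerate(patients)}

    obs_by_out: dict[str, list[tuple[int, float, float]]] = {
        s.outcome_name: [] for s in spec.submodels}
    enc_ages: dict[int, set[float]] = {i: set() for i in range(N)}
    for o in cohort.observations:
        i = index.get(o.patient_id)
        if i is None:
            continue
        enc_ages[i].add(o.age)
        if o.outcome_name in obs_by_out:
            obs_by_out[o.outcome_name].append((i, o.age, o.value))
    enc_sorted = {i: np.array(sorted(a)) for i, a in enc_ages.items()}

    # ---- survival quadrature nodes ---------------------------------------
    pat_nod, w_nod, age_nod = [], [], []
    for i, p in enumerate(patients):
        edges = _switch_breakpoints(p, p.entry_age, p.exit_age)
        for a, b in zip(edges[:-1], edges[1:]):
            half = 0.5 * (b - a)
            pat_nod.extend([i] * _GL_NODES.size)
            age_nod.append(a + half * (_GL_NODES + 1.0))
            w_nod.append(half * _GL_WEIGHTS)
    pat_nod = np.array(pat_nod, dtype=np.intp)
    age_nod = np.concatenate(age_nod)
    w_nod = np.concatenate(w_nod)

    # event-covariate designs (time-varying covariates evaluated per node)
    n_gamma = len(spec.event_covariates)
    W_nod = np.empty((age_nod.size, n_gamma))
    W_exit = np.empty((N, n_gamma))
    for i, p in enumerate(patients):
        mask = pat_nod == i
        if n_gamma:
            W_nod[mask] = covariate_matrix(p, spec.event_covariates,
                                           age_nod[mask], enc_sorted[i])
            W_exit[i] = covariate_matrix(p, spec.event_covariates,
                                         [p.exit_age], enc_sorted[i])[0]
    if isinstance(spec.baseline, SplineLogHazard):
        B_nod = spec.baseline.design(age_nod)
        B_exit = spec.baseline.design(np.array([p.exit_age for p in patients]))
    else:
        B_nod = B_exit = None

    surv = SurvBlock(
        pat_nod=pat_nod, w_nod=w_nod, age_nod=age_nod,
        W_nod=W_nod, W_exit=W_exit, B_nod=B_nod, B_exit=B_exit,
        delta=np.array([p.event for p in patients], dtype=float),
        entry=np.array([p.entry_age for p in patients]),
        exit=np.array([p.exit_age for p in patients]),
    )

    # ---- longitudinal blocks ---------------------------------------------
    blocks = []
    exit_ages = surv.exit
    for s in spec.submodels:
        rows = obs_by_out[s.outcome_name]
        pat = np.array([r[0] for r in rows], dtype=np.intp)
        ages = np.array([r[1] for r in rows])
        y = np.array([r[2] for r in rows])
        p_fix, q_k = s.n_fixed, s.n_random
        X = np.empty((pat.size, p_fix))
        Xnod = np.empty((age_nod.size, p_fix))
        Xexit = np.empty((N, p_fix))
        for i, p in enumerate(patients):
            m_obs = pat == i
            if m_obs.any():
                X[m_obs] = s.fixed_row(p, ages[m_obs], enc_sorted[i])
            m_nod = pat_nod == i
            Xnod[m_nod] = s.fixed_row(p, age_nod[m_nod], enc_sorted[i])
            Xexit[i] = s.fixed_row(p, [exit_ages[i]], enc_sorted[i])[0]
        Z = s.random_row(ages)
        Znod = s.random_row(age_nod)
        Zexit = s.random_row(exit_ages)

        ZtZ = np.zeros((N, q_k, q_k))
        ZtX = np.zeros((N, q_k, p_fix))
        Zty = np.zeros((N, q_k))
        np.add.at(ZtZ, pat, Z[:, :, None] * Z[:, None, :])
        np.add.at(ZtX, pat, Z[:, :, None] * X[:, None, :])
        np.add.at(Zty, pat, Z * y[:, None])

        blocks.append(OutcomeBlock(
            name=s.outcome_name, y=y, X=X, Z=Z, pat=pat, XtX=X.T @ X,
            ZtZ=ZtZ, ZtX=ZtX, Zty=Zty, Xnod=Xnod, Znod=Znod,
            Xexit=Xexit, Zexit=Zexit))

    return FitData(spec=spec, patient_ids=[p.patient_id for p in patients],
                   outcomes=blocks, surv=surv, N=N)
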