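"""Model-core contracts: means, hazard, quadrature, likelihoods."""

import numpy as np
import pytest

from cfjoint import (GaussHermiteControl, JointModelSpec,
                     LongitudinalSubmodelSpec, ParameterVector, Params,
                     SplineLogHazard, WeibullLogHazard,
                     complete_data_log_likelihood, cumulative_hazard,
                     default_config, hazard, longitudinal_mean,
                     marginal_log_likelihood, simulate_cohort,
                     survival_probability)
from cfjoint.cohort import CohortData, PatientEventRecord
from cfjoint.errors import DimensionError, ParameterError
from cfjoint.splines import SplineBasisSpec


@pytest.fixture(scope="module")
def sim():
    cfg = default_config(n_patients=5, seed=3)
    cohort, truth = simulate_cohort(cfg)
    spec = cfg.model_spec()
    return cfg, cohort, truth, spec, truth.unpack(spec)


def _null_spec(center=0.0):
    """One-outcome model with no covariates and a Weibull baseline."""
    sub = LongitudinalSubmodelSpec("FEV1", SplineBasisSpec(1, (6., 20.), ()),
                                   (), (), "intercept_slope")
    return JointModelSpec((sub,), (), (center,), WeibullLogHazard())


def _record():
    return PatientEventRecord("X", 6.0, 18.0, 1,
                              {"genotype": "homozygous", "sex": 1,
                               "hispanic": 0, "ses": 0,
                               "birth_cohort": "<1981"}, {"pa": 11.0})


def test_longitudinal_mean_zero_and_shift(sim):
    *_, spec, params = sim
    sub = spec.submodels[0]
    zero = longitudinal_mean(sub, np.zeros(sub.n_fixed), np.zeros(2), 10.0,
                             _record())
    assert zero == 0.0
    base = longitudinal_mean(sub, params.betas[0], np.zeros(2), 10.0, _record())
    shifted = longitudinal_mean(sub, params.betas[0], np.array([3.5, 0.0]),
                                10.0, _record())
    assert shifted == pytest.approx(base + 3.5)


def test_longitudinal_mean_matches_dot_product(sim):
    *_, spec, params = sim
    rng = np.random.default_rng(1)
    sub = spec.submodels[0]
    beta = rng.normal(size=sub.n_fixed)
    b = rng.normal(size=sub.n_random)
    t = 13.7
    X = sub.fixed_row(_record(), [t])
    Z = sub.random_row([t])
    expected = float(X[0] @ beta + Z[0] @ b)
    assert longitudinal_mean(sub, beta, b, t, _record()) == pytest.approx(expected)
    with pytest.raises(DimensionError):
        longitudinal_mean(sub, beta[:-1], b, t, _record())


def test_hazard_null_association_equals_baseline():
    spec = _null_spec()
    params = Params([np.array([90.0, -10.0])], np.array([7.0]),
                    np.eye(2), np.zeros(0), np.array([0.0]),
                    np.array([np.log(2.0), np.log(15.0)]))
    t = 12.0
    h0 = np.exp(WeibullLogHazard().log_h0(np.array([t]),
                                          params.baseline_coef))[0]
    assert hazard(spec, params, np.array([25.0, -3.0]), t, _record()) == \
        pytest.approx(h0)


def test_hazard_ratio_per_unit_biomarker():
    """A one-unit rise in the error-free biomarker multiplies the hazard by
    exp(a): with a = -0.0305 the ratio is 0.97 after rounding."""
    spec = _null_spec(center=90.0)
    a1 = -0.0305
    params = Params([np.array([90.0, 0.0])], np.array([7.0]), np.eye(2),
                    np.zeros(0), np.array([a1]),
                    np.array([0.0, 0.0]))
    rec = _record()
    h_lo = hazard(spec, params, np.array([0.0, 0.0]), 12.0, rec)
    h_hi = hazard(spec, params, np.array([1.0, 0.0]), 12.0, rec)  # m + 1
    ratio = h_hi / h_lo
    assert ratio == pytest.approx(np.exp(a1), rel=1e-12)
    assert round(ratio, 2) == 0.97


def test_log_hazard_assembles_term_by_term(sim):
    *_, spec, params = sim
    rng = np.random.default_rng(4)
    b = rng.normal(size=spec.n_random_total)
    rec = _record()
    t = 14.2
    lh = np.log(hazard(spec, params, b, t, rec))
    expected = spec.baseline.log_h0(np.array([t]), params.baseline_coef)[0]
    from cfjoint.design import covariate_value
    for g, name in zip(params.gamma, spec.event_covariates):
        expected += g * covariate_value(rec, name, t)
    for k, (sub, sl) in enumerate(zip(spec.submodels, spec.b_slices)):
        m = longitudinal_mean(sub, params.betas[k], b[sl], t, rec)
        expected += params.assoc[k] * (m - spec.centers[k])
    assert lh == pytest.approx(expected, rel=1e-12)


def test_cumulative_hazard_constant_and_weibull():
    spec = _null_spec()
    # shape 1 Weibull: constant hazard 1/scale
    lam = 0.5
    params = Params([np.zeros(2)], np.array([7.0]), np.eye(2), np.zeros(0),
                    np.array([0.0]), np.array([0.0, -np.log(lam)]))
    rec = _record()
    ch = cumulative_hazard(spec, params, np.zeros(2), 6.0, 16.0, rec)
    assert ch == pytest.approx(lam * 10.0, rel=1e-12)
    # general Weibull closed form
    k, s = 2.3, 14.0
    params2 = Params([np.zeros(2)], np.array([7.0]), np.eye(2), np.zeros(0),
                     np.array([0.0]), np.array([np.log(k), np.log(s)]))
    ch2 = cumulative_hazard(spec, params2, np.zeros(2), 6.0, 18.0, rec)
    assert ch2 == pytest.approx((18 / s) ** k - (6 / s) ** k, rel=1e-8)
    with pytest.raises(ParameterError):
        cumulative_hazard(spec, params, np.zeros(2), 10.0, 9.0, rec)


def test_cumulative_hazard_matches_dense_trapezoid(sim):
    *_, spec, params = sim
    rec = _record()
    b = np.array([8.0, -0.7, -5.0, 0.4])
    ch = cumulative_hazard(spec, params, b, rec.entry_age, rec.exit_age, rec)
    grid = np.linspace(rec.entry_age, rec.exit_age, 100001)
    h = hazard(spec, params, b, grid, rec)
    assert ch == pytest.approx(np.trapezoid(h, grid), rel=1e-6)


def test_survival_probability_contracts(sim):
    *_, spec, params = sim
    rec = _record()
    b = np.zeros(spec.n_random_total)
    assert survival_probability(spec, params, b, 9.0, 9.0, rec) == 1.0
    s04 = survival_probability(spec, params, b, 6.0, 14.0, rec)
    s2 = (survival_probability(spec, params, b, 6.0, 10.0, rec)
          * survival_probability(spec, params, b, 10.0, 14.0, rec))
    assert abs(s04 - s2) < 1e-10
    # constant hazard closed form
    null = _null_spec()
    pc = Params([np.zeros(2)], np.array([7.0]), np.eye(2), np.zeros(0),
                np.array([0.0]), np.array([0.0, -np.log(0.1)]))
    assert survival_probability(null, pc, np.zeros(2), 8.0, 13.0, rec) == \
        pytest.approx(np.exp(-0.5), rel=1e-10)


def test_complete_data_loglik_factorises_and_doubles(sim):
    cfg, cohort, truth, spec, params = sim
    b = np.zeros((cohort.n_patients, spec.n_random_total))
    # null association: total = longitudinal-only + survival-only
    params0 = Params([v.copy() for v in params.betas], params.sigmas.copy(),
                     params.re_cov.copy(), params.gamma.copy(),
                     np.zeros_like(params.assoc), params.baseline_coef.copy())
    total = complete_data_log_likelihood(spec, params0, b, cohort)
    from scipy.stats import multivariate_normal, norm
    long_part, surv_part = 0.0, 0.0
    for i, p in enumerate(cohort.patients):
        for k, sub in enumerate(spec.submodels):
            pairs = [(o.age, o.value) for o in cohort.observations
                     if o.patient_id == p.patient_id
                     and o.outcome_name == sub.outcome_name]
            ages = np.array([a for a, _ in pairs])
            y = np.array([v for _, v in pairs])
            m = longitudinal_mean(sub, params0.betas[k], b[i][spec.b_slices[k]],
                                  ages, p, cohort.encounter_ages(p.patient_id))
            long_part += norm.logpdf(y, m, params0.sigmas[k]).sum()
        long_part += multivariate_normal.logpdf(
            b[i], np.zeros(spec.n_random_total), params0.re_cov)
        surv_part += p.event * np.log(hazard(spec, params0, b[i], p.exit_age, p,
                                             cohort.encounter_ages(p.patient_id)))
        surv_part -= cumulative_hazard(spec, params0, b[i], p.entry_age,
                                       p.exit_age, p,
                                       cohort.encounter_ages(p.patient_id))
    assert total == pytest.approx(long_part + surv_part, rel=1e-9)
    # duplication doubles the log likelihood
    doubled = CohortData(
        cohort.observations + [
            type(o)(o.patient_id + "_d", o.age, o.outcome_name, o.value)
            for o in cohort.observations],
        cohort.patients + [
            PatientEventRecord(p.patient_id + "_d", p.entry_age, p.exit_age,
                               p.event, p.baseline_covariates,
                               p.covariate_switch_ages)
            for p in cohort.patients])
    b2 = np.vstack([b, b])
    assert complete_data_log_likelihood(spec, params0, b2, doubled) == \
        pytest.approx(2 * total, rel=1e-9)


def test_marginal_loglik_matches_closed_form_lmm():
    """With null association the random effects integrate out in closed form
    (marginal multivariate normal); adaptive Gauss-Hermite must agree."""
    cfg = default_config(n_patients=4, seed=7, outcomes=("FEV1",),
                         association={"FEV1": 0.0})
    cohort, truth = simulate_cohort(cfg)
    spec = cfg.model_spec()
    params = truth.unpack(spec)
    gh = marginal_log_likelihood(spec, params, cohort, GaussHermiteControl(9))
    gh2 = marginal_log_likelihood(spec, params, cohort, GaussHermiteControl(15))
    assert gh == pytest.approx(gh2, abs=1e-4)   # order refinement stable
    from scipy.stats import multivariate_normal
    closed = 0.0
    for p in cohort.patients:
        sub = spec.submodels[0]
        pairs = [(o.age, o.value) for o in cohort.observations
                 if o.patient_id == p.patient_id]
        ages = np.array([a for a, _ in pairs])
        y = np.array([v for _, v in pairs])
        X = sub.fixed_row(p, ages, cohort.encounter_ages(p.patient_id))
        Z = sub.random_row(ages)
        V = Z @ params.re_cov @ Z.T + params.sigmas[0] ** 2 * np.eye(y.size)
        closed += multivariate_normal.logpdf(y, X @ params.betas[0], V)
        closed += p.event * np.log(hazard(spec, params, np.zeros(2),
                                          p.exit_age, p))
        closed -= cumulative_hazard(spec, params, np.zeros(2), p.entry_age,
                                    p.exit_age, p)
    assert gh == pytest.approx(closed, abs=1e-6)


def test_parameter_vector_round_trip(sim):
    *_, spec, params = sim
    vec = ParameterVector.pack(spec, params)
    back = vec.unpack(spec)
    again = ParameterVector.pack(spec, back)
    assert vec.names == again.names
    assert np.array_equal(vec.values, again.values)


def test_spec_json_round_trip(tmp_path, sim):
    *_, spec, _ = sim
    path = tmp_path / "model.json"
    spec.to_json(path)
    back = JointModelSpec.from_json(path)
    assert back == spec
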