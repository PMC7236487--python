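"""Synthetic-registry generator behaviour against closed-form oracles."""

import numpy as np
import pytest

from cfjoint import (default_config, simulate_cohort, simulate_event_time,
                     simulate_visit_schedule)
from cfjoint.errors import ParameterError
from cfjoint.simulate import SimulationConfig


def test_visit_schedule_determinism_and_degenerate():
    a = simulate_visit_schedule(8.0, 14.0, 4.0, np.random.default_rng(9))
    b = simulate_visit_schedule(8.0, 14.0, 4.0, np.random.default_rng(9))
    assert np.array_equal(a, b)
    assert a[0] == 8.0 and a[-1] <= 14.0
    tiny = simulate_visit_schedule(8.0, 8.0 + 1e-9, 4.0,
                                   np.random.default_rng(0))
    assert np.array_equal(tiny, [8.0])
    with pytest.raises(ParameterError):
        simulate_visit_schedule(8.0, 8.0, 4.0, np.random.default_rng(0))
    with pytest.raises(ParameterError):
        simulate_visit_schedule(8.0, 9.0, 0.0, np.random.default_rng(0))


def test_visit_schedule_renewal_mean():
    """Expected encounter count over T years at rate r is about 1 + r*T."""
    rng = np.random.default_rng(3)
    counts = [simulate_visit_schedule(6.0, 11.0, 4.0, rng).size
              for _ in range(400)]
    assert np.mean(counts) == pytest.approx(21.0, abs=3 * np.std(counts)
                                            / np.sqrt(len(counts)))


def test_event_time_zero_hazard_never_fires():
    rng = np.random.default_rng(1)
    t, d = simulate_event_time(lambda a: np.zeros(np.atleast_1d(a).size),
                               6.0, 20.0, rng)
    assert (t, d) == (20.0, 0)


def test_event_time_constant_hazard_mean():
    rng = np.random.default_rng(2)
    draws = np.array([
        simulate_event_time(lambda a: np.full(np.atleast_1d(a).size, 0.5),
                            0.0, 1e6, rng)[0]
        for _ in range(4000)])
    se = draws.std() / np.sqrt(draws.size)
    assert draws.mean() == pytest.approx(2.0, abs=3 * se)


def test_event_time_piecewise_constant_survival_curve():
    """Hazard 0.2 before age 10 and 0.8 after: empirical survival matches
    the piecewise-exponential closed form within Monte-Carlo bands."""
    rng = np.random.default_rng(4)

    def haz(ages):
        ages = np.atleast_1d(np.asarray(ages, dtype=float))
        return np.where(ages < 10.0, 0.2, 0.8)

    n = 4000
    draws = np.array([simulate_event_time(haz, 6.0, 200.0, rng,
                                          breakpoints=(10.0,))[0]
                      for _ in range(n)])

    def s_true(t):
        return np.exp(-0.2 * min(t - 6.0, 4.0) - 0.8 * max(t - 10.0, 0.0))

    for t in [7.0, 9.0, 10.5, 12.0, 14.0]:
        emp = np.mean(draws > t)
        s = s_true(t)
        band = 3 * np.sqrt(s * (1 - s) / n) + 1e-3
        assert abs(emp - s) < band, f"at age {t}: {emp} vs {s}"


def test_zero_residual_sd_gives_exact_trajectories():
    """With residual SDs of 0 every observation sits exactly on the
    patient's own (intercept+slope+spline) mean trajectory."""
    cfg = default_config(n_patients=20, seed=5)
    from dataclasses import replace
    cfg = replace(cfg, outcomes=tuple(replace(o, residual_sd=0.0)
                                      for o in cfg.outcomes),
                  visit_rate=8.0)
    cohort, truth = simulate_cohort(cfg)
    spec = cfg.model_spec()
    sub = spec.submodels[0]
    for p in cohort.patients:
        pairs = [(o.age, o.value) for o in cohort.observations
                 if o.patient_id == p.patient_id and o.outcome_name == "FEV1"]
        if len(pairs) < 8:
            continue
        ages = np.array([a for a, _ in pairs])
        y = np.array([v for _, v in pairs])
        X = np.hstack([sub.fixed_row(p, ages), sub.random_row(ages)])
        coef, res, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.allclose(X @ coef, y, atol=1e-8)


def test_cohort_structure_and_baseline_frequencies():
    """Male share near 51.6% and event-group FEV1 gap in a large cohort."""
    cfg = default_config(n_patients=5000, seed=12)
    cohort, truth = simulate_cohort(cfg)
    cohort.validate(outcomes=("FEV1", "BMIp"))
    male = np.mean([p.baseline_covariates["sex"] for p in cohort.patients])
    assert abs(male - 0.516) < 0.02

    # under a1 < 0, patients with events have lower baseline FEV1
    obs = cohort.observations_frame()
    first_fev = (obs[obs.outcome == "FEV1"]
                 .sort_values("age").groupby("patient_id")["value"].first())
    status = {p.patient_id: p.event for p in cohort.patients}
    ev = np.array([status[i] for i in first_fev.index])
    assert first_fev[ev == 1].mean() < first_fev[ev == 0].mean() - 1.0


def test_null_association_decouples_biomarker_and_event_time():
    cfg = default_config(n_patients=1500, seed=13,
                         association={"FEV1": 0.0, "BMIp": 0.0})
    cohort, _ = simulate_cohort(cfg)
    obs = cohort.observations_frame()
    first_fev = (obs[obs.outcome == "FEV1"]
                 .sort_values("age").groupby("patient_id")["value"].first())
    span = {p.patient_id: p.exit_age - p.entry_age for p in cohort.patients}
    x = first_fev.to_numpy()
    yv = np.array([span[i] for i in first_fev.index])
    corr = np.corrcoef(x, yv)[0, 1]
    assert abs(corr) < 0.08


def test_mean_event_time_monotone_in_association():
    means = []
    for a1 in (-0.1, -0.05, 0.0):
        cfg = default_config(n_patients=400, seed=77, association={"FEV1": a1},
                             dropout_rate=0.0)
        cohort, _ = simulate_cohort(cfg)
        exits = [p.exit_age for p in cohort.patients if p.event == 1]
        means.append(np.mean(exits))
    assert means[0] < means[1] < means[2]


def test_simulation_determinism_and_config_errors():
    cfg = default_config(n_patients=30, seed=21)
    c1, t1 = simulate_cohort(cfg)
    c2, t2 = simulate_cohort(cfg)
    assert c1.observations == c2.observations
    assert np.array_equal(t1.values, t2.values)
    with pytest.raises(ParameterError):
        default_config(n_patients=10, visit_rate=-1.0)
    with pytest.raises(ParameterError):
        default_config(n_patients=0)


def test_true_parameters_layout_matches_estimator():
    from cfjoint.model import parameter_names
    cfg = default_config(n_patients=10, seed=1)
    spec, truth = cfg.true_parameters()
    assert truth.names == parameter_names(spec)
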