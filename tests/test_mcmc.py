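"""Sampler behaviour: determinism, pooling, summaries, and correctness of
the Gibbs scheme against an independent sampler on the marginal likelihood."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import logsumexp

from cfjoint import (McmcControl, PosteriorSamples, Priors,
                     combine_shard_posteriors, default_config, fit_mcmc,
                     posterior_summary, simulate_cohort)
from cfjoint.errors import ParameterError, SchemaError
from cfjoint.model import (JointModelSpec, LongitudinalSubmodelSpec,
                           WeibullLogHazard, _switch_breakpoints)
from cfjoint.splines import SplineBasisSpec

_GLX, _GLW = np.polynomial.legendre.leggauss(15)


def test_seed_determinism_bit_identical():
    cfg = default_config(n_patients=40, seed=2)
    cohort, _ = simulate_cohort(cfg)
    spec = cfg.model_spec()
    ctrl = McmcControl(n_iterations=150, n_burn_in=100, seed=9)
    a = fit_mcmc(cohort, spec, control=ctrl)
    b = fit_mcmc(cohort, spec, control=ctrl)
    assert a.draws.equals(b.draws)


def test_combine_shard_draws():
    rng = np.random.default_rng(0)
    cols = ["a", "b"]
    base = pd.DataFrame(rng.normal(size=(100, 2)), columns=cols)
    fits = [PosteriorSamples(draws=base.copy(), shard_id=i) for i in range(3)]
    pooled = combine_shard_posteriors(fits)
    assert pooled.n_draws == 300
    assert np.allclose(pooled.draws.mean(), base.mean())   # identical shards
    assert np.array_equal(np.unique(pooled.shard_provenance), [0, 1, 2])
    bad = PosteriorSamples(draws=base.rename(columns={"a": "c"}))
    with pytest.raises(SchemaError):
        combine_shard_posteriors([fits[0], bad])
    with pytest.raises(ParameterError):
        combine_shard_posteriors([])


def test_posterior_summary_hpd_and_tail():
    rng = np.random.default_rng(5)
    draws = pd.DataFrame({"x": rng.normal(size=20000),
                          "c": np.full(20000, 2.5),
                          "neg": -np.abs(rng.normal(size=20000)) - 0.1})
    s = posterior_summary(PosteriorSamples(draws=draws))
    # symmetric unimodal: HPD close to equal-tailed quantiles
    assert s.loc["x", "hpd_low"] == pytest.approx(-1.96, abs=0.08)
    assert s.loc["x", "hpd_high"] == pytest.approx(1.96, abs=0.08)
    assert s.loc["c", "sd"] == 0.0
    assert s.loc["c", "hpd_low"] == s.loc["c", "hpd_high"] == 2.5
    assert s.loc["neg", "tail_prob"] == 0.0


def test_posterior_summary_warns_on_few_draws():
    draws = pd.DataFrame({"x": np.arange(20.0)})
    with pytest.warns(RuntimeWarning):
        posterior_summary(PosteriorSamples(draws=draws))


def _reduced_marginal_factory(cohort, spec, priors):
    """Vectorised marginal log posterior for the reduced model (one outcome,
    intercept-only random effect): independent of the Gibbs code path."""
    pats = []
    obsf = cohort.observations_frame()
    for p in cohort.patients:
        sel = obsf[obsf.patient_id == p.patient_id]
        ages = sel.age.to_numpy()
        y = sel.value.to_numpy()
        X = np.column_stack([np.ones(ages.size), (ages - 6.0) / 14.0])
        edges = _switch_breakpoints(p, p.entry_age, p.exit_age)
        qa, qw = [], []
        for a, b in zip(edges[:-1], edges[1:]):
            half = 0.5 * (b - a)
            qa.append(a + half * (_GLX + 1.0))
            qw.append(half * _GLW)
        qa, qw = np.concatenate(qa), np.concatenate(qw)
        Xq = np.column_stack([np.ones(qa.size), (qa - 6.0) / 14.0])
        XT = np.array([1.0, (p.exit_age - 6.0) / 14.0])
        pats.append((y, X, qa, qw, Xq, XT, p.exit_age, p.event))
    ghx, ghw = np.polynomial.hermite_e.hermegauss(31)
    center = spec.centers[0]

    def log_post(x):
        beta, sig = x[:2], np.exp(x[2])
        tau2, a, th = np.exp(x[3]), x[4], x[5:7]
        log_k, log_s = th
        k = np.exp(log_k)
        total = 0.0
        for (y, X, qa, qw, Xq, XT, T, delta) in pats:
            n = y.size
            resid = y - X @ beta
            prec = n / sig ** 2 + 1.0 / tau2
            mhat = (resid.sum() / sig ** 2) / prec
            sd = prec ** -0.5
            b = mhat + sd * ghx
            ll = (-0.5 * n * np.log(2 * np.pi * sig ** 2)
                  - 0.5 * np.sum((resid[:, None] - b[None, :]) ** 2, axis=0)
                  / sig ** 2)
            log_h0T = log_k - log_s + (k - 1) * (np.log(T) - log_s)
            log_hT = log_h0T + a * (XT @ beta - center + b)
            log_h0q = log_k - log_s + (k - 1) * (np.log(qa) - log_s)
            Lam0 = qw @ np.exp(log_h0q + a * (Xq @ beta - center))
            surv = delta * log_hT - Lam0 * np.exp(a * b)
            pri = -0.5 * np.log(2 * np.pi * tau2) - 0.5 * b ** 2 / tau2
            total += (logsumexp(ll + surv + pri + 0.5 * ghx ** 2 + np.log(ghw))
                      + np.log(sd))
        s2 = sig ** 2
        total += -0.5 * np.sum((beta / priors.beta_sd) ** 2)
        total += (-(priors.sigma2_shape + 1) * np.log(s2)
                  - priors.sigma2_rate / s2) + np.log(2 * s2)
        # 1x1 inverse-Wishart(df = 3, scale = 1) with log-variance Jacobian
        total += (-(1.5 + 1) * np.log(tau2) - 0.5 / tau2) + np.log(tau2)
        total += -0.5 * (a / priors.assoc_sd) ** 2
        total += -0.5 * np.sum((th / priors.baseline_sd) ** 2)
        return total

    return log_post


def test_gibbs_matches_independent_metropolis_on_marginal():
    """On a reduced joint model the blocked Gibbs sampler and a plain
    random-walk Metropolis on the marginalised posterior must agree."""
    cfg = default_config(n_patients=20, seed=42, outcomes=("FEV1",),
                         association={"FEV1": -0.03})
    cohort, _ = simulate_cohort(cfg)
    sub = LongitudinalSubmodelSpec("FEV1", SplineBasisSpec(1, (6., 20.), ()),
                                   (), (), "intercept")
    spec = JointModelSpec((sub,), (), (90.0,), WeibullLogHazard())
    priors = Priors()

    post = fit_mcmc(cohort, spec, priors,
                    McmcControl(n_iterations=3000, n_burn_in=1000, seed=1))
    gm = post.draws.mean()

    log_post = _reduced_marginal_factory(cohort, spec, priors)
    rng = np.random.default_rng(2)
    x = np.array([97.0, -20.0, np.log(7.0), np.log(150.0), -0.03,
                  np.log(3.5), np.log(18.0)])
    scales = np.array([2.0, 3.0, 0.08, 0.3, 0.012, 0.4, 0.12]) * 0.7
    cur = log_post(x)
    chain = []
    for it in range(14000):
        prop = x + scales * rng.standard_normal(7)
        lp = log_post(prop)
        if np.log(rng.random()) < lp - cur:
            x, cur = prop, lp
        if it > 3000:
            chain.append(x.copy())
    chain = np.array(chain)

    assert gm["FEV1.beta.intercept"] == pytest.approx(chain[:, 0].mean(),
                                                      abs=0.8)
    assert gm["FEV1.sigma"] == pytest.approx(np.exp(chain[:, 2]).mean(),
                                             abs=0.15)
    assert gm["re_cov[0,0]"] == pytest.approx(np.exp(chain[:, 3]).mean(),
                                              rel=0.25)
    assert gm["event.assoc.FEV1"] == pytest.approx(chain[:, 4].mean(),
                                                   abs=0.025)


def test_posterior_contraction_with_sample_size(small_cohort):
    """Doubling the cohort should shrink the posterior SD of the lung-
    function association by roughly sqrt(2)."""
    sds = {}
    for n, seed in ((150, 31), (600, 32)):
        cfg = default_config(n_patients=n, seed=seed)
        cohort, _ = simulate_cohort(cfg)
        post = fit_mcmc(cohort, cfg.model_spec(),
                        control=McmcControl(seed=77))
        sds[n] = posterior_summary(post).loc["event.assoc.FEV1", "sd"]
    ratio = sds[150] / sds[600]
    assert 1.3 < ratio < 2.9       # 2.0 expected, wide Monte-Carlo band
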