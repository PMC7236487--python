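"""Bayesian estimation by blocked Metropolis-within-Gibbs.

Update scheme per sweep:

* **Random effects** ``b_i`` — independence proposal from the exact
  Gaussian conditional implied by the longitudinal data and the
  random-effects prior; the Metropolis correction therefore reduces to the
  change in each patient's survival log likelihood. All patients are
  updated in one vectorised step.
* **Fixed effects** ``beta_k`` — same device at the block level: propose
  from the conjugate normal of the linear mixed model, correct for the
  survival term (the hazard depends on ``beta`` through ``m_k(t)``).
* **Residual variances** — conjugate inverse-gamma Gibbs draws.
* **Random-effects covariance** — conjugate inverse-Wishart Gibbs draw.
* **Survival block** (baseline-hazard coefficients, event covariates
  ``gamma``, associations ``a_k``) — adaptive random-walk Metropolis with
  the empirical-covariance proposal of Haario et al.; several sub-steps per
  sweep. Adaptation runs during burn-in only, so retained draws come from a
  fixed kernel.

Shard-pooled estimation follows the split/fit/pool strategy used for very
large registries: patients are partitioned into event-balanced shards, each
shard is fitted separately, and the retained draws are pooled (default:
simple concatenation, i.e. equal shard weighting).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import invwishart

from ._assemble import FitData, assemble
from .cohort import CohortData, split_into_shards
from .errors import NumericalError, ParameterError, SchemaError
from .model import JointModelSpec, ParameterVector, Params, parameter_names

__all__ = [
    "McmcControl", "Priors", "PosteriorSamples", "fit_mcmc",
    "fit_sharded", "combine_shard_posteriors", "posterior_summary",
]


@dataclass(frozen=True)
class McmcControl:
    """Run-length and adaptation settings.

    The default 900 iterations with 600 burn-in mirrors the registry
    analysis this package emulates; 300 retained draws is marginal, which
    is why effective sample sizes and split-chain statistics are always
    attached to the result.
    """

    n_iterations: int = 900
    n_burn_in: int = 600
    thinning: int = 1
    seed: int = 0
    n_survival_substeps: int = 5
    store_random_effects: bool = False

    def __post_init__(self) -> None:
        if self.thinning < 1:
            raise ParameterError("thinning must be >= 1")
        if not self.n_burn_in < self.n_iterations:
            raise ParameterError("n_burn_in must be < n_iterations")


@dataclass(frozen=True)
class Priors:
    """Weakly informative defaults; every scale is configurable."""

    beta_sd: float = 1e3
    gamma_sd: float = 10.0
    assoc_sd: float = 5.0
    baseline_sd: float = 10.0
    sigma2_shape: float = 0.01
    sigma2_rate: float = 0.01
    re_cov_extra_df: float = 2.0     # inverse-Wishart df = q + this
    re_cov_scale: float = 1.0        # inverse-Wishart scale = this * I


@dataclass
class PosteriorSamples:
    """Retained draws with named columns matching the parameter layout."""

    draws: pd.DataFrame
    random_effect_draws: np.ndarray | None = None
    patient_ids: list[str] | None = None
    shard_id: int | None = None
    shard_provenance: np.ndarray | None = None
    diagnostics: pd.DataFrame | None = None
    spec: JointModelSpec | None = None    # resolved spec used for the fit

    @property
    def n_draws(self) -> int:
        return len(self.draws)

    @property
    def parameter_names(self) -> list[str]:
        return list(self.draws.columns)

    def mean_vector(self, spec: JointModelSpec) -> ParameterVector:
        return ParameterVector(self.parameter_names,
                               self.draws.mean().to_numpy())

    def draw_vector(self, idx: int) -> ParameterVector:
        return ParameterVector(self.parameter_names,
                               self.draws.iloc[idx].to_numpy())


# --------------------------------------------------------------------------
# sampler internals
# --------------------------------------------------------------------------

class _State:
    """Mutable sampler state plus cached linear-predictor pieces."""

    def __init__(self, data: FitData, priors: Priors, rng):
        self.data = data
        self.priors = priors
        self.rng = rng
        spec = data.spec
        self.K = len(spec.submodels)
        self.q_slices = spec.b_slices
        self.q = spec.n_random_total
        self.centers = spec.centers
        N = data.N

        self.betas = []
        self.sigma2 = np.empty(self.K)
        for k, blk in enumerate(data.outcomes):
            ridge = 1e-8 * np.eye(blk.X.shape[1])
            beta = np.linalg.solve(blk.XtX + ridge, blk.X.T @ blk.y)
            resid = blk.y - blk.X @ beta
            self.betas.append(beta)
            self.sigma2[k] = max(np.var(resid) * 0.5, 1e-4)
        self.b = np.zeros((N, self.q))
        self.Sigma = np.eye(self.q)
        for k, blk in enumerate(data.outcomes):
            sl = self.q_slices[k]
            resid = blk.y - blk.X @ self.betas[k]
            pat_mean = np.bincount(blk.pat, resid, minlength=N) / np.maximum(
                np.bincount(blk.pat, minlength=N), 1)
            self.Sigma[sl.start, sl.start] = max(np.var(pat_mean), 0.1)
            if sl.stop - sl.start > 1:
                self.Sigma[sl.start + 1, sl.start + 1] = 0.5

        self.gamma = np.zeros(len(spec.event_covariates))
        self.assoc = np.zeros(self.K)
        rate = max(data.surv.delta.sum(), 0.5) / np.sum(
            data.surv.exit - data.surv.entry)
        if data.surv.B_nod is not None:
            self.theta = np.full(spec.baseline.n_par, np.log(rate))
        else:
            self.theta = np.array([0.0, -np.log(rate)])
        self._refresh_long_caches()
        self._refresh_surv()
        if not np.isfinite(self.sll.sum()):
            raise NumericalError("non-finite log-posterior at initialization "
                                 "(survival block)")

    # -- caches -------------------------------------------------------------
    def _refresh_long_caches(self):
        d = self.data
        self.m_obs = []
        self.m_nod = []
        self.m_exit = []
        for k, blk in enumerate(d.outcomes):
            sl = self.q_slices[k]
            self.m_obs.append(blk.X @ self.betas[k]
                              + np.einsum("ij,ij->i", blk.Z, self.b[blk.pat, sl]))
            self.m_nod.append(blk.Xnod @ self.betas[k]
                              + np.einsum("ij,ij->i", blk.Znod,
                                          self.b[d.surv.pat_nod, sl]))
            self.m_exit.append(blk.Xexit @ self.betas[k]
                               + np.einsum("ij,ij->i", blk.Zexit, self.b[:, sl]))

    def _eta_base(self):
        d = self.data
        base_nod = d.log_h0_nodes(self.theta)
        base_exit = d.log_h0_exit(self.theta)
        if self.gamma.size:
            base_nod = base_nod + d.surv.W_nod @ self.gamma
            base_exit = base_exit + d.surv.W_exit @ self.gamma
        return base_nod, base_exit

    def _refresh_surv(self):
        self.eta_base_nod, self.eta_base_exit = self._eta_base()
        self._recompute_sll()

    def _recompute_sll(self):
        d = self.data
        eta_nod = self.eta_base_nod.copy()
        eta_exit = self.eta_base_exit.copy()
        for k in range(self.K):
            eta_nod += self.assoc[k] * (self.m_nod[k] - self.centers[k])
            eta_exit += self.assoc[k] * (self.m_exit[k] - self.centers[k])
        with np.errstate(over="ignore"):
            self.Lam = np.bincount(d.surv.pat_nod,
                                   d.surv.w_nod * np.exp(eta_nod),
                                   minlength=d.N)
        self.eta_exit = eta_exit
        self.sll = d.surv.delta * eta_exit - self.Lam

    # -- updates ------------------------------------------------------------
    def update_b(self):
        d = self.data
        N = d.N
        P = np.broadcast_to(np.linalg.inv(self.Sigma), (N, self.q, self.q)).copy()
        r = np.zeros((N, self.q))
        for k, blk in enumerate(d.outcomes):
            sl = self.q_slices[k]
            P[:, sl, sl] += blk.ZtZ / self.sigma2[k]
            r[:, sl] = (blk.Zty - blk.ZtX @ self.betas[k]) / self.sigma2[k]
        L = np.linalg.cholesky(P)
        mu = np.linalg.solve(P, r[..., None])[..., 0]
        eps = self.rng.standard_normal((N, self.q))
        prop = mu + np.linalg.solve(np.transpose(L, (0, 2, 1)),
                                    eps[..., None])[..., 0]
        # survival log-lik under proposal
        db = prop - self.b
        eta_nod = self.eta_base_nod.copy()
        eta_exit = self.eta_base_exit.copy()
        for k, blk in enumerate(d.outcomes):
            sl = self.q_slices[k]
            dm_nod = np.einsum("ij,ij->i", blk.Znod, db[d.surv.pat_nod, sl])
            dm_exit = np.einsum("ij,ij->i", blk.Zexit, db[:, sl])
            eta_nod += self.assoc[k] * (self.m_nod[k] + dm_nod - self.centers[k])
            eta_exit += self.assoc[k] * (self.m_exit[k] + dm_exit - self.centers[k])
        with np.errstate(over="ignore"):
            Lam_p = np.bincount(d.surv.pat_nod, d.surv.w_nod * np.exp(eta_nod),
                                minlength=N)
        sll_p = d.surv.delta * eta_exit - Lam_p
        accept = np.log(self.rng.random(N)) < (sll_p - self.sll)
        self.b[accept] = prop[accept]
        self._refresh_long_caches()
        self._recompute_sll()
        return accept.mean()

    def update_betas(self):
        d = self.data
        tau2 = self.priors.beta_sd ** 2
        for k, blk in enumerate(d.outcomes):
            sl = self.q_slices[k]
            zb = np.einsum("ij,ij->i", blk.Z, self.b[blk.pat, sl])
            prec = blk.XtX / self.sigma2[k] + np.eye(blk.X.shape[1]) / tau2
            rhs = blk.X.T @ (blk.y - zb) / self.sigma2[k]
            Lp = np.linalg.cholesky(prec)
            mu = np.linalg.solve(prec, rhs)
            eps = self.rng.standard_normal(mu.size)
            prop = mu + np.linalg.solve(Lp.T, eps)
            if self.assoc[k] == 0.0:
                self.betas[k] = prop
                continue
            dmn = blk.Xnod @ (prop - self.betas[k])
            dme = blk.Xexit @ (prop - self.betas[k])
            eta_nod_old = None  # incremental evaluation below
            w_exp = d.surv.w_nod * np.exp(
                self.eta_base_nod
                + sum(self.assoc[j] * (self.m_nod[j] - self.centers[j])
                      for j in range(self.K)))
            dLam = np.bincount(d.surv.pat_nod,
                               w_exp * np.expm1(self.assoc[k] * dmn),
                               minlength=d.N)
            dll = float(np.sum(d.surv.delta * self.assoc[k] * dme) - dLam.sum())
            if np.log(self.rng.random()) < dll:
                self.betas[k] = prop
        self._refresh_long_caches()
        self._recompute_sll()

    def update_sigma2(self):
        for k, blk in enumerate(self.data.outcomes):
            resid = blk.y - self.m_obs[k]
            shape = self.priors.sigma2_shape + 0.5 * blk.y.size
            rate = self.priors.sigma2_rate + 0.5 * float(resid @ resid)
            self.sigma2[k] = rate / self.rng.gamma(shape)

    def update_Sigma(self):
        nu = self.priors.re_cov_extra_df + self.q + self.data.N
        S = self.priors.re_cov_scale * np.eye(self.q) + self.b.T @ self.b
        self.Sigma = invwishart.rvs(df=nu, scale=S, random_state=self.rng)
        self.Sigma = np.atleast_2d(self.Sigma)

    def phi_get(self):
        return np.concatenate([self.gamma, self.assoc, self.theta])

    def phi_set(self, phi):
        ng, K = self.gamma.size, self.K
        self.gamma = phi[:ng]
        self.assoc = phi[ng:ng + K]
        self.theta = phi[ng + K:]

    def phi_log_prior(self, phi):
        ng, K = self.gamma.size, self.K
        pr = self.priors
        sd = np.concatenate([np.full(ng, pr.gamma_sd), np.full(K, pr.assoc_sd),
                             np.full(self.theta.size, pr.baseline_sd)])
        return float(-0.5 * np.sum((phi / sd) ** 2))

    def phi_loglik(self, phi):
        d = self.data
        ng, K = self.gamma.size, self.K
        gamma, assoc, theta = phi[:ng], phi[ng:ng + K], phi[ng + K:]
        eta_nod = d.log_h0_nodes(theta)
        eta_exit = d.log_h0_exit(theta)
        if ng:
            eta_nod = eta_nod + d.surv.W_nod @ gamma
            eta_exit = eta_exit + d.surv.W_exit @ gamma
        for k in range(K):
            eta_nod = eta_nod + assoc[k] * (self.m_nod[k] - self.centers[k])
            eta_exit = eta_exit + assoc[k] * (self.m_exit[k] - self.centers[k])
        with np.errstate(over="ignore"):
            Lam = float(np.sum(d.surv.w_nod * np.exp(eta_nod)))
        return float(d.surv.delta @ eta_exit) - Lam

    def update_phi(self, prop_chol, n_steps):
        phi = self.phi_get()
        lp = self.phi_loglik(phi) + self.phi_log_prior(phi)
        n_acc = 0
        for _ in range(n_steps):
            prop = phi + prop_chol @ self.rng.standard_normal(phi.size)
            lp_prop = self.phi_loglik(prop) + self.phi_log_prior(prop)
            if np.log(self.rng.random()) < lp_prop - lp:
                phi, lp = prop, lp_prop
                n_acc += 1
        self.phi_set(phi)
        self._refresh_surv()
        return n_acc / n_steps


def fit_mcmc(cohort: CohortData, spec: JointModelSpec,
             priors: Priors | None = None,
             control: McmcControl | None = None,
             shard_id: int | None = None) -> PosteriorSamples:
    """Fit the joint model by MCMC and return retained posterior draws.

    Deterministic given ``control.seed``; burn-in draws are discarded and
    the remainder thinned per ``control``.
    """
    priors = priors or Priors()
    control = control or McmcControl()
    data = assemble(cohort, spec)
    spec = data.spec
    rng = np.random.default_rng(control.seed)
    state = _State(data, priors, rng)

    d_phi = state.phi_get().size
    prop_chol = 0.02 * np.eye(d_phi)
    phi_hist = []
    adapt_every, adapt_start = 25, 50

    names = parameter_names(spec)
    kept: list[np.ndarray] = []
    kept_b: list[np.ndarray] = []
    phi_acc_post = []

    for it in range(control.n_iterations):
        state.update_b()
        state.update_betas()
        state.update_sigma2()
        state.update_Sigma()
        acc = state.update_phi(prop_chol, control.n_survival_substeps)
        if it >= control.n_burn_in:
            phi_acc_post.append(acc)

        if it < control.n_burn_in:
            phi_hist.append(state.phi_get())
            if it >= adapt_start and (it + 1) % adapt_every == 0:
                hist = np.array(phi_hist[max(0, it - 300):])
                cov = np.cov(hist.T) + 1e-8 * np.eye(d_phi)
                prop_chol = np.linalg.cholesky(2.38 ** 2 / d_phi * cov)
        elif (it - control.n_burn_in) % control.thinning == 0:
            vec = ParameterVector.pack(spec, Params(
                [b.copy() for b in state.betas], np.sqrt(state.sigma2),
                state.Sigma.copy(), state.gamma.copy(), state.assoc.copy(),
                state.theta.copy()))
            kept.append(vec.values)
            if control.store_random_effects:
                kept_b.append(state.b.copy())

    if phi_acc_post and np.mean(phi_acc_post) == 0.0:
        warnings.warn("survival block accepted no proposals after burn-in; "
                      "adaptation failed", RuntimeWarning)

    draws = pd.DataFrame(np.array(kept), columns=names)
    samples = PosteriorSamples(
        draws=draws,
        random_effect_draws=np.array(kept_b) if kept_b else None,
        patient_ids=data.patient_ids,
        shard_id=shard_id,
        diagnostics=_diagnostics(draws),
        spec=spec,
    )
    return samples


def _diagnostics(draws: pd.DataFrame) -> pd.DataFrame:
    """Per-parameter effective sample size and split-chain R-hat."""
    import arviz as az
    n = len(draws)
    half = n // 2
    rows = {}
    for col in draws.columns:
        x = draws[col].to_numpy()
        if np.allclose(x, x[0]):
            rows[col] = (float(n), 1.0)
            continue
        split = x[: 2 * half].reshape(2, half)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rows[col] = (float(az.ess(split)), float(az.rhat(split)))
    return pd.DataFrame(rows, index=["ess", "rhat"]).T


def fit_sharded(cohort: CohortData, spec: JointModelSpec, n_shards: int,
                priors: Priors | None = None,
                control: McmcControl | None = None,
                seed: int | None = None) -> tuple[PosteriorSamples,
                                                  list[PosteriorSamples]]:
    """Split/fit/pool: event-balanced shards fitted independently, draws pooled."""
    control = control or McmcControl()
    seed = control.seed if seed is None else seed
    shards = split_into_shards(cohort, n_shards, seed)
    fits = []
    for s_id, shard in enumerate(shards):
        ctrl = McmcControl(control.n_iterations, control.n_burn_in,
                           control.thinning, seed + 1000 * (s_id + 1),
                           control.n_survival_substeps,
                           control.store_random_effects)
        fits.append(fit_mcmc(shard, spec, priors, ctrl, shard_id=s_id))
    return combine_shard_posteriors(fits), fits


def combine_shard_posteriors(shard_fits: list[PosteriorSamples],
                             rule: str = "concat") -> PosteriorSamples:
    """Pool shard-level MCMC draws into one posterior sample.

    The default rule concatenates retained draws with equal shard weight
    (pooled count = sum of shard counts). The pooling rule is deliberately
    isolated here: equal-weight concatenation understates between-shard
    variability, so alternatives can be slotted in.
    """
    if not shard_fits:
        raise ParameterError("no shard fits supplied")
    cols = shard_fits[0].parameter_names
    for f in shard_fits[1:]:
        if f.parameter_names != cols:
            raise SchemaError("shard posteriors have different parameter layouts")
    if rule != "concat":
        raise ParameterError(f"unknown combining rule {rule!r}")
    draws = pd.concat([f.draws for f in shard_fits], ignore_index=True)
    provenance = np.concatenate([
        np.full(f.n_draws, f.shard_id if f.shard_id is not None else i)
        for i, f in enumerate(shard_fits)])
    return PosteriorSamples(draws=draws, shard_provenance=provenance,
                            diagnostics=_diagnostics(draws),
                            spec=shard_fits[0].spec)


def posterior_summary(samples: PosteriorSamples,
                      level: float = 0.95) -> pd.DataFrame:
    """Posterior mean, SD, HPD interval and two-sided tail probability.

    The HPD interval is the narrowest window over the sorted draws that
    contains ``level`` of them. The tail probability is
    ``2 * min(Pr(param > 0), Pr(param < 0))``, a Bayesian analogue of a
    two-sided p-value.
    """
    if samples.n_draws < 100:
        warnings.warn("fewer than 100 retained draws; summaries are imprecise",
                      RuntimeWarning)
    rows = []
    for col in samples.parameter_names:
        x = np.sort(samples.draws[col].to_numpy())
        n = x.size
        m = max(1, int(np.ceil(level * n)))
        if m >= n:
            lo, hi = x[0], x[-1]
        else:
            widths = x[m - 1:] - x[: n - m + 1]
            j = int(np.argmin(widths))
            lo, hi = x[j], x[j + m - 1]
        p_pos = np.mean(x > 0)
        p_neg = np.mean(x < 0)
        rows.append((col, x.mean(), x.std(ddof=1) if n > 1 else 0.0,
                     lo, hi, 2 * min(p_pos, p_neg)))
    return pd.DataFrame(rows, columns=["parameter", "mean", "sd",
                                       "hpd_low", "hpd_high", "tail_prob"]
                        ).set_index("parameter")
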