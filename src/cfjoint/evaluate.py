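"""Model evaluation: Kaplan-Meier summaries, landmark/window AUC, the
cross-validation harness, and parameter-recovery reporting.

Discrimination is assessed with a dynamic (landmark) AUC: among patients at
risk and event-free at landmark age ``t``, the AUC over the window
``(t, t + dt]`` is the probability that a randomly chosen patient who has a
first exacerbation inside the window was assigned a higher predicted risk
(1 - predicted event-free probability) than a randomly chosen patient known
to be event-free through ``t + dt``. Patients censored inside the window
are excluded from pair formation by default; an inverse-probability-of-
censoring-weighted variant is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.utils import median_survival_times

from .cohort import CohortData, PatientEventRecord
from .errors import ParameterError, SchemaError
from .mcmc import McmcControl, PosteriorSamples, Priors, fit_mcmc
from .model import JointModelSpec, ParameterVector
from .predict import PatientHistory, pe_free_profile

__all__ = ["KaplanMeierResult", "kaplan_meier", "AucResult", "dynamic_auc",
           "CvControl", "cross_validated_auc", "parameter_recovery_report"]


@dataclass
class KaplanMeierResult:
    """Product-limit estimate on the age scale with delayed entry."""

    curve: pd.DataFrame              # columns: age, survival, lower, upper
    median: float                    # inf when not reached
    median_ci: tuple[float, float]

    @property
    def median_reached(self) -> bool:
        return np.isfinite(self.median)

    def survival_at(self, age: float) -> float:
        s = self.curve[self.curve["age"] <= age + 1e-12]["survival"]
        return float(s.iloc[-1]) if len(s) else 1.0


def kaplan_meier(patients: list[PatientEventRecord]) -> KaplanMeierResult:
    """Kaplan-Meier of age at first exacerbation with left truncation.

    Patients contribute to the risk set only while under follow-up
    (entry_age < t <= exit_age); the confidence band is Greenwood-based.
    """
    if not patients:
        raise ParameterError("at least one patient required")
    exit_ages = np.array([p.exit_age for p in patients])
    entry_ages = np.array([p.entry_age for p in patients])
    events = np.array([p.event for p in patients])
    kmf = KaplanMeierFitter()
    kmf.fit(durations=exit_ages, event_observed=events, entry=entry_ages)
    ci = kmf.confidence_interval_
    curve = pd.DataFrame({
        "age": kmf.survival_function_.index.to_numpy(),
        "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
        "lower": ci.iloc[:, 0].to_numpy(),
        "upper": ci.iloc[:, 1].to_numpy(),
    })
    median = float(kmf.median_survival_time_)
    med_ci = median_survival_times(kmf.confidence_interval_)
    lo = float(med_ci.iloc[0, 0])
    hi = float(med_ci.iloc[0, 1])
    return KaplanMeierResult(curve=curve, median=median, median_ci=(lo, hi))


@dataclass(frozen=True)
class AucResult:
    """One landmark/window AUC cell."""

    landmark_age: float
    window: float
    auc: float                      # NaN when no comparable pairs exist
    n_comparable_pairs: int
    replicate_id: int = 0
    fold_id: int = 0


def dynamic_auc(risks: dict, patients: list[PatientEventRecord],
                landmark: float, window: float, replicate_id: int = 0,
                fold_id: int = 0, censoring: str = "exclude") -> AucResult:
    """Landmark/window AUC from per-patient predicted risks.

    ``risks`` maps patient_id -> predicted risk of an event in
    ``(landmark, landmark + window]``; higher risk should precede events.
    """
    if censoring not in ("exclude", "ipcw"):
        raise ParameterError("censoring must be 'exclude' or 'ipcw'")
    end = landmark + window
    cases, controls, case_w, ctrl_w = [], [], [], []
    if censoring == "ipcw":
        cens_km = KaplanMeierFitter()
        cens_km.fit(
            durations=np.array([p.exit_age for p in patients]),
            event_observed=np.array([1 - p.event for p in patients]),
            entry=np.array([p.entry_age for p in patients]))

        def G(t):
            return max(float(cens_km.predict(t)), 1e-8)
    for p in patients:
        if p.patient_id not in risks:
            continue
        at_risk = p.entry_age <= landmark < p.exit_age
        if not at_risk:
            continue
        r = risks[p.patient_id]
        if p.event == 1 and landmark < p.exit_age <= end:
            cases.append(r)
            case_w.append(1.0 / G(p.exit_age) if censoring == "ipcw" else 1.0)
        elif p.exit_age > end:
            controls.append(r)
            ctrl_w.append(1.0 / G(end) if censoring == "ipcw" else 1.0)
    n_pairs = len(cases) * len(controls)
    if n_pairs == 0:
        return AucResult(landmark, window, float("nan"), 0, replicate_id, fold_id)
    ca = np.asarray(cases)[:, None]
    co = np.asarray(controls)[None, :]
    conc = (ca > co) + 0.5 * (ca == co)
    w = np.asarray(case_w)[:, None] * np.asarray(ctrl_w)[None, :]
    auc = float(np.sum(conc * w) / np.sum(w))
    return AucResult(landmark, window, auc, n_pairs, replicate_id, fold_id)


@dataclass(frozen=True)
class CvControl:
    """Repeated subsampled k-fold cross-validation settings.

    Mirrors the registry validation design: per repetition, draw
    ``subsample_size`` patients, split into ``n_folds`` patient-level
    folds, fit on the rest, and score held-out landmark risks.
    """

    n_folds: int = 5
    subsample_size: int = 700
    n_repetitions: int = 100
    landmark_ages: tuple[float, ...] = (12.0, 16.0)
    windows: tuple[float, ...] = (0.5, 1.0, 2.0)
    seed: int = 0
    n_mc_predict: int = 60

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ParameterError("n_folds must be >= 2")


def cross_validated_auc(cohort: CohortData, spec: JointModelSpec,
                        priors: Priors | None = None,
                        mcmc_control: McmcControl | None = None,
                        cv: CvControl | None = None) -> list[AucResult]:
    """The cross-validation harness behind the AUC box plots.

    Deterministic given ``cv.seed`` (subsampling, fold assignment and the
    per-fold fitting seeds all derive from it). Cells with no comparable
    pairs are recorded with ``auc = NaN`` rather than raised.
    """
    cv = cv or CvControl()
    mcmc_control = mcmc_control or McmcControl()
    if cv.subsample_size > cohort.n_patients:
        raise ParameterError("subsample_size exceeds cohort size")
    root = np.random.SeedSequence(cv.seed)
    rep_seqs = root.spawn(cv.n_repetitions)
    results: list[AucResult] = []
    all_ids = np.array(cohort.patient_ids)

    for rep in range(cv.n_repetitions):
        rng = np.random.default_rng(rep_seqs[rep])
        ids = rng.choice(all_ids, size=cv.subsample_size, replace=False)
        perm = rng.permutation(ids)
        folds = np.array_split(perm, cv.n_folds)
        for f, test_ids in enumerate(folds):
            train_ids = np.setdiff1d(perm, test_ids)
            train = cohort.subset(train_ids)
            test = cohort.subset(test_ids)
            fit_seed = int(rng.integers(0, 2 ** 31 - 1))
            ctrl = McmcControl(mcmc_control.n_iterations,
                               mcmc_control.n_burn_in, mcmc_control.thinning,
                               fit_seed, mcmc_control.n_survival_substeps)
            posterior = fit_mcmc(train, spec, priors, ctrl)
            rspec = posterior.spec
            for t in cv.landmark_ages:
                horizons = [t + w for w in cv.windows]
                risks = {w: {} for w in cv.windows}
                for p in test.patients:
                    if not (p.entry_age <= t < p.exit_age):
                        continue
                    obs = tuple(o for o in test.observations
                                if o.patient_id == p.patient_id and o.age <= t)
                    hist = PatientHistory(p, obs, t)
                    preds = pe_free_profile(
                        hist, posterior, rspec, horizons,
                        n_mc=cv.n_mc_predict,
                        seed=int(rng.integers(0, 2 ** 31 - 1)))
                    for w, pred in zip(cv.windows, preds):
                        risks[w][p.patient_id] = 1.0 - pred.point_estimate
                for w in cv.windows:
                    results.append(dynamic_auc(risks[w], test.patients, t, w,
                                               replicate_id=rep, fold_id=f))
    return results


def auc_table(results: list[AucResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def parameter_recovery_report(truth: ParameterVector,
                              summaries: list[pd.DataFrame]) -> pd.DataFrame:
    """Bias, RMSE and HPD coverage across replicate fits.

    ``summaries`` are :func:`cfjoint.mcmc.posterior_summary` tables, one per
    replicate. Parameters are matched by name; names present in only one
    layout (e.g. a different baseline-hazard family) are skipped.
    """
    if not summaries:
        raise ParameterError("at least one replicate summary required")
    truth_map = dict(zip(truth.names, truth.values))
    common = [n for n in summaries[0].index if n in truth_map]
    for s in summaries[1:]:
        if list(s.index) != list(summaries[0].index):
            raise SchemaError("replicate summaries have different layouts")
    rows = []
    for name in common:
        tv = truth_map[name]
        means = np.array([s.loc[name, "mean"] for s in summaries])
        cover = np.array([
            s.loc[name, "hpd_low"] <= tv <= s.loc[name, "hpd_high"]
            for s in summaries])
        rows.append((name, tv, means.mean() - tv,
                     float(np.sqrt(np.mean((means - tv) ** 2))),
                     float(cover.mean())))
    return pd.DataFrame(rows, columns=["parameter", "truth", "bias", "rmse",
                                       "coverage"]).set_index("parameter")
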