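"""Cohort containers and delimited-text input/output.

The analysis operates on two tables:

* a long-format observation table, one row per biomarker measurement at a
  clinical encounter (``patient_id, age, outcome, value``), and
* a one-row-per-patient event table with entry/exit ages on the age scale,
  the first-exacerbation indicator, baseline covariates, and onset ages of
  the acquired ("switch on and stay on") time-varying covariates.

Ages are decimal years. Patients enter the risk set at their first recorded
encounter (delayed entry / left truncation), so ``entry_age`` is part of the
event record rather than implicitly zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import CohortValidationError, ParameterError, ReferentialError, SchemaError

logger = logging.getLogger(__name__)

__all__ = [
    "OUTCOMES", "GENOTYPES", "BIRTH_COHORTS", "SWITCH_COVARIATES",
    "LongitudinalObservation", "PatientEventRecord", "CohortData",
    "read_long_cohort", "write_cohort", "encounters_in_prior_year",
    "split_into_shards",
]

#: Biomarkers the models know about: lung function (% predicted) and the
#: three growth percentiles.
OUTCOMES = ("FEV1", "BMIp", "WFA", "HFA")
PERCENTILE_OUTCOMES = ("BMIp", "WFA", "HFA")

GENOTYPES = ("homozygous", "heterozygous", "none_unknown")
BIRTH_COHORTS = ("<1981", "1981-1989", "1990-1994", "1995-1999", ">1999")
SWITCH_COVARIATES = ("mrsa", "pa", "cfrd", "enzymes")

OBS_COLUMNS = ["patient_id", "age", "outcome", "value"]
EVENT_COLUMNS = [
    "patient_id", "entry_age", "exit_age", "event",
    "genotype", "sex", "hispanic", "ses", "birth_cohort",
    "mrsa_age", "pa_age", "cfrd_age", "enzymes_age",
]

DEFAULT_AGE_WINDOW = (6.0, 20.0)


@dataclass(frozen=True)
class LongitudinalObservation:
    """A single biomarker measurement at one clinical encounter."""

    patient_id: str
    age: float
    outcome_name: str
    value: float


@dataclass(frozen=True)
class PatientEventRecord:
    """Per-patient follow-up summary and covariates.

    ``exit_age`` is the age at first pulmonary exacerbation when
    ``event == 1`` and the censoring age otherwise. ``covariate_switch_ages``
    holds the onset age of each acquired covariate (absent key = never
    acquired); once switched on a covariate stays on.
    """

    patient_id: str
    entry_age: float
    exit_age: float
    event: int
    baseline_covariates: dict = field(default_factory=dict)
    covariate_switch_ages: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.entry_age < self.exit_age:
            raise CohortValidationError(
                f"patient {self.patient_id}: entry_age ({self.entry_age}) must be "
                f"< exit_age ({self.exit_age})"
            )
        if self.event not in (0, 1):
            raise CohortValidationError(
                f"patient {self.patient_id}: event must be 0 or 1"
            )
        for name, age in self.covariate_switch_ages.items():
            if age is not None and (not np.isfinite(age) or age < 0):
                raise CohortValidationError(
                    f"patient {self.patient_id}: switch age for {name!r} must be "
                    "finite and >= 0"
                )

    def covariate_on(self, name: str, t: float) -> float:
        """Step-function value of an acquired covariate at age ``t``."""
        age = self.covariate_switch_ages.get(name)
        if age is None:
            return 0.0
        return 1.0 if t >= age else 0.0


@dataclass
class CohortData:
    """The single currency of the pipeline: observations plus event records."""

    observations: list[LongitudinalObservation]
    patients: list[PatientEventRecord]

    @property
    def patient_ids(self) -> list[str]:
        return [p.patient_id for p in self.patients]

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def observations_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(o.patient_id, o.age, o.outcome_name, o.value) for o in self.observations],
            columns=OBS_COLUMNS,
        )

    def events_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.patients:
            row = {
                "patient_id": p.patient_id,
                "entry_age": p.entry_age,
                "exit_age": p.exit_age,
                "event": p.event,
            }
            for key in ("genotype", "sex", "hispanic", "ses", "birth_cohort"):
                row[key] = p.baseline_covariates.get(key)
            for name in SWITCH_COVARIATES:
                row[f"{name}_age"] = p.covariate_switch_ages.get(name)
            rows.append(row)
        return pd.DataFrame(rows, columns=EVENT_COLUMNS)

    def encounter_ages(self, patient_id: str) -> np.ndarray:
        """Distinct encounter ages of one patient, sorted."""
        ages = {o.age for o in self.observations if o.patient_id == patient_id}
        return np.array(sorted(ages))

    def subset(self, patient_ids) -> "CohortData":
        keep = set(patient_ids)
        return CohortData(
            observations=[o for o in self.observations if o.patient_id in keep],
            patients=[p for p in self.patients if p.patient_id in keep],
        )

    def validate(self, outcomes: tuple[str, ...] | None = None,
                 age_window: tuple[float, float] = DEFAULT_AGE_WINDOW) -> None:
        """Check structural invariants; raise on the first violation."""
        known = {p.patient_id: p for p in self.patients}
        lo, hi = age_window
        for o in self.observations:
            if o.patient_id not in known:
                raise ReferentialError(
                    f"observation references unknown patient {o.patient_id!r}"
                )
            p = known[o.patient_id]
            if not (p.entry_age - 1e-9 <= o.age <= p.exit_age + 1e-9):
                raise CohortValidationError(
                    f"patient {o.patient_id}: observation age {o.age} outside "
                    f"[{p.entry_age}, {p.exit_age}]"
                )
            if not (lo - 1e-9 <= o.age <= hi + 1e-9):
                raise CohortValidationError(
                    f"patient {o.patient_id}: observation age {o.age} outside the "
                    f"eligibility window [{lo}, {hi}]"
                )
            if o.outcome_name in PERCENTILE_OUTCOMES and not 0.0 <= o.value <= 100.0:
                raise CohortValidationError(
                    f"patient {o.patient_id}: {o.outcome_name} value {o.value} "
                    "outside [0, 100]"
                )
            if o.outcome_name == "FEV1" and not o.value > 0:
                raise CohortValidationError(
                    f"patient {o.patient_id}: FEV1 value must be > 0"
                )
        if outcomes:
            by_patient: dict[str, dict[str, float]] = {}
            for o in self.observations:
                by_patient.setdefault(o.patient_id, {})
                prev = by_patient[o.patient_id].get(o.outcome_name)
                if prev is None or o.age < prev:
                    by_patient[o.patient_id][o.outcome_name] = o.age
            for p in self.patients:
                firsts = by_patient.get(p.patient_id, {})
                for k in outcomes:
                    if k not in firsts:
                        raise CohortValidationError(
                            f"patient {p.patient_id}: no {k} observation"
                        )


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def read_long_cohort(observations_path, events_path,
                     age_window: tuple[float, float] = DEFAULT_AGE_WINDOW,
                     validate: bool = True) -> CohortData:
    """Read the two CSV tables into a validated :class:`CohortData`.

    Observation rows with ages outside ``age_window`` are dropped (the count
    is logged), mirroring the eligibility rule that excludes encounters
    before age 6 or after age 20.
    """
    obs_df = pd.read_csv(observations_path)
    ev_df = pd.read_csv(events_path)
    _require_columns(obs_df, OBS_COLUMNS, observations_path)
    _require_columns(ev_df, EVENT_COLUMNS, events_path)

    lo, hi = age_window
    in_window = (obs_df["age"] >= lo) & (obs_df["age"] <= hi)
    n_dropped = int((~in_window).sum())
    if n_dropped:
        logger.info("dropped %d observation(s) outside age window [%s, %s]",
                    n_dropped, lo, hi)
        obs_df = obs_df[in_window]

    patients = []
    for row in ev_df.itertuples(index=False):
        switch = {}
        for name in SWITCH_COVARIATES:
            raw = getattr(row, f"{name}_age")
            if raw is not None and not (isinstance(raw, float) and np.isnan(raw)):
                switch[name] = float(raw)
        patients.append(PatientEventRecord(
            patient_id=str(row.patient_id),
            entry_age=float(row.entry_age),
            exit_age=float(row.exit_age),
            event=int(row.event),
            baseline_covariates={
                "genotype": row.genotype, "sex": int(row.sex),
                "hispanic": int(row.hispanic), "ses": int(row.ses),
                "birth_cohort": row.birth_cohort,
            },
            covariate_switch_ages=switch,
        ))

    observations = [
        LongitudinalObservation(str(r.patient_id), float(r.age),
                                str(r.outcome), float(r.value))
        for r in obs_df.itertuples(index=False)
    ]
    cohort = CohortData(observations=observations, patients=patients)
    if validate:
        cohort.validate(age_window=age_window)
    return cohort


def write_cohort(cohort: CohortData, observations_path, events_path) -> None:
    """Write the two CSV tables (inverse of :func:`read_long_cohort`)."""
    cohort.observations_frame().to_csv(observations_path, index=False)
    cohort.events_frame().to_csv(events_path, index=False)


def encounters_in_prior_year(encounter_ages, t: float) -> int:
    """Number of distinct encounters in the half-open year ``(t - 1, t]``.

    Used as a time-varying covariate to absorb irregular-sampling bias:
    sicker patients are seen more often.
    """
    ages = np.unique(np.asarray(encounter_ages, dtype=float))
    return int(np.sum((ages > t - 1.0) & (ages <= t)))


def split_into_shards(cohort: CohortData, n_shards: int, seed: int) -> list[CohortData]:
    """Partition patients into ``n_shards`` shards balanced on event fraction.

    Patients are shuffled within each event stratum and dealt round-robin,
    so every shard's exacerbation percentage is as close to the overall one
    as the integer arithmetic allows. Deterministic given ``seed``.
    """
    if n_shards < 1:
        raise ParameterError("n_shards must be >= 1")
    if n_shards > cohort.n_patients:
        raise ParameterError(
            f"n_shards ({n_shards}) exceeds patient count ({cohort.n_patients})"
        )
    if n_shards == 1:
        return [cohort]
    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    offset = 0
    for stratum in (1, 0):
        ids = sorted(p.patient_id for p in cohort.patients if p.event == stratum)
        order = rng.permutation(len(ids))
        for rank, idx in enumerate(order):
            assignment[ids[idx]] = (offset + rank) % n_shards
        offset += len(ids)
    shards = []
    for s in range(n_shards):
        ids = [pid for pid, a in assignment.items() if a == s]
        shards.append(cohort.subset(ids))
    return shards
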