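"""Covariate encoding and design-row construction.

A design "recipe" is a list of covariate names resolved against a fixed
registry, so that generator and fitter assemble byte-identical matrices from
the same cohort. Baseline categorical covariates are dummy-coded against
fixed reference levels (genotype reference: homozygous; birth-cohort
reference: "<1981"); acquired covariates are step functions of age; the
encounter count is evaluated from the patient's own visit history.
"""

from __future__ import annotations

import numpy as np

from .cohort import (BIRTH_COHORTS, GENOTYPES, PatientEventRecord,
                     encounters_in_prior_year)
from .errors import ParameterError
from .splines import SplineBasisSpec, build_spline_basis

__all__ = [
    "BASELINE_COLUMNS", "TIME_VARYING_COLUMNS", "covariate_value",
    "covariate_matrix", "fixed_design", "random_design", "fixed_design_columns",
]

BASELINE_COLUMNS = (
    "sex", "hispanic", "ses",
    "genotype_heterozygous", "genotype_none_unknown",
    "birth_cohort_1981_1989", "birth_cohort_1990_1994",
    "birth_cohort_1995_1999", "birth_cohort_gt1999",
)
TIME_VARYING_COLUMNS = ("mrsa", "pa", "cfrd", "enzymes", "encounters_prior_year")

_COHORT_DUMMY = {
    "birth_cohort_1981_1989": "1981-1989",
    "birth_cohort_1990_1994": "1990-1994",
    "birth_cohort_1995_1999": "1995-1999",
    "birth_cohort_gt1999": ">1999",
}

#: age at which random slopes are centred so intercepts and slopes are
#: interpretable (mid-window value) and weakly correlated
RANDOM_SLOPE_CENTER = 13.0


def covariate_value(patient: PatientEventRecord, name: str, t: float,
                    encounter_ages=None) -> float:
    """Value of one named covariate for ``patient`` at age ``t``."""
    base = patient.baseline_covariates
    if name in ("sex", "hispanic", "ses"):
        return float(base.get(name, 0))
    if name == "genotype_heterozygous":
        return float(base.get("genotype") == "heterozygous")
    if name == "genotype_none_unknown":
        return float(base.get("genotype") not in ("homozygous", "heterozygous"))
    if name in _COHORT_DUMMY:
        return float(base.get("birth_cohort") == _COHORT_DUMMY[name])
    if name in ("mrsa", "pa", "cfrd", "enzymes"):
        return patient.covariate_on(name, t)
    if name == "encounters_prior_year":
        if encounter_ages is None:
            raise ParameterError("encounter ages required for encounters_prior_year")
        return float(encounters_in_prior_year(encounter_ages, t))
    raise ParameterError(f"unknown covariate {name!r}")


def covariate_matrix(patient: PatientEventRecord, names, ages,
                     encounter_ages=None) -> np.ndarray:
    """``(len(ages), len(names))`` covariate matrix for one patient."""
    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    cols = []
    for name in names:
        if name in TIME_VARYING_COLUMNS:
            cols.append(np.array([
                covariate_value(patient, name, t, encounter_ages) for t in ages
            ]))
        else:
            cols.append(np.full(ages.shape, covariate_value(patient, name, 0.0)))
    if not cols:
        return np.empty((ages.size, 0))
    return np.column_stack(cols)


def fixed_design_columns(spline: SplineBasisSpec, covariates,
                         interactions=()) -> list[str]:
    """Column names of the fixed-effects design, in assembly order."""
    names = ["intercept"]
    names += [f"age_ns{j + 1}" for j in range(spline.degrees_of_freedom)]
    names += list(covariates)
    for cov in interactions:
        names += [f"{cov}:age_ns{j + 1}" for j in range(spline.degrees_of_freedom)]
    return names


def fixed_design(patient: PatientEventRecord, ages, spline: SplineBasisSpec,
                 covariates, interactions=(), encounter_ages=None) -> np.ndarray:
    """Fixed-effects design matrix: intercept, age splines, covariates and
    optional covariate-by-spline interactions."""
    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    ns = build_spline_basis(ages, spline)
    cov = covariate_matrix(patient, covariates, ages, encounter_ages)
    blocks = [np.ones((ages.size, 1)), ns, cov]
    for name in interactions:
        w = covariate_matrix(patient, [name], ages, encounter_ages)
        blocks.append(ns * w)
    return np.hstack(blocks)


def random_design(ages, structure: str = "intercept_slope") -> np.ndarray:
    """Random-effects design: intercept, or intercept plus centred age."""
    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    if structure == "intercept":
        return np.ones((ages.size, 1))
    if structure == "intercept_slope":
        return np.column_stack([np.ones(ages.size), ages - RANDOM_SLOPE_CENTER])
    raise ParameterError(f"unknown random-effects structure {structure!r}")


def random_design_dim(structure: str) -> int:
    return {"intercept": 1, "intercept_slope": 2}[structure]
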