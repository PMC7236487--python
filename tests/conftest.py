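"""Shared fixtures: small simulated cohorts and one reusable posterior fit."""

import warnings

import numpy as np
import pytest

from cfjoint import (McmcControl, default_config, fit_mcmc, simulate_cohort)

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_cohort():
    """300-patient two-outcome cohort with the default study conditions."""
    cfg = default_config(n_patients=300, seed=11)
    cohort, truth = simulate_cohort(cfg)
    return cfg, cohort, truth


@pytest.fixture(scope="session")
def small_fit():
    """A modest fitted posterior shared by prediction and evaluation tests."""
    cfg = default_config(n_patients=150, seed=7)
    cohort, truth = simulate_cohort(cfg)
    spec = cfg.model_spec()
    posterior = fit_mcmc(cohort, spec,
                         control=McmcControl(n_iterations=500, n_burn_in=250,
                                             seed=3))
    return cfg, cohort, truth, posterior
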