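"""Shared fixtures.

The expensive MCMC fits are session-scoped and shared between the unit
tests and the acceptance suite so each posterior is sampled exactly once.
"""

import warnings

import numpy as np
import pytest

import metagaze as mg
from metagaze.inference import compare_models

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=RuntimeWarning)


@pytest.fixture(scope="session")
def design():
    return mg.generate_task_design(seed=1)


@pytest.fixture(scope="session")
def trace(design):
    return mg.info_trace(design)


@pytest.fixture(scope="session")
def small_cohort(design):
    """A 12-infant cohort for fast model-level tests."""
    return mg.apply_exclusion(mg.simulate_cohort(design, mg.CohortConfig(n_infants=12), seed=3))


@pytest.fixture(scope="session")
def downweight_cohort(design):
    """Study-scale cohort simulated under the default (downweighting) kernel."""
    return mg.apply_exclusion(mg.simulate_cohort(design, seed=42))


@pytest.fixture(scope="session")
def variant_fits(design, trace, downweight_cohort):
    """All four weighting variants fitted to the same downweight cohort."""
    fits = {}
    for name in ("null", "upweight", "downweight", "full"):
        model = mg.build_model(name, downweight_cohort, trace)
        fits[name] = mg.fit(model, mg.FitConfig(tune=350, draws=350, seed=10))
    return fits


@pytest.fixture(scope="session")
def comparison(variant_fits):
    return compare_models(variant_fits)


@pytest.fixture(scope="session")
def recovery_fits(design, trace):
    """Five replicate full-model fits on cohorts simulated with
    beta1 = 0.065 and lam1 = 0 at the study's sample size (n = 73)."""
    results = []
    for rep_seed in range(5):
        cohort = mg.apply_exclusion(mg.simulate_cohort(design, seed=rep_seed))
        model = mg.build_model("full", cohort, trace)
        results.append(mg.fit(model, mg.FitConfig(tune=350, draws=350, seed=rep_seed)))
    return results


@pytest.fixture(scope="session")
def efficiency_result(design):
    """Efficiency regression on a meta-learning cohort (negative log-trial
    learning curve, positive sequence x trial interaction)."""
    table = mg.simulate_latency_learning(design, n_infants=73, seed=5)
    return mg.fit_efficiency_model(
        table, config=mg.FitConfig(tune=500, draws=500, seed=3)
    )
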