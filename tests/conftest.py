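"""Shared fixtures: synthetic references and simulated cohorts.

The expensive default-condition cohort (n = 2000) is session-scoped and
shared by every test that only reads it.
"""

from __future__ import annotations

import dataclasses

import pytest

from anthrocohort import SimulationParams, simulate_cohort, synth_lms_reference
from anthrocohort.cleaning import clean_cohort


@pytest.fixture(scope="session")
def ref():
    return synth_lms_reference(seed=7)


@pytest.fixture(scope="session")
def default_sim():
    """Cohort under the default study conditions (n = 2000, fixed seed)."""
    return simulate_cohort(SimulationParams(n_children=2000, seed=1234))


@pytest.fixture(scope="session")
def default_cleaned(default_sim):
    cleaning, screening = clean_cohort(default_sim.visits, default_sim.reference)
    return cleaning, screening


@pytest.fixture(scope="session")
def quiet_params():
    """Low-variance configuration: no natural SAM or implausible values, so
    every screening/elimination event is attributable to an injection."""
    return SimulationParams(
        n_children=120, seed=99,
        haz_start_sd=0.6, whz_start_sd=0.5, whz_noise_sd=0.2,
        muac_baseline_sd_mm=4.0,
        implausible_rates={"HAZ": 0.0, "WHZ": 0.0, "WAZ": 0.0},
    )


def params_with(base: SimulationParams, **overrides) -> SimulationParams:
    return dataclasses.replace(base, **overrides)
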