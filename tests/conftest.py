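"""Shared fixtures: the expensive simulation/estimation runs are computed
once per session and reused by the unit and acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest

from dceana.construct import (NO_OVERLAP_GENERATORS, OVERLAP_GENERATORS,
                              generator_design, orthogonal_array_25)
from dceana.eclc import fit_eclc, stepwise_selection
from dceana.mnl import fit_mnl
from dceana.simulate import default_scenario, simulate

@pytest.fixture(scope="session")
def oa25():
    return orthogonal_array_25()


@pytest.fixture(scope="session")
def gendev_no_overlap(oa25):
    return generator_design(oa25, list(NO_OVERLAP_GENERATORS))


@pytest.fixture(scope="session")
def gendev_overlap(oa25):
    return generator_design(oa25, list(OVERLAP_GENERATORS))


@pytest.fixture(scope="session")
def recovery_runs():
    """Default scenario (no overlap) simulated and ECLC-fitted at a fixed
    prefix of seeds; recovery properties average over these replicates."""
    runs = []
    for seed in (1, 2, 3):
        sc = default_scenario(0, seed=seed)
        data, labels = simulate(sc)
        fit = fit_eclc(data, sc.spec, seed=1, n_restarts=1)
        runs.append({"scenario": sc, "data": data, "labels": labels, "fit": fit})
    return runs


@pytest.fixture(scope="session")
def stepwise_run():
    """Five-step selection on the default scenario (seed 1)."""
    sc = default_scenario(0, seed=1)
    data, labels = simulate(sc)
    fit, trace = stepwise_selection(data, threshold=0.05, seed=10)
    return {"scenario": sc, "data": data, "labels": labels, "fit": fit, "trace": trace}


@pytest.fixture(scope="session")
def full_attendance_cohort():
    """A 2000-respondent cohort where everyone attends all attributes, with
    its plain MNL fit (parameter-recovery and LLN checks)."""
    from dceana.eclc import AttendancePattern, ECLCSpec

    sc = default_scenario(0, seed=7)
    sc.spec = ECLCSpec((AttendancePattern.full(),))
    sc.class_probs = np.array([1.0])
    sc.n_respondents = 2000
    data, labels = simulate(sc)
    fit = fit_mnl(data)
    return {"scenario": sc, "data": data, "fit": fit}
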