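"""Shared fixtures: one simulated experiment reused across the suite."""

import warnings

import numpy as np
import pytest

from confbound import (
    AgentParams,
    ConfidencePool,
    DesignSpec,
    annotate_conf_hat,
    second_decision_table,
    simulate_dataset,
)

BASE_SEED = 20160915


@pytest.fixture(scope="session")
def design():
    return DesignSpec()


@pytest.fixture(scope="session")
def agent():
    return AgentParams()


@pytest.fixture(scope="session")
def dataset(design, agent):
    """Full 9-session simulated experiment (5,544 trials)."""
    return simulate_dataset(design, agent, BASE_SEED)


@pytest.fixture(scope="session")
def pool(dataset):
    return ConfidencePool.from_trials(dataset)


@pytest.fixture(scope="session")
def annotated(dataset, pool):
    return annotate_conf_hat(dataset, pool)


@pytest.fixture(scope="session")
def second_table(annotated):
    """Second-decision trials (double D2nd + D2star) ready for fitting."""
    return second_decision_table(annotated)


@pytest.fixture(autouse=True)
def _quiet_convergence_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield
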