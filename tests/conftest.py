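"""Shared fixtures: small simulated datasets reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

import dcpm
from dcpm import simulate as sim


@pytest.fixture(scope="session")
def tiny_null_dataset():
    """Two subjects, one run, no planted coupling."""
    spec = sim.preset_null_small(seed=11, n_subjects=2, n_nodes=12,
                                 n_trials_per_run=8)
    return sim.simulate_dataset(spec)


@pytest.fixture(scope="session")
def coupled_dataset():
    """Small dataset with planted positive/negative edges, strong coupling."""
    pos, neg = sim.random_planted_edges(30, 10, 10, seed=5)
    spec = sim.SimulationSpec(
        n_subjects=6, n_nodes=30, n_sessions=1, n_runs_per_session=1,
        n_trials_per_run=25, planted_positive_edges=pos,
        planted_negative_edges=neg, coupling_strength=2.0, seed=4,
    )
    return sim.simulate_dataset(spec), spec


@pytest.fixture(scope="session")
def coupled_matrix(coupled_dataset):
    """Trial-by-edge matrix of the coupled dataset, arousal construct."""
    (series, trials, truth), spec = coupled_dataset
    tensors = [dcpm.compute_synchrony(s) for s in series]
    X = dcpm.trial_average(tensors, trials, construct="arousal")
    return X, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
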