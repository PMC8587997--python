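"""Shared fixtures.

The expensive fixtures are session-scoped: one small 5-participant cohort
for unit-level checks, and one default-sized 20-participant cohort (at the
reduced 25-timepoint grid) whose segmented, screened and scaled cycles feed
the identification, relevance-recovery and subspace-overlap tests.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import gaitprint as gp
from gaitprint.layout import VariableLayout
from gaitprint.preprocess import DataMatrix, scale_matrix

N_TIMEPOINTS = 25


@pytest.fixture(scope="session")
def small_cfg() -> gp.CohortConfig:
    return gp.CohortConfig(n_participants=5, trial_duration=12.0, seed=42)


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return gp.synthesize_cohort(small_cfg)


@pytest.fixture(scope="session")
def small_trial(small_cfg, small_cohort):
    profiles, trials = small_cohort
    return trials[profiles[0].participant_id]["CR"]


def build_matrix(trials, n_timepoints=N_TIMEPOINTS):
    cycles = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for per_trial in trials.values():
            for trial in per_trial.values():
                cycles.extend(gp.process_trial(trial, n_timepoints=n_timepoints))
    layout = VariableLayout(n_timepoints)
    raw = gp.assemble_matrix(cycles, layout, scale=False)
    keep, report = gp.filter_outliers(raw.values,
                                      raw.index["participant"].to_numpy())
    return DataMatrix(
        values=scale_matrix(raw.values[keep]),
        index=raw.index.loc[keep].reset_index(drop=True),
        layout=layout,
    ), report


@pytest.fixture(scope="session")
def small_matrix(small_cohort):
    _, trials = small_cohort
    matrix, _ = build_matrix(trials)
    return matrix


# ---------------------------------------------------------------------------
# Default cohort products shared by the acceptance-level tests


@pytest.fixture(scope="session")
def default_cfg() -> gp.CohortConfig:
    """The default study conditions: 20 participants, 30 s trials."""
    return gp.CohortConfig(seed=0)


@pytest.fixture(scope="session")
def default_cohort(default_cfg):
    return gp.synthesize_cohort(default_cfg)


#: reduced timepoint grid of the default-cohort experiments
DEFAULT_TIMEPOINTS = 30


@pytest.fixture(scope="session")
def default_matrix(default_cohort):
    _, trials = default_cohort
    matrix, _ = build_matrix(trials, n_timepoints=DEFAULT_TIMEPOINTS)
    return matrix


@pytest.fixture(scope="session")
def default_split(default_matrix):
    pool = default_matrix.restrict(["CR", "WR"])
    test = default_matrix.restrict(["TR"])
    return pool, test


def train_identifier(pool, cycles_per_participant, seed=5):
    labels = pool.index["participant"].to_numpy()
    chosen = gp.sample_training_indices(labels, cycles_per_participant, seed)
    cfg = gp.NetworkConfig(
        input_nodes=pool.layout.n_variables,
        output_nodes=int(np.unique(labels).size),
        seed=seed,
    )
    weights, log = gp.train(pool.values[chosen], labels[chosen], cfg)
    return weights, log


@pytest.fixture(scope="session")
def trained_10(default_split):
    pool, _ = default_split
    return train_identifier(pool, 10)


@pytest.fixture(scope="session")
def trained_5(default_split):
    pool, _ = default_split
    return train_identifier(pool, 5)


@pytest.fixture(scope="session")
def default_ranking(default_split, trained_10):
    from gaitprint.relevance import (
        aggregate_relevance,
        relevance_for_cycles,
        smooth_pattern_matrix,
    )

    _, test = default_split
    weights, _ = trained_10
    labels = test.index["participant"].to_numpy()
    patterns, correct = relevance_for_cycles(weights, test.values, labels)
    smoothed = smooth_pattern_matrix(patterns, test.layout)
    _, overall, ranked = aggregate_relevance(smoothed, labels[correct],
                                             test.layout)
    return ranked
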