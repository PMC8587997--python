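"""Shared helper for the example scripts: cohort -> scaled data matrix."""

import warnings

import gaitprint as gp
from gaitprint.layout import VariableLayout
from gaitprint.preprocess import DataMatrix, scale_matrix


def build_matrix(config: gp.CohortConfig, n_timepoints: int = 25) -> DataMatrix:
    """Simulate, segment, screen and scale a cohort into one DataMatrix."""
    warnings.filterwarnings("ignore")
    _, trials = gp.synthesize_cohort(config)
    layout = VariableLayout(n_timepoints)
    cycles = []
    for per_trial in trials.values():
        for trial in per_trial.values():
            cycles.extend(gp.process_trial(trial, n_timepoints=n_timepoints))
    raw = gp.assemble_matrix(cycles, layout, scale=False)
    keep, _ = gp.filter_outliers(raw.values,
                                 raw.index["participant"].to_numpy())
    return DataMatrix(values=scale_matrix(raw.values[keep]),
                      index=raw.index.loc[keep].reset_index(drop=True),
                      layout=layout)
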