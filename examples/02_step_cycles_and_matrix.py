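"""Parse recordings into canonical step cycles and build the data matrix.

Cycles run from one touch-down to the next (opposite feet), are resampled
to a fixed grid, trunk-mirrored and relabeled to standing/swinging sides,
screened for outliers with local outlier probabilities (LoOP) on their
first three principal components, and scaled per cycle to [-1, 1].
"""

import warnings

import gaitprint as gp
from gaitprint.layout import VariableLayout
from gaitprint.preprocess import DataMatrix, scale_matrix

warnings.filterwarnings("ignore")

config = gp.CohortConfig(n_participants=4, trial_duration=15.0, seed=7)
_, trials = gp.synthesize_cohort(config)

n_timepoints = 25  # reduced grid; the full-scale convention is 100
layout = VariableLayout(n_timepoints)
cycles = []
for per_trial in trials.values():
    for trial in per_trial.values():
        cycles.extend(gp.process_trial(trial, n_timepoints=n_timepoints))
print(f"segmented {len(cycles)} step cycles; each flattens to "
      f"{layout.n_variables} variables (18 joints x 3 planes x {n_timepoints})")

raw = gp.assemble_matrix(cycles, layout, scale=False)
keep, report = gp.filter_outliers(raw.values,
                                  raw.index["participant"].to_numpy())
print("outlier screening (LoOP on 3-PC loadings, per participant):")
print(report.to_string(index=False))

matrix = DataMatrix(values=scale_matrix(raw.values[keep]),
                    index=raw.index.loc[keep].reset_index(drop=True),
                    layout=layout)
print(f"data matrix: {matrix.values.shape[0]} cycles x "
      f"{matrix.values.shape[1]} variables, entries in "
      f"[{matrix.values.min():.2f}, {matrix.values.max():.2f}]")

d = layout.descriptor(matrix.values.shape[1] // 2)
print(f"e.g. column {d.flat_index} is {d.joint} {d.plane} at timepoint "
      f"{d.timepoint} ({d.group} group)")
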