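"""Train the shallow network to identify runners from single step cycles.

The model trains on cycles pooled from the two training runs (CR, WR) and
is evaluated on every cycle of the held-out transition run (TR); accuracy
is the percentage of TR cycles assigned to the correct runner.
"""

import warnings

import numpy as np

import gaitprint as gp
from examples_common import build_matrix

warnings.filterwarnings("ignore")

matrix = build_matrix(gp.CohortConfig(n_participants=6, trial_duration=15.0,
                                      seed=7))
pool = matrix.restrict(["CR", "WR"])
test = matrix.restrict(["TR"])
labels = pool.index["participant"].to_numpy()

chosen = gp.sample_training_indices(labels, 10, seed=3)
config = gp.NetworkConfig(
    input_nodes=matrix.layout.n_variables,
    output_nodes=int(np.unique(labels).size),
    seed=5,
)
print(f"network: {config.input_nodes} -> {config.resolved_hidden_nodes} "
      f"(tanh) -> {config.output_nodes} nodes; training on "
      f"{len(chosen)} cycles (10 per runner)")

weights, log = gp.train(pool.values[chosen], labels[chosen], config)
print(f"trained for {log['epochs_run']} epochs "
      f"(early stop: {log['early_stopped']}), final loss {log['loss'][-1]:.4f}")

predictions, _ = gp.classify(weights, test.values)
report = gp.accuracy_by_participant(predictions,
                                    test.index["participant"].to_numpy())
print(report.per_participant.to_string(index=False))
print(f"overall held-out accuracy: {report.overall:.2f}% "
      f"({int(report.per_participant['n_total'].sum())} TR cycles)")
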