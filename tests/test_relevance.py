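"""Layer-wise relevance propagation: epsilon rule, smoothing, aggregation."""

import numpy as np
import pytest

import gaitprint as gp
from gaitprint.errors import ContractViolationError, PipelineOrderError
from gaitprint.layout import VariableLayout
from gaitprint.network import NetworkWeights, forward
from gaitprint.relevance import (
    LrpConfig,
    RelevancePattern,
    aggregate_relevance,
    propagate_relevance,
    propagate_relevance_batch,
    smooth_pattern_matrix,
    smooth_relevance,
)


def _net(w1, w2, b1=None, b2=None, classes=None):
    w1 = np.asarray(w1, dtype=float)
    w2 = np.asarray(w2, dtype=float)
    return NetworkWeights(
        w1=w1, b1=np.zeros(w1.shape[1]) if b1 is None else np.asarray(b1, float),
        w2=w2, b2=np.zeros(w2.shape[1]) if b2 is None else np.asarray(b2, float),
        classes=np.arange(w2.shape[1]) if classes is None else classes,
    )


def lrp_reference(weights, x, target, eps):
    """Independent loop-based epsilon-rule oracle (biases excluded from
    denominators; relevance starts at the target's pre-softmax score)."""
    hidden, scores = forward(weights, x.reshape(1, -1))
    hidden, scores = hidden[0], scores[0]
    r_out = scores[target]
    denom = sum(hidden[j] * weights.w2[j, target] for j in range(hidden.size))
    sgn = 1.0 if denom >= 0 else -1.0
    r_hidden = np.array([
        hidden[j] * weights.w2[j, target] / (denom + eps * sgn) * r_out
        for j in range(hidden.size)
    ])
    pre = x @ weights.w1
    r_in = np.zeros(x.size)
    for j in range(hidden.size):
        s = 1.0 if pre[j] >= 0 else -1.0
        for i in range(x.size):
            r_in[i] += x[i] * weights.w1[i, j] / (pre[j] + eps * s) * r_hidden[j]
    return r_in, r_hidden, r_out


def test_single_layer_closed_form_weights_two_minus_one():
    # pass-through first layer (identity weights) so the input relevances
    # reproduce the one-layer closed form a_j * w_j: proportional to (2, -1)
    w = _net(np.eye(2), [[2.0, 0.0], [-1.0, 0.0]])
    pattern = propagate_relevance(w, np.array([1.0, 1.0]), 0,
                                  LrpConfig(epsilon=1e-9))
    expected = np.tanh(1.0) * np.array([2.0, -1.0])
    assert np.allclose(pattern.scores, expected, atol=1e-6)


def test_all_zero_weights_give_zero_relevance():
    w = _net(np.zeros((3, 4)), np.zeros((4, 2)))
    r = propagate_relevance_batch(w, np.ones((1, 3)), np.array([0]))
    assert np.allclose(r, 0.0)


def test_relevance_conservation_at_every_layer():
    rng = np.random.default_rng(0)
    w = _net(rng.normal(scale=0.3, size=(12, 24)),
             rng.normal(scale=0.3, size=(24, 4)),
             b1=rng.normal(scale=0.05, size=24),
             b2=rng.normal(scale=0.05, size=4))
    x = rng.normal(size=12)
    eps = 1e-9
    r_in_ref, r_hidden_ref, r_out = lrp_reference(w, x, 2, eps)
    # per-layer conservation: the total is preserved through both transitions
    assert abs(r_hidden_ref.sum() - r_out) <= 1e-3 * abs(r_out)
    assert abs(r_in_ref.sum() - r_hidden_ref.sum()) <= 1e-3 * abs(r_out)
    # and the vectorized implementation agrees with the loop oracle
    mine = propagate_relevance_batch(w, x.reshape(1, -1), np.array([2]),
                                     LrpConfig(epsilon=eps))[0]
    assert np.allclose(mine, r_in_ref, atol=1e-10)
    assert abs(mine.sum() - r_out) <= 1e-3 * abs(r_out)


def test_conservation_on_trained_cycle(small_matrix, request):
    rng = np.random.default_rng(1)
    pool = small_matrix.restrict(["CR", "WR"])
    labels = pool.index["participant"].to_numpy()
    chosen = gp.sample_training_indices(labels, 3, seed=1)
    cfg = gp.NetworkConfig(input_nodes=pool.layout.n_variables,
                           output_nodes=int(np.unique(labels).size),
                           batch_size=5, epoch_limit=150, seed=4)
    w, _ = gp.train(pool.values[chosen], labels[chosen], cfg)
    x = pool.values[chosen[0]]
    pred, scores = gp.classify(w, x.reshape(1, -1))
    t_idx = int(np.flatnonzero(w.classes == pred[0])[0])
    r = propagate_relevance_batch(w, x.reshape(1, -1), np.array([t_idx]),
                                  LrpConfig(epsilon=1e-9))[0]
    assert abs(r.sum() - scores[0, t_idx]) <= 1e-3 * abs(scores[0, t_idx])


def test_misclassified_cycle_rejected():
    w = _net(np.eye(2), [[2.0, 0.0], [-1.0, 0.0]])
    with pytest.raises(ContractViolationError):
        propagate_relevance(w, np.array([1.0, 1.0]), 1)


# --- smoothing -------------------------------------------------------------


def _layout25():
    return VariableLayout(25)


def test_constant_pattern_is_unchanged_by_smoothing():
    layout = _layout25()
    pattern = np.full(layout.n_variables, 0.7)
    out = smooth_pattern_matrix(pattern, layout)
    assert np.allclose(out, 0.7, atol=1e-12)


def test_impulse_response_single_pass_is_quarter_half_quarter():
    layout = _layout25()
    pattern = np.zeros(layout.n_variables)
    center = layout.flat_index("Knee-st.", "flexion", 13)
    pattern[center] = 1.0
    out = smooth_pattern_matrix(pattern, layout,
                                LrpConfig(smoothing_passes=1))
    assert np.allclose(out[center - 2 : center + 3],
                       [0.0, 0.25, 0.5, 0.25, 0.0])


def test_impulse_response_two_passes_is_binomial_five_tap():
    layout = _layout25()
    pattern = np.zeros(layout.n_variables)
    center = layout.flat_index("Knee-st.", "flexion", 13)
    pattern[center] = 1.0
    out = smooth_pattern_matrix(pattern, layout, LrpConfig(smoothing_passes=2))
    assert np.allclose(out[center - 3 : center + 4],
                       [0.0, 0.0625, 0.25, 0.375, 0.25, 0.0625, 0.0])


def test_smoothing_never_crosses_trajectory_boundaries():
    layout = _layout25()
    pattern = np.zeros(layout.n_variables)
    sl = layout.trajectory_slice("L5S1", "abduction")
    pattern[sl.stop - 1] = 1.0  # impulse at the last timepoint
    out = smooth_pattern_matrix(pattern, layout)
    assert np.allclose(out[sl.stop :], 0.0)  # next trajectory untouched
    assert out[sl.stop - 1] > 0


def test_edge_kernel_renormalizes_to_two_thirds_one_third():
    layout = _layout25()
    pattern = np.zeros(layout.n_variables)
    sl = layout.trajectory_slice("L5S1", "abduction")
    pattern[sl.start] = 1.0
    out = smooth_pattern_matrix(pattern, layout, LrpConfig(smoothing_passes=1))
    assert np.isclose(out[sl.start], 2.0 / 3.0)
    assert np.isclose(out[sl.start + 1], 0.25)


def test_smoothing_preserves_mass_on_interior_support():
    layout = _layout25()
    rng = np.random.default_rng(2)
    pattern = np.zeros(layout.n_variables)
    sl = layout.trajectory_slice("Hip-sw.", "rotation")
    interior = slice(sl.start + 5, sl.stop - 5)
    pattern[interior] = rng.normal(size=interior.stop - interior.start)
    out = smooth_pattern_matrix(pattern, layout)
    assert np.isclose(out[sl].sum(), pattern[sl].sum(), atol=1e-12)


def test_smoothing_requires_raw_stage():
    layout = _layout25()
    smoothed = RelevancePattern(scores=np.zeros(layout.n_variables),
                                stage="smoothed")
    with pytest.raises(PipelineOrderError):
        smooth_relevance(smoothed, layout)


def test_smooth_relevance_advances_stage():
    layout = _layout25()
    raw = RelevancePattern(scores=np.zeros(layout.n_variables), stage="raw")
    assert smooth_relevance(raw, layout).stage == "smoothed"


# --- aggregation and ranking ----------------------------------------------


def _tiny_layout():
    # smallest layout (2 timepoints) only to satisfy shape bookkeeping when
    # aggregation maths is checked on hand-sized vectors
    return VariableLayout(2)


def test_single_pattern_rectified_normalized_example():
    layout = _tiny_layout()
    pattern = np.zeros(layout.n_variables)
    pattern[:3] = [3.0, -6.0, 0.0]
    per, overall, ranked = aggregate_relevance(
        pattern.reshape(1, -1), np.array(["P1"]), layout
    )
    assert np.allclose(per["P1"][:3], [0.5, 1.0, 0.0])
    assert np.isclose(overall.max(), 1.0)


def test_identical_patterns_across_participants_average_to_themselves():
    layout = _tiny_layout()
    rng = np.random.default_rng(3)
    pattern = rng.normal(size=layout.n_variables)
    stacked = np.vstack([pattern, pattern, pattern, pattern])
    participants = np.array(["A", "A", "B", "B"])
    per, overall, _ = aggregate_relevance(stacked, participants, layout)
    expected = np.abs(pattern) / np.abs(pattern).max()
    assert np.allclose(per["A"], expected)
    assert np.allclose(overall, expected)


def test_ranking_invariant_to_positive_rescaling_of_raw_relevance():
    layout = _tiny_layout()
    rng = np.random.default_rng(4)
    patterns = rng.normal(size=(6, layout.n_variables))
    participants = np.array(["A", "A", "B", "B", "C", "C"])
    _, overall1, r1 = aggregate_relevance(patterns, participants, layout)
    scaled = patterns * np.array([2.0, 2.0, 17.0, 17.0, 0.3, 0.3])[:, None]
    _, overall2, r2 = aggregate_relevance(scaled, participants, layout)
    assert np.allclose(overall1, overall2)
    assert np.array_equal(r1.order, r2.order)


def test_rank_ties_break_by_ascending_flat_index():
    layout = _tiny_layout()
    pattern = np.ones((1, layout.n_variables))
    _, _, ranked = aggregate_relevance(pattern, np.array(["A"]), layout)
    assert np.array_equal(ranked.order, np.arange(layout.n_variables))
    assert np.all(np.diff(ranked.scores) <= 0)


def test_ranked_frame_carries_descriptors():
    layout = _layout25()
    rng = np.random.default_rng(5)
    pattern = rng.random((1, layout.n_variables))
    _, _, ranked = aggregate_relevance(pattern, np.array(["A"]), layout)
    frame = ranked.to_frame()
    assert list(frame.columns[:2]) == ["rank", "flat_index"]
    assert frame.shape[0] == layout.n_variables
    assert (frame["score"].diff().dropna() <= 1e-15).all()
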