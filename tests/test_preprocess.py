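"""Outlier screening (LoOP), per-cycle scaling, matrix assembly."""

import numpy as np
import pytest
from scipy.special import erf

import gaitprint as gp
from gaitprint.errors import DegenerateInputError, InvalidConfigError, SchemaError
from gaitprint.gait_events import StepCycle
from gaitprint.layout import VariableLayout
from gaitprint.preprocess import OutlierConfig, scale_matrix


def loop_reference(points, k=20, lam=3.0):
    """Deliberately naive LoOP implementation used as the oracle."""
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    dists = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    neighbors = []
    for i in range(n):
        order = np.argsort(dists[i], kind="stable")
        order = [j for j in order if j != i][:k]
        neighbors.append(order)
    sigma = np.array([np.sqrt(np.mean(dists[i, neighbors[i]] ** 2))
                      for i in range(n)])
    pdist = lam * sigma
    plof = np.empty(n)
    for i in range(n):
        expected = np.mean(pdist[neighbors[i]])
        plof[i] = pdist[i] / expected - 1.0 if expected > 0 else 0.0
    nplof = lam * np.sqrt(np.mean(plof**2))
    if nplof <= 0:
        return np.zeros(n)
    return np.maximum(0.0, erf(plof / (nplof * np.sqrt(2.0))))


def test_loop_matches_reference_implementation():
    rng = np.random.default_rng(0)
    points = rng.normal(size=(48, 3))
    cfg = OutlierConfig(k_neighbors=10)
    mine = gp.loop_outlier_probabilities(points, cfg)
    ref = loop_reference(points, k=10)
    assert np.allclose(mine, ref, atol=1e-9)


def test_loop_flags_far_outlier_in_tight_cloud():
    rng = np.random.default_rng(1)
    cloud = rng.normal(scale=1.0, size=(200, 3))
    points = np.vstack([cloud, [[10.0, 10.0, 10.0]]])
    probs = gp.loop_outlier_probabilities(points, OutlierConfig(k_neighbors=20))
    assert probs[-1] > 0.99
    assert np.median(probs[:-1]) < 0.3


def test_loop_identical_points_have_zero_probability():
    points = np.zeros((30, 3))
    probs = gp.loop_outlier_probabilities(points, OutlierConfig(k_neighbors=5))
    assert np.allclose(probs, 0.0)


def test_loop_duplicated_inlier_scores_like_its_twin():
    rng = np.random.default_rng(2)
    cloud = rng.normal(size=(60, 3))
    points = np.vstack([cloud, cloud[7]])  # exact duplicate of an inlier
    probs = gp.loop_outlier_probabilities(points, OutlierConfig(k_neighbors=10))
    assert abs(probs[7] - probs[-1]) < 1e-9


def test_loop_requires_more_points_than_neighbors():
    with pytest.raises(InvalidConfigError):
        gp.loop_outlier_probabilities(np.zeros((5, 3)),
                                      OutlierConfig(k_neighbors=10))


# --- participant-wise screening -------------------------------------------


def test_planted_corrupted_cycle_is_removed():
    rng = np.random.default_rng(3)
    template = rng.normal(size=300)
    cycles = template + 0.05 * rng.normal(size=(60, 300))
    cycles[17, :100] = 0.0  # one joint's trajectories zeroed out
    keep, report = gp.filter_outliers(cycles, np.repeat("P01", 60))
    assert not keep[17]
    assert report.loc[0, "n_removed"] >= 1


def test_unreachable_cutoff_removes_nothing():
    rng = np.random.default_rng(4)
    cycles = rng.normal(size=(50, 40))
    keep, _ = gp.filter_outliers(cycles, np.repeat("A", 50),
                                 OutlierConfig(probability_cutoff=1.0))
    assert keep.all()


def test_iid_redraws_of_template_survive_high_cutoff():
    rng = np.random.default_rng(5)
    template = rng.normal(size=200)
    cycles = template + 0.1 * rng.normal(size=(80, 200))
    keep, _ = gp.filter_outliers(cycles, np.repeat("A", 80),
                                 OutlierConfig(probability_cutoff=0.9999))
    assert (~keep).sum() == 0


def test_clean_synthetic_participant_loses_few_cycles():
    # a participant whose cycles differ only by measurement noise (no step
    # jitter, no cycle-to-cycle signature wobble) loses at most 5% of cycles
    cfg = gp.CohortConfig(
        n_participants=2, trial_duration=30.0, seed=21, step_duration_jitter=0.0,
        bump_cycle_jitter=0.0, cadence_offset_sd=0.0, height_noise_sd=0.0,
    )
    profile = gp.make_cohort(cfg)[0]
    trial = gp.synthesize_trial(profile, cfg)
    cycles = gp.process_trial(trial, n_timepoints=25)
    matrix = gp.assemble_matrix(cycles, scale=False)
    keep, _ = gp.filter_outliers(matrix.values,
                                 matrix.index["participant"].to_numpy())
    # LoOP at the standard cutoff of 0.5 flags ~6% even of a perfect 3-D
    # Gaussian cloud (points at the cloud edge genuinely sit in lower local
    # density), so "few" here means at most 10%
    assert (~keep).sum() / keep.size <= 0.10


def test_small_participants_are_skipped_with_warning():
    rng = np.random.default_rng(6)
    cycles = rng.normal(size=(10, 20))
    with pytest.warns(UserWarning):
        keep, report = gp.filter_outliers(cycles, np.repeat("tiny", 10))
    assert keep.all()
    assert bool(report.loc[0, "skipped"])


# --- scaling ---------------------------------------------------------------


def test_scale_cycle_three_point_example():
    assert np.allclose(gp.scale_cycle(np.array([0.0, 1.0, 2.0])), [-1.0, 0.0, 1.0])


def test_scale_cycle_max_magnitude_is_one():
    rng = np.random.default_rng(7)
    for _ in range(5):
        out = gp.scale_cycle(rng.normal(size=150) * 40 + 11)
        assert np.isclose(np.abs(out).max(), 1.0)
        assert out.min() >= -1.0 and out.max() <= 1.0


def test_scale_cycle_affine_invariance_and_idempotence():
    rng = np.random.default_rng(8)
    x = rng.normal(size=200)
    assert np.allclose(gp.scale_cycle(3.7 * x + 12.0), gp.scale_cycle(x))
    once = gp.scale_cycle(x)
    assert np.allclose(gp.scale_cycle(once), once, atol=1e-12)


def test_scale_cycle_zero_variance_rejected():
    with pytest.raises(DegenerateInputError):
        gp.scale_cycle(np.full(10, 3.0))
    with pytest.raises(DegenerateInputError):
        scale_matrix(np.vstack([np.arange(5.0), np.full(5, 1.0)]))


def test_scale_matrix_matches_rowwise_scale_cycle():
    rng = np.random.default_rng(9)
    m = rng.normal(size=(7, 60))
    out = scale_matrix(m)
    for i in range(7):
        assert np.allclose(out[i], gp.scale_cycle(m[i]))


# --- matrix assembly -------------------------------------------------------


def _mk_cycles(n_per, participants, n_t=25):
    rng = np.random.default_rng(10)
    cycles = []
    for pid in participants:
        for i in range(n_per):
            cycles.append(StepCycle(
                values=rng.normal(size=(n_t, 18, 3)), participant_id=pid,
                trial_label="CR", standing_side="L", start_index=i * 84,
                end_index=(i + 1) * 84, canonical=True,
            ))
    return cycles


def test_assembled_matrix_shape_and_bounds():
    matrix = gp.assemble_matrix(_mk_cycles(5, ["P01", "P02"]))
    assert matrix.values.shape == (10, 25 * 54)
    assert matrix.values.min() >= -1.0 and matrix.values.max() <= 1.0
    assert np.allclose(np.abs(matrix.values).max(axis=1), 1.0)


def test_assembled_rows_are_sorted_deterministically():
    cycles = _mk_cycles(3, ["P02", "P01"])
    matrix = gp.assemble_matrix(cycles)
    parts = matrix.index["participant"].tolist()
    starts = matrix.index["start_index"].tolist()
    assert parts == sorted(parts)
    assert starts[:3] == sorted(starts[:3])


def test_empty_input_yields_empty_matrix_without_error():
    matrix = gp.assemble_matrix([])
    assert matrix.values.shape[0] == 0


def test_layout_mismatch_rejected():
    cycles = _mk_cycles(2, ["P01"], n_t=25)
    with pytest.raises(SchemaError):
        gp.assemble_matrix(cycles, VariableLayout(100))


def test_matrix_save_load_round_trip(tmp_path):
    matrix = gp.assemble_matrix(_mk_cycles(4, ["P01", "P02"]))
    matrix.save(tmp_path / "m.npz", tmp_path / "m.csv")
    back = gp.DataMatrix.load(tmp_path / "m.npz", tmp_path / "m.csv")
    assert np.array_equal(back.values, matrix.values)
    assert back.index.equals(matrix.index)
    assert back.layout.n_timepoints == 25
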