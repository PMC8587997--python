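"""Subset selection, PCA projection, alpha-shape volumes, overlap, profiles."""

import numpy as np
import pytest

import gaitprint as gp
from gaitprint.errors import DegenerateSubspaceError, InvalidConfigError, UndefinedOverlapError
from gaitprint.layout import VariableLayout
from gaitprint.overlap import (
    AlphaShape,
    OverlapConfig,
    bounding_volume,
    pairwise_overlap_percent,
    sample_inside,
    subset_schedule,
)
from gaitprint.relevance import RankedVariables


def _ranking(n_timepoints=100, scores=None):
    layout = VariableLayout(n_timepoints)
    n = layout.n_variables
    if scores is None:
        scores = np.ones(n)
    order = np.argsort(-scores, kind="stable")
    return RankedVariables(order=order, scores=scores[order], layout=layout)


def test_select_all_variables_either_direction():
    ranked = _ranking()
    for direction in ("most_relevant", "least_relevant"):
        sel = gp.select_subset(ranked, 5400, direction)
        assert sorted(sel.tolist()) == list(range(5400))


def test_top_ten_percent_of_full_ranking_is_540():
    ranked = _ranking()
    assert gp.select_subset(ranked, 540, "most_relevant").size == 540


def test_tied_scores_select_lowest_flat_indices_first():
    ranked = _ranking()
    assert np.array_equal(gp.select_subset(ranked, 10, "most_relevant"),
                          np.arange(10))


def test_select_subset_rejects_out_of_range_k():
    ranked = _ranking(25)
    with pytest.raises(InvalidConfigError):
        gp.select_subset(ranked, 0, "most_relevant")
    with pytest.raises(InvalidConfigError):
        gp.select_subset(ranked, ranked.n_variables + 1, "least_relevant")
    with pytest.raises(InvalidConfigError):
        gp.select_subset(ranked, 5, "sideways")


def test_most_and_least_partitions_are_disjoint_for_distinct_scores():
    rng = np.random.default_rng(0)
    layout = VariableLayout(25)
    scores = rng.random(layout.n_variables)
    order = np.argsort(-scores, kind="stable")
    ranked = RankedVariables(order=order, scores=scores[order], layout=layout)
    most = gp.select_subset(ranked, 100, "most_relevant")
    least = gp.select_subset(ranked, 100, "least_relevant")
    assert not set(most) & set(least)
    assert scores[most].min() > scores[least].max()


# --- PCA projection --------------------------------------------------------


def test_data_in_three_dimensional_subspace_projects_losslessly():
    rng = np.random.default_rng(1)
    basis = np.linalg.qr(rng.normal(size=(20, 3)))[0]
    scores_true = rng.normal(size=(50, 3)) * [5.0, 2.0, 1.0]
    data = scores_true @ basis.T + rng.normal(size=20)  # affine offset
    scores, evr = gp.pca3_project(data)
    # reconstruction through the fitted axes is exact
    centred = data - data.mean(axis=0)
    recon_err = np.linalg.norm(centred) ** 2 - np.linalg.norm(scores) ** 2
    assert abs(recon_err) < 1e-9
    assert np.isclose(evr.sum(), 1.0)


def test_duplicated_rows_project_identically():
    rng = np.random.default_rng(2)
    data = rng.normal(size=(30, 8))
    doubled = np.vstack([data, data])
    scores, _ = gp.pca3_project(doubled)
    assert np.allclose(scores[:30], scores[30:])


def test_rank_deficient_matrix_rejected():
    rng = np.random.default_rng(3)
    line = np.outer(rng.normal(size=40), rng.normal(size=6))
    with pytest.raises(DegenerateSubspaceError):
        gp.pca3_project(line)


def test_isotropic_cloud_spreads_variance_evenly():
    rng = np.random.default_rng(4)
    data = rng.normal(size=(4000, 10))
    _, evr = gp.pca3_project(data)
    assert np.all(np.abs(evr - 0.1) < 0.02)


# --- alpha-shape volumes ---------------------------------------------------


def test_unit_tetrahedron_volume_is_one_sixth():
    points = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
    shape = bounding_volume(points)
    assert np.isclose(shape.volume, 1.0 / 6.0, atol=1e-9)


def _unit_cube_grid(n_side=10):
    g = np.linspace(0.0, 1.0, n_side)
    return np.array(np.meshgrid(g, g, g)).reshape(3, -1).T


def test_thousand_point_unit_cube_volume_close_to_one():
    # 1000 points uniformly covering the unit cube (10x10x10 grid)
    shape = bounding_volume(_unit_cube_grid())
    assert abs(shape.volume - 1.0) < 0.1


def test_bounding_volume_is_deterministic():
    rng = np.random.default_rng(6)
    pts = rng.normal(size=(80, 3))
    a = bounding_volume(pts)
    b = bounding_volume(pts.copy())
    assert a.volume == b.volume
    assert a.alpha == b.alpha
    assert np.array_equal(a.kept, b.kept)


def test_alpha_shape_encloses_every_input_point():
    rng = np.random.default_rng(7)
    pts = rng.normal(size=(60, 3))
    shape = bounding_volume(pts)
    # vertices of kept tetrahedra cover all points by construction
    covered = np.unique(shape.delaunay.simplices[shape.kept])
    assert covered.size == 60


def test_coplanar_cloud_falls_back_with_warning():
    rng = np.random.default_rng(8)
    flat = np.column_stack([rng.normal(size=(30, 2)), np.zeros(30)])
    with pytest.warns(UserWarning):
        shape = bounding_volume(flat)
    assert shape.volume >= 0.0


def test_fewer_than_four_points_rejected():
    with pytest.raises(DegenerateSubspaceError):
        bounding_volume(np.zeros((3, 3)))


# --- Monte-Carlo overlap ---------------------------------------------------


def _cube_shape(shift=0.0):
    return bounding_volume(_unit_cube_grid() + shift)


def test_overlap_with_itself_is_exactly_hundred_percent():
    cube = _cube_shape()
    rng = np.random.default_rng(10)
    assert pairwise_overlap_percent(cube, cube, mc_samples=5000, rng=rng) == 100.0


def test_disjoint_translated_cubes_do_not_overlap():
    a = _cube_shape(0.0)
    b = _cube_shape(5.0)
    rng = np.random.default_rng(12)
    assert pairwise_overlap_percent(a, b, mc_samples=5000, rng=rng) == 0.0


def test_half_shifted_cube_overlaps_fifty_percent():
    a = _cube_shape(0.0)
    b_pts = a.points.copy()
    b_pts[:, 0] += 0.5
    b = bounding_volume(b_pts)
    rng = np.random.default_rng(13)
    pct = pairwise_overlap_percent(a, b, mc_samples=100_000, rng=rng)
    assert abs(pct - 50.0) < 1.0


def test_zero_volume_reference_is_undefined():
    cube = _cube_shape()
    empty = AlphaShape(points=cube.points, delaunay=cube.delaunay,
                       kept=np.zeros_like(cube.kept), alpha=0.0, volume=0.0)
    with pytest.raises(UndefinedOverlapError):
        pairwise_overlap_percent(empty, cube, mc_samples=1000)


def test_samples_drawn_inside_shape_are_members():
    shape = _cube_shape()
    rng = np.random.default_rng(14)
    samples = sample_inside(shape, 2000, rng)
    assert shape.contains(samples).all()


# --- schedule and profiles -------------------------------------------------


def test_full_schedule_has_1079_sizes():
    sizes = subset_schedule(OverlapConfig(), 5400)
    assert sizes.size == 1079
    assert sizes[0] == 10 and sizes[-1] == 5400
    assert np.all(np.diff(sizes) == 5)


def test_schedule_terminates_at_variable_count():
    sizes = subset_schedule(OverlapConfig(step=150), 1350)
    assert sizes[-1] == 1350
    assert np.all(np.diff(sizes) > 0)


def test_profile_of_flexion_only_subset():
    layout = VariableLayout(25)
    scores = np.zeros(layout.n_variables)
    sl = layout.trajectory_slice("Knee-st.", "flexion")
    scores[sl] = np.linspace(2.0, 1.0, 25)
    order = np.argsort(-scores, kind="stable")
    ranked = RankedVariables(order=order, scores=scores[order], layout=layout)
    profiles = gp.profile_variables(ranked, k=25)
    most = profiles["most_relevant"]
    assert np.isclose(most.by_movement["flexion/extension"], 1.0)
    assert np.isclose(most.by_group["lower"], 1.0)
    assert most.by_time.sum() == 25


def test_uniform_random_subset_spreads_over_groups():
    rng = np.random.default_rng(15)
    layout = VariableLayout(100)
    scores = rng.random(layout.n_variables)
    order = np.argsort(-scores, kind="stable")
    ranked = RankedVariables(order=order, scores=scores[order], layout=layout)
    profiles = gp.profile_variables(ranked)  # default k = 540
    for prof in profiles.values():
        assert prof.subset.size == 540
        for frac in prof.by_group:
            assert abs(frac - 1.0 / 3.0) < 0.07  # ~3.5 binomial sd
        assert np.isclose(prof.by_group.sum(), 1.0)
        assert np.isclose(prof.by_movement.sum(), 1.0)
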