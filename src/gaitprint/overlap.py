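"""Principal-subspace overlap of participants' movement patterns.

Step cycles restricted to the k most (or least) relevant variables are
projected onto their first three principal axes; each participant's cycles
form a 3-D point cloud that is bounded by an alpha shape (the smallest
alpha yielding a single connected region enclosing all the points, the
MATLAB ``alphaShape`` default criterion). The overlap of participant a's
volume with participant b's is estimated by seeded Monte-Carlo membership
sampling and expressed as a percentage of a's volume — an intentionally
asymmetric quantity. Repeating this while growing the variable subset in
steps of five traces how similarity between individuals decays as more
(most-relevant first vs. least-relevant first) variables define the
movement pattern. The extreme 10% of variables are additionally profiled
by movement plane, cycle time and joint group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError
from sklearn.decomposition import PCA

from .errors import (
    DegenerateSubspaceError,
    InvalidConfigError,
    UndefinedOverlapError,
)
from .relevance import RankedVariables


@dataclass(frozen=True)
class OverlapConfig:
    """Iteration schedule and Monte-Carlo settings."""

    start_size: int = 10
    step: int = 5
    end_size: int | None = None  # defaults to all variables
    n_components: int = 3
    mc_samples: int = 100_000
    min_points_per_participant: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.start_size < self.n_components + 1:
            raise InvalidConfigError("start_size must exceed n_components")
        if self.step < 1:
            raise InvalidConfigError("step must be at least 1")
        if self.mc_samples < 100:
            raise InvalidConfigError("mc_samples unreasonably small")


def subset_schedule(config: OverlapConfig, n_variables: int) -> np.ndarray:
    """Subset sizes: start, start+step, ... capped and terminated at n_variables."""
    end = config.end_size if config.end_size is not None else n_variables
    end = min(end, n_variables)
    sizes = np.arange(config.start_size, end + 1, config.step)
    if sizes.size == 0 or sizes[-1] != end:
        sizes = np.append(sizes, end)
    return sizes.astype(int)


def select_subset(ranked: RankedVariables, k: int, direction: str) -> np.ndarray:
    """Flat indices of the k most or least relevant variables.

    ``most_relevant`` takes the head of the descending ranking,
    ``least_relevant`` the tail (least relevant first); rank ties were
    already broken by ascending flat index in the ranking itself.
    """
    if not 1 <= k <= ranked.n_variables:
        raise InvalidConfigError(
            f"k={k} outside 1..{ranked.n_variables}"
        )
    if direction == "most_relevant":
        return ranked.order[:k].copy()
    if direction == "least_relevant":
        return ranked.order[-k:][::-1].copy()
    raise InvalidConfigError(f"unknown direction {direction!r}")


def pca3_project(matrix: np.ndarray, n_components: int = 3
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Mean-centred projection onto the first three principal axes.

    Returns the scores and the explained-variance ratios.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] < n_components + 1 or matrix.shape[1] < n_components:
        raise DegenerateSubspaceError(
            f"matrix {matrix.shape} too small for {n_components} components"
        )
    centred = matrix - matrix.mean(axis=0)
    if np.linalg.matrix_rank(centred) < n_components:
        raise DegenerateSubspaceError("data rank below the requested subspace")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(matrix)
    return scores, pca.explained_variance_ratio_


# ---------------------------------------------------------------------------
# Alpha shapes


def _circumradii(points: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    """Circumradius of every tetrahedron in a 3-D Delaunay triangulation."""
    a = points[simplices[:, 0]]
    rhs_pts = points[simplices[:, 1:]]  # (m, 3, 3)
    ba = rhs_pts - a[:, None, :]
    rhs = 0.5 * np.einsum("ijk,ijk->ij", ba, ba)
    radii = np.empty(simplices.shape[0])
    for i in range(simplices.shape[0]):
        try:
            center = np.linalg.solve(ba[i], rhs[i])
        except np.linalg.LinAlgError:
            radii[i] = np.inf
            continue
        radii[i] = np.linalg.norm(center)
    return radii


def _tet_volumes(points: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    a = points[simplices[:, 0]]
    m = points[simplices[:, 1:]] - a[:, None, :]
    return np.abs(np.linalg.det(m)) / 6.0


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> bool:
        ri, rj = self.find(i), self.find(j)
        if ri == rj:
            return False
        self.parent[ri] = rj
        return True


@dataclass
class AlphaShape:
    """Alpha complex over a 3-D point cloud with membership testing."""

    points: np.ndarray
    delaunay: Delaunay
    kept: np.ndarray  # bool per Delaunay simplex
    alpha: float
    volume: float

    def contains(self, queries: np.ndarray) -> np.ndarray:
        queries = np.atleast_2d(np.asarray(queries, dtype=float))
        simplex = self.delaunay.find_simplex(queries)
        inside = simplex >= 0
        inside[inside] = self.kept[simplex[inside]]
        return inside

    @property
    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        return self.points.min(axis=0), self.points.max(axis=0)


def bounding_volume(points: np.ndarray, jitter_seed: int = 0) -> AlphaShape:
    """Alpha shape with the smallest alpha giving one region over all points.

    Tetrahedra are admitted in order of increasing circumradius until the
    admitted complex is a single connected region whose vertices cover every
    input point; the radius reached at that moment is the critical alpha.
    Degenerate (coplanar) clouds fall back to the convex hull of minutely
    jittered points, with a warning.
    """
    points = np.asarray(points, dtype=float)
    if points.shape[0] < 4:
        raise DegenerateSubspaceError("need at least 4 points for a 3-D volume")
    try:
        tri = Delaunay(points)
        degenerate = tri.simplices.shape[0] == 0
    except QhullError:
        degenerate = True
    if degenerate:
        warnings.warn("degenerate point cloud; using convex hull of jittered points")
        rng = np.random.default_rng([jitter_seed, 977])
        scale = max(np.abs(points).max(), 1.0) * 1e-9
        points = points + rng.normal(0.0, scale, size=points.shape)
        tri = Delaunay(points, qhull_options="QJ")

    radii = _circumradii(points, tri.simplices)
    volumes = _tet_volumes(points, tri.simplices)
    order = np.argsort(radii, kind="stable")
    n_tets = order.size
    uf = _UnionFind(n_tets)
    faces: dict[tuple, int] = {}
    n_components = 0
    covered = np.zeros(points.shape[0], dtype=bool)
    n_covered = 0
    kept = np.zeros(n_tets, dtype=bool)
    alpha = float(radii[order[-1]])
    for t in order:
        kept[t] = True
        n_components += 1
        verts = tri.simplices[t]
        for drop in range(4):
            face = tuple(sorted(np.delete(verts, drop)))
            other = faces.get(face)
            if other is None:
                faces[face] = t
            elif uf.union(t, other):
                n_components -= 1
        for v in verts:
            if not covered[v]:
                covered[v] = True
                n_covered += 1
        if n_components == 1 and n_covered == points.shape[0]:
            alpha = float(radii[t])
            break
    return AlphaShape(
        points=points,
        delaunay=tri,
        kept=kept,
        alpha=alpha,
        volume=float(volumes[kept].sum()),
    )


def sample_inside(shape: AlphaShape, n_samples: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample approximately uniform points inside an alpha shape."""
    if shape.volume <= 0:
        raise UndefinedOverlapError("reference shape has zero volume")
    lo, hi = shape.bounding_box
    accepted = []
    n_acc = 0
    for _ in range(50):
        proposals = rng.uniform(lo, hi, size=(n_samples, 3))
        inside = shape.contains(proposals)
        pts = proposals[inside]
        if pts.size:
            accepted.append(pts)
            n_acc += pts.shape[0]
        if n_acc >= n_samples:
            break
    if n_acc == 0:
        raise UndefinedOverlapError("no Monte-Carlo sample fell inside the shape")
    return np.concatenate(accepted)[:n_samples]


def pairwise_overlap_percent(volume_a: AlphaShape, volume_b: AlphaShape,
                             mc_samples: int = 100_000,
                             rng: np.random.Generator | None = None,
                             samples_in_a: np.ndarray | None = None) -> float:
    """Percentage of a's volume shared with b (Monte-Carlo estimate).

    ``samples_in_a`` lets callers reuse one sample set for many partners b.
    """
    if volume_a.volume <= 0:
        raise UndefinedOverlapError("reference volume is zero; overlap undefined")
    if samples_in_a is None:
        rng = rng or np.random.default_rng(0)
        samples_in_a = sample_inside(volume_a, mc_samples, rng)
    return float(volume_b.contains(samples_in_a).mean() * 100.0)


# ---------------------------------------------------------------------------
# Overlap curves


@dataclass
class OverlapCurve:
    """Mean +/- SEM pairwise overlap per subset size for one direction."""

    sizes: np.ndarray
    mean_overlap: np.ndarray  # percent; NaN where a size failed
    sem_overlap: np.ndarray
    direction: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"size": self.sizes, "direction": self.direction,
             "mean_overlap": self.mean_overlap, "sem_overlap": self.sem_overlap}
        )


def participant_overlaps(scores: np.ndarray, participants: np.ndarray,
                         config: OverlapConfig) -> np.ndarray:
    """All ordered-pair overlap percentages for one projected subspace."""
    participants = np.asarray(participants)
    ids = pd.unique(participants)
    shapes = {}
    for pid in ids:
        pts = scores[participants == pid]
        if pts.shape[0] < config.min_points_per_participant:
            warnings.warn(f"participant {pid}: too few points for a volume")
            continue
        shapes[pid] = bounding_volume(pts, jitter_seed=config.seed)
    pair_values = []
    for a in ids:
        if a not in shapes or shapes[a].volume <= 0:
            continue
        rng = np.random.default_rng(
            [config.seed, 499, int(np.flatnonzero(ids == a)[0])]
        )
        samples = sample_inside(shapes[a], config.mc_samples, rng)
        for b in ids:
            if b == a or b not in shapes:
                continue
            pair_values.append(
                pairwise_overlap_percent(shapes[a], shapes[b],
                                         samples_in_a=samples)
            )
    return np.asarray(pair_values)


def overlap_curve(matrix: np.ndarray, participants: np.ndarray,
                  ranked: RankedVariables, config: OverlapConfig,
                  direction: str) -> OverlapCurve:
    """Mean pairwise overlap as the variable subset grows by five.

    For each size in the schedule the matrix is restricted to the top/bottom
    variables, freshly projected onto three principal axes, bounded per
    participant and compared pairwise. A failure at one size (degenerate
    subspace, for instance) records NaN and the run continues.
    """
    matrix = np.asarray(matrix, dtype=float)
    sizes = subset_schedule(config, ranked.n_variables)
    means = np.full(sizes.shape, np.nan)
    sems = np.full(sizes.shape, np.nan)
    for i, k in enumerate(sizes):
        try:
            cols = select_subset(ranked, int(k), direction)
            scores, _ = pca3_project(matrix[:, cols], config.n_components)
            values = participant_overlaps(scores, participants, config)
        except (DegenerateSubspaceError, UndefinedOverlapError, QhullError) as exc:
            warnings.warn(f"size {k} failed ({exc}); recorded as missing")
            continue
        if values.size == 0:
            continue
        means[i] = values.mean()
        sems[i] = values.std(ddof=1) / np.sqrt(values.size) if values.size > 1 else 0.0
    return OverlapCurve(sizes=sizes, mean_overlap=means, sem_overlap=sems,
                        direction=direction)


# ---------------------------------------------------------------------------
# Variable profiling


MOVEMENT_LABELS = {
    "flexion": "flexion/extension",
    "abduction": "ab-/adduction",
    "rotation": "int/ext rotation",
}


@dataclass
class VariableProfile:
    """Stratified composition of an extreme-relevance variable subset."""

    direction: str
    subset: np.ndarray
    by_movement: pd.Series  # fraction per movement type
    by_time: np.ndarray  # count per timepoint (1-based positions)
    by_time_smoothed: np.ndarray  # 5-point moving average of by_time
    by_group: pd.Series  # fraction per {spine, upper, lower}


def _moving_average(counts: np.ndarray, window: int = 5) -> np.ndarray:
    kernel = np.ones(window) / window
    return np.convolve(counts, kernel, mode="same")


def profile_variables(ranked: RankedVariables, k: int | None = None
                      ) -> dict[str, VariableProfile]:
    """Profile the k most and least relevant variables (default: top 10%).

    Fractions per stratification sum to one; the time histogram is reported
    raw and with a 5-point moving average.
    """
    layout = ranked.layout
    if k is None:
        k = ranked.n_variables // 10
    desc = layout.descriptor_frame()
    out = {}
    for direction in ("most_relevant", "least_relevant"):
        subset = select_subset(ranked, k, direction)
        sub = desc.iloc[subset]
        by_movement = (
            sub["plane"].map(MOVEMENT_LABELS).value_counts(normalize=True)
            .reindex(MOVEMENT_LABELS.values(), fill_value=0.0)
        )
        counts = np.bincount(sub["timepoint"].to_numpy() - 1,
                             minlength=layout.n_timepoints).astype(float)
        by_group = (
            sub["group"].value_counts(normalize=True)
            .reindex(["spine", "upper", "lower"], fill_value=0.0)
        )
        out[direction] = VariableProfile(
            direction=direction,
            subset=subset,
            by_movement=by_movement,
            by_time=counts,
            by_time_smoothed=_moving_average(counts),
            by_group=by_group,
        )
    return out
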