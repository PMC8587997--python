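"""Outlier removal and scaling of step cycles; analysis-matrix assembly.

Per participant, step cycles are projected onto their first three principal
axes and screened with local outlier probabilities (LoOP; Kriegel et al.,
CIKM 2009): a k-nearest-neighbour density construction that yields a
calibrated outlier probability in [0, 1] per cycle. Surviving cycles are
scaled individually — z-scored over their own variables and rescaled so the
largest magnitude is exactly 1 — and stacked into a single data matrix whose
columns follow the canonical variable layout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import erf
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .errors import DegenerateInputError, InvalidConfigError, SchemaError
from .gait_events import StepCycle
from .layout import VariableLayout


@dataclass(frozen=True)
class OutlierConfig:
    """LoOP screening parameters (Kriegel et al. defaults)."""

    n_components: int = 3
    k_neighbors: int = 20
    lambda_: float = 3.0
    probability_cutoff: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.probability_cutoff <= 1.0:
            raise InvalidConfigError("probability_cutoff must lie in (0, 1]")
        if self.k_neighbors < 2:
            raise InvalidConfigError("k_neighbors must be at least 2")


def loop_outlier_probabilities(points: np.ndarray,
                               config: OutlierConfig | None = None) -> np.ndarray:
    """Local outlier probability of every point in a small point cloud.

    Implements the LoOP construction: the probabilistic set distance of a
    point is ``lambda`` times the quadratic mean of its k-nearest-neighbour
    distances; its PLOF compares that distance with the expectation over its
    neighbours; PLOF values are normalized by their quadratic mean (nPLOF)
    and squashed through the Gaussian error function.
    """
    config = config or OutlierConfig()
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    k = config.k_neighbors
    if n <= k:
        raise InvalidConfigError(f"need more than k_neighbors={k} points, got {n}")
    nn = NearestNeighbors(n_neighbors=k + 1, algorithm="brute")
    nn.fit(points)
    dist, idx = nn.kneighbors(points)
    dist, idx = dist[:, 1:], idx[:, 1:]  # drop self
    sigma = np.sqrt(np.mean(dist**2, axis=1))
    pdist = config.lambda_ * sigma
    expected = np.mean(pdist[idx], axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        plof = np.where(expected > 0, pdist / expected - 1.0, 0.0)
    nplof = config.lambda_ * np.sqrt(np.mean(plof**2))
    if nplof <= 0:
        return np.zeros(n)
    return np.maximum(0.0, erf(plof / (nplof * np.sqrt(2.0))))


def filter_outliers(matrix: np.ndarray, participants: np.ndarray,
                    config: OutlierConfig | None = None
                    ) -> tuple[np.ndarray, pd.DataFrame]:
    """Screen cycles participant-wise; return a keep-mask and a report.

    For each participant the flattened cycles are reduced to loadings on
    their first three principal axes (mean-centred PCA, no variance
    scaling); cycles whose LoOP probability exceeds the cutoff are dropped.
    Participants with too few cycles for the neighbourhood size are kept
    unscreened, with a warning.
    """
    config = config or OutlierConfig()
    matrix = np.asarray(matrix, dtype=float)
    participants = np.asarray(participants)
    keep = np.ones(matrix.shape[0], dtype=bool)
    rows = []
    for pid in pd.unique(participants):
        sel = np.flatnonzero(participants == pid)
        n_p = sel.size
        if n_p <= config.k_neighbors:
            warnings.warn(
                f"participant {pid}: only {n_p} cycles "
                f"(need > {config.k_neighbors}); outlier screening skipped"
            )
            rows.append((pid, n_p, 0, True))
            continue
        n_comp = min(config.n_components, n_p - 1, matrix.shape[1])
        pca = PCA(n_components=n_comp, svd_solver="full")
        loadings = pca.fit_transform(matrix[sel])
        probs = loop_outlier_probabilities(loadings, config)
        drop = probs > config.probability_cutoff
        keep[sel[drop]] = False
        rows.append((pid, n_p, int(drop.sum()), False))
    report = pd.DataFrame(
        rows, columns=["participant", "n_cycles", "n_removed", "skipped"]
    )
    return keep, report


def scale_cycle(values: np.ndarray) -> np.ndarray:
    """Scale one flattened cycle to [-1, 1].

    Subtract the cycle's own mean, divide by its own standard deviation,
    then divide by the maximum absolute z-score so the extreme value sits
    exactly at -1 or +1. Affine transforms of the input (positive gain)
    leave the output unchanged, and the operation is idempotent.
    """
    values = np.asarray(values, dtype=float)
    sd = values.std()
    if sd == 0:
        raise DegenerateInputError("cycle has zero variance; cannot scale")
    z = (values - values.mean()) / sd
    return z / np.abs(z).max()


def scale_matrix(matrix: np.ndarray) -> np.ndarray:
    """Row-wise :func:`scale_cycle` over a cycles-by-variables matrix."""
    matrix = np.asarray(matrix, dtype=float)
    sd = matrix.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd[:, 0] == 0)
        raise DegenerateInputError(f"cycles {bad.tolist()} have zero variance")
    z = (matrix - matrix.mean(axis=1, keepdims=True)) / sd
    return z / np.abs(z).max(axis=1, keepdims=True)


@dataclass
class DataMatrix:
    """Scaled step cycles stacked row-wise, with a label index.

    ``values`` is ``(n_cycles, n_variables)`` with every entry in [-1, 1];
    ``index`` holds one row of (participant, trial, standing_side,
    start_index) per cycle; columns follow the canonical layout.
    """

    values: np.ndarray
    index: pd.DataFrame
    layout: VariableLayout

    @property
    def n_cycles(self) -> int:
        return int(self.values.shape[0])

    def restrict(self, trials) -> "DataMatrix":
        """Sub-matrix containing only cycles from the given trial labels."""
        mask = self.index["trial"].isin(list(trials)).to_numpy()
        return DataMatrix(
            values=self.values[mask],
            index=self.index.loc[mask].reset_index(drop=True),
            layout=self.layout,
        )

    def save(self, array_path, index_path) -> None:
        np.savez_compressed(array_path, values=self.values,
                            n_timepoints=self.layout.n_timepoints)
        self.index.to_csv(index_path, index=False)

    @classmethod
    def load(cls, array_path, index_path) -> "DataMatrix":
        with np.load(array_path) as data:
            values = data["values"]
            layout = VariableLayout(int(data["n_timepoints"]))
        index = pd.read_csv(index_path)
        return cls(values=values, index=index, layout=layout)


def assemble_matrix(cycles: list[StepCycle],
                    layout: VariableLayout | None = None,
                    scale: bool = True) -> DataMatrix:
    """Stack (optionally scaled) canonical cycles into one DataMatrix.

    Rows are ordered deterministically by (participant, trial, cycle onset).
    """
    if not cycles:
        layout = layout or VariableLayout()
        return DataMatrix(
            values=np.empty((0, layout.n_variables)),
            index=pd.DataFrame(
                columns=["participant", "trial", "standing_side", "start_index"]
            ),
            layout=layout,
        )
    n_t = cycles[0].values.shape[0]
    layout = layout or VariableLayout(n_t)
    for c in cycles:
        if c.values.shape != (layout.n_timepoints, 18, 3):
            raise SchemaError(
                f"cycle shape {c.values.shape} does not match layout "
                f"({layout.n_timepoints}, 18, 3)"
            )
    order = sorted(
        range(len(cycles)),
        key=lambda i: (cycles[i].participant_id, cycles[i].trial_label,
                       cycles[i].start_index),
    )
    rows = np.stack([layout.flatten(cycles[i].values) for i in order])
    if scale:
        rows = scale_matrix(rows)
    index = pd.DataFrame(
        {
            "participant": [cycles[i].participant_id for i in order],
            "trial": [cycles[i].trial_label for i in order],
            "standing_side": [cycles[i].standing_side for i in order],
            "start_index": [cycles[i].start_index for i in order],
        }
    )
    return DataMatrix(values=rows, index=index, layout=layout)
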