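"""Layer-wise relevance propagation and relevance-pattern aggregation.

The pre-softmax score of the predicted output node is redistributed
backwards through the network with the epsilon rule,

    R_j = sum_k  a_j w_jk / (sum_j' a_j' w_j'k + eps * sign(...))  *  R_k ,

so each input variable of a correctly classified step cycle receives one
relevance score (its relevance pattern). The tanh nonlinearity passes
relevance through unchanged and biases are left out of the denominator,
which keeps the total relevance conserved up to epsilon-driven error at
every layer transition.

Patterns are then smoothed along each joint/plane trajectory with a
(0.25, 0.50, 0.25) kernel applied twice, averaged participant-wise,
rectified and max-normalized, and finally averaged across participants and
ranked in descending order of importance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractViolationError, InvalidConfigError, PipelineOrderError
from .layout import VariableLayout
from .network import NetworkWeights, forward

STAGES = ("raw", "smoothed", "participant_mean", "rectified_normalized",
          "overall_mean")


@dataclass(frozen=True)
class LrpConfig:
    """Epsilon-rule stabilizer and smoothing settings."""

    epsilon: float = 1e-6
    smoothing_weights: tuple[float, float, float] = (0.25, 0.50, 0.25)
    smoothing_passes: int = 2

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise InvalidConfigError("epsilon must be positive")
        if abs(sum(self.smoothing_weights) - 1.0) > 1e-12:
            raise InvalidConfigError("smoothing weights must sum to 1")


@dataclass
class RelevancePattern:
    """Relevance scores aligned to the canonical variable layout."""

    scores: np.ndarray
    stage: str
    participant_id: str | None = None

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise InvalidConfigError(f"unknown stage {self.stage!r}")


def _eps_divide(numer: np.ndarray, denom: np.ndarray, eps: float) -> np.ndarray:
    sign = np.where(denom >= 0, 1.0, -1.0)
    return numer / (denom + eps * sign)


def propagate_relevance_batch(weights: NetworkWeights, x: np.ndarray,
                              targets: np.ndarray,
                              config: LrpConfig | None = None) -> np.ndarray:
    """Epsilon-rule input relevances for a batch of cycles.

    ``targets`` gives the output-node index explained for each row; the
    explained quantity is that node's pre-softmax score.
    """
    config = config or LrpConfig()
    x = np.atleast_2d(np.asarray(x, dtype=float))
    targets = np.atleast_1d(np.asarray(targets, dtype=int))
    hidden, _ = forward(weights, x)
    eps = config.epsilon

    # output layer -> hidden layer; only the target node carries relevance
    w2_t = weights.w2[:, targets].T  # (n, hidden)
    z_hk = hidden * w2_t
    denom_k = z_hk.sum(axis=1, keepdims=True)
    # relevance starts at the explained quantity: the target node's
    # pre-softmax score; redistribution shares exclude the bias term
    r_out = denom_k + weights.b2[targets][:, None]
    r_hidden = _eps_divide(z_hk, denom_k, eps) * r_out

    # hidden layer -> input layer (tanh treated as transparent)
    pre = x @ weights.w1  # (n, hidden), bias excluded by the rule
    share = _eps_divide(r_hidden, pre, eps)  # (n, hidden)
    r_input = (share @ weights.w1.T) * x
    return r_input


def propagate_relevance(weights: NetworkWeights, cycle: np.ndarray,
                        target_class, config: LrpConfig | None = None
                        ) -> RelevancePattern:
    """Relevance pattern of one cycle for its (correct) predicted class.

    The caller must only pass correctly classified cycles; passing a cycle
    whose prediction differs from ``target_class`` raises a contract
    violation, mirroring the restriction of the analysis to correct
    classifications.
    """
    cycle = np.asarray(cycle, dtype=float).reshape(1, -1)
    _, scores = forward(weights, cycle)
    predicted = weights.classes[int(scores.argmax(axis=1)[0])]
    if predicted != target_class:
        raise ContractViolationError(
            f"cycle classified as {predicted!r}, not {target_class!r}; "
            "relevance is only defined for correct classifications"
        )
    t_idx = int(np.flatnonzero(weights.classes == target_class)[0])
    scores = propagate_relevance_batch(weights, cycle, np.asarray([t_idx]), config)
    return RelevancePattern(scores=scores[0], stage="raw")


def relevance_for_cycles(weights: NetworkWeights, x: np.ndarray,
                         labels: np.ndarray,
                         config: LrpConfig | None = None
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Raw relevance patterns for every correctly classified cycle.

    Returns ``(patterns, correct_mask)``; rows of ``patterns`` correspond to
    the cycles where ``correct_mask`` is True.
    """
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    _, scores = forward(weights, x)
    pred = weights.classes[scores.argmax(axis=1)]
    correct = pred == labels
    class_index = {c: i for i, c in enumerate(weights.classes.tolist())}
    targets = np.asarray([class_index[c] for c in labels[correct]])
    patterns = propagate_relevance_batch(weights, x[correct], targets, config)
    return patterns, correct


def _smooth_rows(rows: np.ndarray, kernel: tuple[float, float, float]) -> np.ndarray:
    """One pass of the 3-point kernel along axis 1, truncated-renormalized edges."""
    prev_w, mid_w, next_w = kernel
    out = mid_w * rows.copy()
    out[:, 1:] += prev_w * rows[:, :-1]
    out[:, :-1] += next_w * rows[:, 1:]
    # renormalize the truncated edge kernels so weights still sum to 1
    out[:, 0] /= mid_w + next_w
    out[:, -1] /= prev_w + mid_w
    return out


def smooth_pattern_matrix(patterns: np.ndarray, layout: VariableLayout,
                          config: LrpConfig | None = None) -> np.ndarray:
    """Smooth many raw patterns along the timepoint axis of each trajectory."""
    config = config or LrpConfig()
    patterns = np.asarray(patterns, dtype=float)
    single = patterns.ndim == 1
    patterns = np.atleast_2d(patterns)
    n = patterns.shape[0]
    T = layout.n_timepoints
    rows = patterns.reshape(n * (patterns.shape[1] // T), T)
    for _ in range(config.smoothing_passes):
        rows = _smooth_rows(rows, config.smoothing_weights)
    out = rows.reshape(patterns.shape)
    return out[0] if single else out


def smooth_relevance(pattern: RelevancePattern, layout: VariableLayout,
                     config: LrpConfig | None = None) -> RelevancePattern:
    """Smooth a raw relevance pattern (kernel applied within trajectories only)."""
    if pattern.stage != "raw":
        raise PipelineOrderError(
            f"smoothing expects a raw pattern, got stage {pattern.stage!r}"
        )
    scores = smooth_pattern_matrix(pattern.scores, layout, config)
    return RelevancePattern(scores=scores, stage="smoothed",
                            participant_id=pattern.participant_id)


@dataclass
class RankedVariables:
    """Variables ordered by descending overall mean relevance."""

    order: np.ndarray  # permutation of flat indices, most relevant first
    scores: np.ndarray  # relevance sorted to match `order` (non-increasing)
    layout: VariableLayout

    @property
    def n_variables(self) -> int:
        return int(self.order.shape[0])

    def to_frame(self) -> pd.DataFrame:
        desc = self.layout.descriptor_frame().iloc[self.order].reset_index(drop=True)
        desc.insert(0, "rank", np.arange(1, self.n_variables + 1))
        desc["score"] = self.scores
        return desc


def aggregate_relevance(patterns: np.ndarray, participants: np.ndarray,
                        layout: VariableLayout
                        ) -> tuple[dict[str, np.ndarray], np.ndarray, RankedVariables]:
    """Participant-wise aggregation and overall descending ranking.

    Per participant: mean over that participant's smoothed patterns,
    rectification (absolute value) and division by the maximum, giving
    values in [0, 1] with the most relevant variable at exactly 1. The
    overall pattern is the across-participant mean of those, again
    max-normalized; ties in the final descending sort break by ascending
    flat index.

    Returns (per-participant patterns, overall pattern, ranking).
    """
    patterns = np.asarray(patterns, dtype=float)
    participants = np.asarray(participants)
    per_participant: dict[str, np.ndarray] = {}
    for pid in pd.unique(participants):
        sel = participants == pid
        if not sel.any():
            warnings.warn(f"participant {pid} has no patterns; excluded")
            continue
        mean = np.abs(patterns[sel].mean(axis=0))
        peak = mean.max()
        if peak <= 0:
            warnings.warn(f"participant {pid} has an all-zero pattern; excluded")
            continue
        per_participant[str(pid)] = mean / peak
    if not per_participant:
        raise InvalidConfigError("no participant produced a usable pattern")
    overall = np.mean(list(per_participant.values()), axis=0)
    overall = overall / overall.max()
    order = np.argsort(-overall, kind="stable")
    ranked = RankedVariables(order=order, scores=overall[order], layout=layout)
    return per_participant, overall, ranked
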