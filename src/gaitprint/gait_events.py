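"""Gait-event detection and step-cycle extraction.

Touch-downs and take-offs are found from the vertical foot (calcaneus) and
toe (metatarsal) positions: swing maxima of each side's mean foot/toe
trajectory delimit search windows, and within each window the contact onset
is the first sample at which either the foot or the toe drops below a
threshold set 2 cm above that channel's local minimum (the offset is the
last such sample). Considering both markers keeps the rule consistent for
rearfoot and forefoot strike patterns.

A step cycle is the period between two consecutive touch-downs of opposite
feet. Cycles are linearly resampled to a fixed number of timepoints
(100 by default), trunk frontal/transverse angles of left-standing cycles
are mirrored, and extremity channels are relabeled from left/right to
standing/swinging so all cycles share one canonical layout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .errors import DegenerateInputError, TooShortError
from .layout import EXTREMITY_BASES, SPINE_JOINTS, VariableLayout
from .synthetic import RawTrial


@dataclass(frozen=True)
class EventConfig:
    """Threshold rule parameters for contact detection."""

    threshold_above_min: float = 0.02  # metres above the window-local minimum
    min_peak_separation: float = 0.2  # seconds between swing maxima

    def __post_init__(self) -> None:
        if self.threshold_above_min <= 0:
            raise ValueError("threshold_above_min must be positive")


@dataclass
class GaitEvents:
    """Detected contact events, merged across sides, index-sorted."""

    touchdowns: np.ndarray  # sample indices
    touchdown_sides: list[str]
    takeoffs: np.ndarray
    takeoff_sides: list[str]

    @property
    def n_touchdowns(self) -> int:
        return int(self.touchdowns.shape[0])


@dataclass
class StepCycle:
    """One step cycle of joint angles.

    ``values`` is ``(n_timepoints, 18, 3)``. Before :func:`mirror_and_relabel`
    the joint axis follows the raw left/right roster; afterwards it follows
    the canonical standing/swinging roster shared by the whole package.
    """

    values: np.ndarray
    participant_id: str
    trial_label: str
    standing_side: str  # 'L' or 'R'
    start_index: int
    end_index: int
    canonical: bool = False

    def flatten(self, layout: VariableLayout | None = None) -> np.ndarray:
        layout = layout or VariableLayout(self.values.shape[0])
        return layout.flatten(self.values)


def _side_events(foot: np.ndarray, toe: np.ndarray, side: str,
                 config: EventConfig, fs: float):
    """Contact on/offsets for one side from its foot and toe heights."""
    mean_traj = 0.5 * (foot + toe)
    span = float(mean_traj.max() - mean_traj.min())
    if span <= 1e-9:
        return [], []
    distance = max(1, int(round(config.min_peak_separation * fs)))
    peaks, _ = find_peaks(mean_traj, distance=distance, prominence=0.25 * span)
    touchdowns, takeoffs = [], []
    for a, b in zip(peaks[:-1], peaks[1:]):
        window = slice(a, b + 1)
        below = np.zeros(b + 1 - a, dtype=bool)
        for channel in (foot, toe):
            seg = channel[window]
            below |= seg < (seg.min() + config.threshold_above_min)
        idx = np.flatnonzero(below)
        if idx.size == 0:
            continue
        touchdowns.append(a + idx[0])
        takeoffs.append(a + idx[-1])
    return touchdowns, takeoffs


def detect_events(trial: RawTrial, config: EventConfig | None = None,
                  sampling_rate: float | None = None) -> GaitEvents:
    """Detect touch-down and take-off events in a continuous recording."""
    config = config or EventConfig()
    heights = np.concatenate(
        [trial.foot_height_left, trial.foot_height_right,
         trial.toe_height_left, trial.toe_height_right]
    )
    if heights.shape[0] < 4:
        raise TooShortError("height channels too short for event detection")
    if heights.max() <= 0:
        raise DegenerateInputError("height channels are non-positive everywhere")
    if sampling_rate is None:
        dt = np.diff(trial.time)
        sampling_rate = 1.0 / float(np.median(dt)) if dt.size else 1.0

    events = []
    for side, foot, toe in (
        ("L", trial.foot_height_left, trial.toe_height_left),
        ("R", trial.foot_height_right, trial.toe_height_right),
    ):
        tds, tos = _side_events(foot, toe, side, config, sampling_rate)
        events.extend(("td", i, side) for i in tds)
        events.extend(("to", i, side) for i in tos)
    events.sort(key=lambda e: (e[1], e[0]))
    td_idx = [i for kind, i, _ in events if kind == "td"]
    td_side = [s for kind, _, s in events if kind == "td"]
    to_idx = [i for kind, i, _ in events if kind == "to"]
    to_side = [s for kind, _, s in events if kind == "to"]
    return GaitEvents(
        touchdowns=np.asarray(td_idx, dtype=int),
        touchdown_sides=td_side,
        takeoffs=np.asarray(to_idx, dtype=int),
        takeoff_sides=to_side,
    )


def segment_step_cycles(trial: RawTrial, events: GaitEvents) -> list[StepCycle]:
    """Cut the recording into step cycles between consecutive touch-downs.

    The touchdown opening a cycle defines its standing side; pairs of
    same-side touchdowns (a missed contact in between) are skipped. The
    trailing segment after the last touchdown is dropped.
    """
    if events.n_touchdowns < 2:
        warnings.warn("fewer than 2 touchdowns: no step cycles segmented")
        return []
    cycles = []
    for k in range(events.n_touchdowns - 1):
        i, j = int(events.touchdowns[k]), int(events.touchdowns[k + 1])
        side_i, side_j = events.touchdown_sides[k], events.touchdown_sides[k + 1]
        if side_i == side_j:
            warnings.warn(
                f"touchdowns {i} and {j} are both side {side_i}; cycle skipped"
            )
            continue
        cycles.append(
            StepCycle(
                values=trial.joint_angles[i : j + 1].copy(),
                participant_id=trial.participant_id,
                trial_label=trial.trial_label,
                standing_side=side_i,
                start_index=i,
                end_index=j,
            )
        )
    return cycles


def time_normalize(values: np.ndarray, n_timepoints: int = 100) -> np.ndarray:
    """Linearly resample a cycle to ``n_timepoints`` equally spaced phases.

    Both endpoints are preserved; each joint/plane channel is interpolated
    independently.
    """
    values = np.asarray(values, dtype=float)
    m = values.shape[0]
    if m < 2:
        raise TooShortError("cycle must contain at least 2 samples")
    if m == n_timepoints:
        return values.copy()
    src = np.linspace(0.0, 1.0, m)
    dst = np.linspace(0.0, 1.0, n_timepoints)
    flat = values.reshape(m, -1)
    out = np.empty((n_timepoints, flat.shape[1]))
    for c in range(flat.shape[1]):
        out[:, c] = np.interp(dst, src, flat[:, c])
    return out.reshape((n_timepoints,) + values.shape[1:])


# raw roster: spine joints occupy the first 6 slots, then L/R pairs per base
_SPINE_SLICE = slice(0, len(SPINE_JOINTS))


def mirror_and_relabel(cycle: StepCycle) -> StepCycle:
    """Mirror trunk angles of left-standing cycles and relabel extremities.

    For left-standing cycles, spine frontal (abduction) and transverse
    (rotation) angles are sign-flipped; sagittal angles are never modified.
    Extremity joints are reordered from left/right to standing/swinging
    pairs. Applying the operation twice restores the original values.
    """
    values = cycle.values.copy()
    left_standing = cycle.standing_side == "L"
    if left_standing:
        values[:, _SPINE_SLICE, 0] *= -1.0  # abduction / frontal plane
        values[:, _SPINE_SLICE, 1] *= -1.0  # rotation / transverse plane
    n_spine = len(SPINE_JOINTS)
    for b in range(len(EXTREMITY_BASES)):
        first = n_spine + 2 * b
        pair = cycle.values[:, (first, first + 1), :]
        if left_standing:
            values[:, first, :] = pair[:, 0, :]  # L is standing
            values[:, first + 1, :] = pair[:, 1, :]
        else:
            values[:, first, :] = pair[:, 1, :]  # R is standing
            values[:, first + 1, :] = pair[:, 0, :]
    return StepCycle(
        values=values,
        participant_id=cycle.participant_id,
        trial_label=cycle.trial_label,
        standing_side=cycle.standing_side,
        start_index=cycle.start_index,
        end_index=cycle.end_index,
        canonical=not cycle.canonical,
    )


def process_trial(trial: RawTrial, event_config: EventConfig | None = None,
                  n_timepoints: int = 100) -> list[StepCycle]:
    """Detect events, segment, time-normalize and canonicalize one trial."""
    events = detect_events(trial, event_config)
    cycles = []
    for raw in segment_step_cycles(trial, events):
        normalized = StepCycle(
            values=time_normalize(raw.values, n_timepoints),
            participant_id=raw.participant_id,
            trial_label=raw.trial_label,
            standing_side=raw.standing_side,
            start_index=raw.start_index,
            end_index=raw.end_index,
        )
        cycles.append(mirror_and_relabel(normalized))
    return cycles


def touchdown_error_ms(trial: RawTrial, events: GaitEvents,
                       sampling_rate: float | None = None) -> float:
    """Mean absolute touchdown timing error against ground truth, in ms.

    Each detected touchdown is matched to the nearest ground-truth contact
    onset of the same side; detections further than one step from any truth
    event are ignored.
    """
    if sampling_rate is None:
        sampling_rate = 1.0 / float(np.median(np.diff(trial.time)))
    errors = []
    truth = trial.true_touchdowns
    truth_sides = np.asarray(trial.true_touchdown_sides)
    for idx, side in zip(events.touchdowns, events.touchdown_sides):
        candidates = truth[truth_sides == side]
        if candidates.size == 0:
            continue
        err = np.abs(candidates - idx).min()
        if err < sampling_rate * 0.5:  # within half a second
            errors.append(err)
    if not errors:
        raise DegenerateInputError("no detected touchdowns matched ground truth")
    return float(np.mean(errors)) / sampling_rate * 1000.0
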