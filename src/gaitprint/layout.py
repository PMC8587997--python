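"""Canonical variable layout for flattened step cycles.

A time-normalized step cycle is a ``(n_timepoints, 18, 3)`` array of joint
angles: 18 joint locations (6 spine joints plus the standing- and
swinging-side shoulder, elbow, wrist, hip, knee and ankle) times 3 movement
planes per joint. Within each joint the plane rows are ordered abduction
(frontal plane), rotation (transverse plane), flexion (sagittal plane).

Flattening is joint-major with the timepoint running fastest::

    flat_index = (joint_index * 3 + plane_index) * n_timepoints + (timepoint - 1)

so each consecutive block of ``n_timepoints`` values is one joint/plane
trajectory. At the default 100 timepoints a cycle flattens to exactly
5400 variables. Every module in the package shares this layout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

SPINE_JOINTS = ("L5S1", "L4L3", "L1T12", "T9T8", "T1C7", "C1Head")
EXTREMITY_BASES = ("Shoulder", "Elbow", "Wrist", "Hip", "Knee", "Ankle")

#: Canonical joint order: spine joints first, then each extremity joint as a
#: standing-side / swinging-side pair.
JOINTS: tuple[str, ...] = SPINE_JOINTS + tuple(
    f"{base}-{side}" for base in EXTREMITY_BASES for side in ("st.", "sw.")
)

#: Raw (pre-relabeling) joint order used by continuous recordings: spine
#: joints, then each extremity joint as a left / right pair.
RAW_JOINTS: tuple[str, ...] = SPINE_JOINTS + tuple(
    f"{base}-{side}" for base in EXTREMITY_BASES for side in ("L", "R")
)

PLANES = ("abduction", "rotation", "flexion")

N_JOINTS = len(JOINTS)
N_PLANES = len(PLANES)
DEFAULT_TIMEPOINTS = 100
FULL_N_VARIABLES = N_JOINTS * N_PLANES * DEFAULT_TIMEPOINTS  # 5400

UPPER_BASES = ("Shoulder", "Elbow", "Wrist")
LOWER_BASES = ("Hip", "Knee", "Ankle")


def joint_group(joint: str) -> str:
    """Anatomical group of a canonical joint label: spine, upper or lower."""
    if joint in SPINE_JOINTS:
        return "spine"
    base = joint.split("-")[0]
    if base in UPPER_BASES:
        return "upper"
    if base in LOWER_BASES:
        return "lower"
    raise ValueError(f"unknown joint label: {joint!r}")


@dataclass(frozen=True)
class VariableDescriptor:
    """Human-readable identity of one flattened step-cycle variable."""

    flat_index: int
    joint: str
    plane: str
    timepoint: int  # 1-based position within the normalized cycle
    group: str


@dataclass(frozen=True)
class VariableLayout:
    """Bijection between flat indices and (joint, plane, timepoint) triples.

    Parameters
    ----------
    n_timepoints
        Number of samples per normalized joint/plane trajectory. 100 is the
        canonical full-scale value (5400 variables); smaller values give the
        reduced layouts used for fast experimentation.
    """

    n_timepoints: int = DEFAULT_TIMEPOINTS

    def __post_init__(self) -> None:
        if self.n_timepoints < 2:
            raise ValueError("n_timepoints must be at least 2")

    @property
    def n_variables(self) -> int:
        return N_JOINTS * N_PLANES * self.n_timepoints

    def flat_index(self, joint: str, plane: str, timepoint: int) -> int:
        """Flat index of (joint label, plane label, 1-based timepoint)."""
        j = JOINTS.index(joint)
        p = PLANES.index(plane)
        if not 1 <= timepoint <= self.n_timepoints:
            raise ValueError(f"timepoint {timepoint} outside 1..{self.n_timepoints}")
        return (j * N_PLANES + p) * self.n_timepoints + (timepoint - 1)

    def descriptor(self, flat_index: int) -> VariableDescriptor:
        """Inverse of :meth:`flat_index`."""
        if not 0 <= flat_index < self.n_variables:
            raise IndexError(f"flat index {flat_index} outside 0..{self.n_variables - 1}")
        traj, t = divmod(flat_index, self.n_timepoints)
        j, p = divmod(traj, N_PLANES)
        joint = JOINTS[j]
        return VariableDescriptor(
            flat_index=flat_index,
            joint=joint,
            plane=PLANES[p],
            timepoint=t + 1,
            group=joint_group(joint),
        )

    def flatten(self, cycle: np.ndarray) -> np.ndarray:
        """Flatten a ``(n_timepoints, 18, 3)`` cycle into canonical order."""
        cycle = np.asarray(cycle)
        expected = (self.n_timepoints, N_JOINTS, N_PLANES)
        if cycle.shape != expected:
            raise ValueError(f"expected cycle of shape {expected}, got {cycle.shape}")
        return np.transpose(cycle, (1, 2, 0)).reshape(-1)

    def unflatten(self, flat: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`flatten`."""
        flat = np.asarray(flat)
        if flat.shape != (self.n_variables,):
            raise ValueError(f"expected {self.n_variables} values, got {flat.shape}")
        return np.transpose(
            flat.reshape(N_JOINTS, N_PLANES, self.n_timepoints), (2, 0, 1)
        )

    def timepoint_percent(self, timepoint: int) -> float:
        """Cycle phase (in %) of a 1-based timepoint; endpoints are 0 and 100."""
        return (timepoint - 1) * 100.0 / (self.n_timepoints - 1)

    def trajectory_slice(self, joint: str, plane: str) -> slice:
        """Slice of the flat vector holding one joint/plane trajectory."""
        start = self.flat_index(joint, plane, 1)
        return slice(start, start + self.n_timepoints)

    def descriptor_frame(self):
        """All descriptors as a pandas DataFrame (flat_index-ordered)."""
        import pandas as pd

        records = [self.descriptor(i) for i in range(self.n_variables)]
        return pd.DataFrame(
            {
                "flat_index": [d.flat_index for d in records],
                "joint": [d.joint for d in records],
                "plane": [d.plane for d in records],
                "timepoint": [d.timepoint for d in records],
                "group": [d.group for d in records],
            }
        )


FULL_LAYOUT = VariableLayout(DEFAULT_TIMEPOINTS)
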