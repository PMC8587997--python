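"""Seeded synthetic running-kinematics generator.

Produces cohorts of "participants" who share one generic, periodic running
waveform per joint/plane and differ only through planted, phase-localized
signature bumps (plus optional broad-band coefficient perturbations and a
personal cadence offset). Because the individuality is planted at known
(joint, plane, phase-window) locations, the generator doubles as an oracle:
downstream relevance rankings can be scored against the ground-truth mask of
signature variables, and event detectors against ground-truth touchdowns.

Model sketch
------------
* Every canonical joint/plane trajectory is a truncated Fourier series in
  step phase ``u in [0, 1)`` (4 harmonics). Spine frontal/transverse series
  use a sine-only basis so they vanish at touchdown and can flip sign between
  left- and right-standing steps, which is what trunk mirroring undoes.
* Standing/swinging extremity trajectories are the two halves of a single
  stride-periodic series, so each physical leg's channel is continuous as it
  alternates between the standing and swinging role.
* Participant signatures are Gaussian bumps in phase, centred inside the
  configured windows, with per-participant random centre, width, sign and
  amplitude; cycle-to-cycle variability scales the bumps per step.
* Foot and toe heights follow a ``sqrt(sin)`` swing arc over a low stance
  plateau; the steep approach near ground contact keeps threshold-based
  touchdown detection sharp. Stance occupies 60% of each step cycle.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import InvalidConfigError, TooShortError
from .layout import (
    EXTREMITY_BASES,
    JOINTS,
    N_JOINTS,
    N_PLANES,
    PLANES,
    RAW_JOINTS,
    SPINE_JOINTS,
    VariableLayout,
)

#: Fraction of a step cycle the standing leg spends in ground contact.
STANCE_FRACTION = 0.6

#: Peak swing heights of the foot (calcaneus) and toe markers, metres.
FOOT_SWING_HEIGHT = 0.15
TOE_SWING_HEIGHT = 0.10

#: Resting marker height during the stance plateau, metres.
PLATEAU_HEIGHT = 0.010

#: White measurement noise on the height channels, metres.
HEIGHT_NOISE_SD = 0.002

N_HARMONICS = 4

# Characteristic angular scale (degrees) per joint base and plane
# (abduction, rotation, flexion). Sagittal amplitudes dominate, as in running.
_AMPLITUDE_SCALE = {
    "spine": (3.0, 5.0, 6.0),
    "Shoulder": (8.0, 6.0, 20.0),
    "Elbow": (4.0, 5.0, 25.0),
    "Wrist": (4.0, 5.0, 10.0),
    "Hip": (7.0, 6.0, 35.0),
    "Knee": (4.0, 5.0, 55.0),
    "Ankle": (5.0, 6.0, 22.0),
}

TRIAL_LABELS = ("CR", "WR", "TR")


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults emulate a 20-athlete running cohort recorded at 240 Hz with a
    ~0.35 s step duration; individual signatures sit around 25-35% and
    70-80% of the step cycle, in the spine and lower-extremity joints.
    """

    n_participants: int = 20
    n_joints: int = N_JOINTS
    sampling_rate: float = 240.0
    trial_duration: float = 30.0
    mean_step_duration: float = 0.35
    step_duration_jitter: float = 0.03
    noise_sd: float = 1.5
    signature_windows: tuple[tuple[float, float], ...] = ((25.0, 35.0), (70.0, 80.0))
    signature_joints: tuple[int, ...] = (0, 1, 2, 3, 12, 13, 14, 15, 16, 17)
    signature_planes: tuple[str, ...] = PLANES
    signature_amplitude: float = 10.0
    coefficient_jitter: float = 0.0
    cadence_offset_sd: float = 0.02
    bump_cycle_jitter: float = 0.10
    strike_offset_s: float = 0.005
    height_noise_sd: float = HEIGHT_NOISE_SD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise InvalidConfigError("n_participants must be at least 2")
        if self.n_joints != N_JOINTS:
            raise InvalidConfigError(
                f"the canonical joint roster is fixed at {N_JOINTS} joints"
            )
        for lo, hi in self.signature_windows:
            if not (0.0 <= lo <= hi <= 100.0):
                raise InvalidConfigError(
                    f"signature window ({lo}, {hi}) outside [0, 100]"
                )
        for sd_name in ("step_duration_jitter", "noise_sd", "bump_cycle_jitter",
                        "coefficient_jitter", "cadence_offset_sd",
                        "height_noise_sd"):
            if getattr(self, sd_name) < 0:
                raise InvalidConfigError(f"{sd_name} must be non-negative")
        for j in self.signature_joints:
            if not 0 <= j < N_JOINTS:
                raise InvalidConfigError(f"signature joint index {j} out of range")
        for p in self.signature_planes:
            if p not in PLANES:
                raise InvalidConfigError(f"unknown plane {p!r}")
        if self.sampling_rate <= 0 or self.mean_step_duration <= 0:
            raise InvalidConfigError("sampling_rate and mean_step_duration must be positive")


@dataclass(frozen=True)
class SignatureBump:
    """One planted deviation: a Gaussian in phase, Hann-tapered to vanish
    outside its window so the planted signal has compact support exactly
    inside (window_lo, window_hi). Centre/width in % of step cycle."""

    joint: int
    plane: int
    center: float
    width: float
    amplitude: float
    sign: float
    window_lo: float
    window_hi: float


@dataclass(frozen=True)
class ParticipantProfile:
    """Deterministic generative parameters of one synthetic participant."""

    participant_id: str
    index: int
    fourier_coefficients: np.ndarray  # (n_series, 2, N_HARMONICS + 1)
    signature_bumps: tuple[SignatureBump, ...]
    cadence_offset: float


# ---------------------------------------------------------------------------
# Fourier machinery
#
# Canonical series bookkeeping: spine joints carry their own per-plane series
# in step phase; each extremity base carries one stride-periodic series per
# plane whose first/second halves are the standing/swinging trajectories.
# The coefficient array rows are ordered: 6 spine joints x 3 planes, then
# 6 extremity bases x 3 planes.
_N_SPINE_SERIES = len(SPINE_JOINTS) * N_PLANES
_N_SERIES = _N_SPINE_SERIES + len(EXTREMITY_BASES) * N_PLANES


def _series_index(joint_or_base: str, plane_idx: int) -> int:
    if joint_or_base in SPINE_JOINTS:
        return SPINE_JOINTS.index(joint_or_base) * N_PLANES + plane_idx
    return _N_SPINE_SERIES + EXTREMITY_BASES.index(joint_or_base) * N_PLANES + plane_idx


def _base_coefficients(config: CohortConfig) -> np.ndarray:
    """Shared generic waveform coefficients, drawn once per cohort seed."""
    rng = np.random.default_rng([config.seed, 101])
    coeffs = np.zeros((_N_SERIES, 2, N_HARMONICS + 1))
    harmonics = np.arange(1, N_HARMONICS + 1)
    for joint in SPINE_JOINTS:
        for p in range(N_PLANES):
            scale = _AMPLITUDE_SCALE["spine"][p]
            row = _series_index(joint, p)
            if PLANES[p] == "flexion":
                coeffs[row, 0, 0] = rng.normal(0.0, scale / 2)
                coeffs[row, 0, 1:] = rng.normal(0.0, scale / harmonics)
            # frontal/transverse spine series are sine-only (vanish at
            # touchdown) so that left/right sign alternation is continuous
            coeffs[row, 1, 1:] = rng.normal(0.0, scale / harmonics)
    for base in EXTREMITY_BASES:
        for p in range(N_PLANES):
            scale = _AMPLITUDE_SCALE[base][p]
            row = _series_index(base, p)
            coeffs[row, 0, 0] = rng.normal(0.0, scale / 2)
            coeffs[row, 0, 1:] = rng.normal(0.0, scale / harmonics)
            coeffs[row, 1, 1:] = rng.normal(0.0, scale / harmonics)
    return coeffs


def _eval_series(coeffs_row: np.ndarray, phase: np.ndarray) -> np.ndarray:
    """Evaluate one truncated Fourier series at phases in [0, 1)."""
    k = np.arange(N_HARMONICS + 1)
    ang = 2.0 * np.pi * np.multiply.outer(phase, k)
    return np.cos(ang) @ coeffs_row[0] + np.sin(ang) @ coeffs_row[1]


# ---------------------------------------------------------------------------
# Cohort construction


def make_cohort(config: CohortConfig) -> list[ParticipantProfile]:
    """Create deterministic participant profiles for one cohort.

    Identical configs give byte-identical profiles. Each participant's
    signature bumps are drawn from a participant-specific stream, so
    distinct participants deviate from the shared waveform in distinct ways.
    """
    base = _base_coefficients(config)
    plane_indices = [PLANES.index(p) for p in config.signature_planes]
    profiles: list[ParticipantProfile] = []
    for i in range(config.n_participants):
        rng = np.random.default_rng([config.seed, 211, i])
        coeffs = base * (1.0 + config.coefficient_jitter * rng.standard_normal(base.shape))
        bumps: list[SignatureBump] = []
        for joint in config.signature_joints:
            for p in plane_indices:
                for lo, hi in config.signature_windows:
                    width = hi - lo
                    center = rng.uniform(lo + 0.25 * width, hi - 0.25 * width)
                    sigma = rng.uniform(0.20 * width, 0.35 * width)
                    amp = config.signature_amplitude * rng.uniform(0.8, 1.2)
                    sign = 1.0 if rng.random() < 0.5 else -1.0
                    bumps.append(
                        SignatureBump(joint, p, center, sigma, amp, sign, lo, hi)
                    )
        cadence = config.cadence_offset_sd * rng.standard_normal()
        profiles.append(
            ParticipantProfile(
                participant_id=f"P{i + 1:02d}",
                index=i,
                fourier_coefficients=coeffs,
                signature_bumps=tuple(bumps),
                cadence_offset=float(cadence),
            )
        )
    return profiles


def _bump_values(bumps, joint: int, plane: int, phase: np.ndarray,
                 amp_scale=1.0) -> np.ndarray:
    """Sum of a participant's planted bumps for one canonical trajectory.

    Each bump is a Gaussian multiplied by a flat-top (Tukey) taper over its
    window, so the planted deviation keeps its amplitude across the window
    interior yet is identically zero outside the window.
    """
    out = np.zeros_like(phase, dtype=float)
    pct = phase * 100.0
    r = 0.25  # fraction of the window tapered at each edge
    for b in bumps:
        if b.joint == joint and b.plane == plane:
            inside = (pct > b.window_lo) & (pct < b.window_hi)
            if not np.any(inside):
                continue
            rel = (pct[inside] - b.window_lo) / (b.window_hi - b.window_lo)
            edge = np.minimum(rel, 1.0 - rel)
            taper = np.where(edge < r,
                             0.5 * (1.0 - np.cos(np.pi * edge / r)), 1.0)
            gauss = np.exp(-0.5 * ((pct[inside] - b.center) / b.width) ** 2)
            out[inside] += b.sign * b.amplitude * gauss * taper
    return out * amp_scale


def expected_cycle(profile: ParticipantProfile, config: CohortConfig,
                   n_timepoints: int = 100) -> np.ndarray:
    """Noise-free canonical step cycle, shape ``(n_timepoints, 18, 3)``.

    This is the deterministic waveform a perfectly segmented, mirrored and
    relabeled cycle converges to as noise goes to zero; tests use it as the
    generator's ground truth.
    """
    u = np.linspace(0.0, 1.0, n_timepoints)
    cycle = np.zeros((n_timepoints, N_JOINTS, N_PLANES))
    for j, joint in enumerate(JOINTS):
        for p in range(N_PLANES):
            if joint in SPINE_JOINTS:
                row = profile.fourier_coefficients[_series_index(joint, p)]
                vals = _eval_series(row, u)
            else:
                base_name, role = joint.split("-")
                row = profile.fourier_coefficients[_series_index(base_name, p)]
                stride_phase = u / 2.0 if role == "st." else 0.5 + u / 2.0
                vals = _eval_series(row, stride_phase)
            vals = vals + _bump_values(profile.signature_bumps, j, p, u)
            cycle[:, j, p] = vals
    return cycle


def planted_signature_mask(config: CohortConfig,
                           layout: VariableLayout | None = None) -> np.ndarray:
    """Boolean mask over flattened variables that carry planted signatures.

    A variable is masked when its joint is a signature joint, its plane a
    signature plane, and the phase interval its timepoint represents
    intersects a signature window (endpoints included). Timepoint ``t`` of a
    ``T``-point cycle sits at phase ``(t-1)/(T-1)*100`` and represents a cell
    of width ``100/(T-1)`` centred there; at the canonical 100 timepoints the
    (25, 35) window therefore covers 11 timepoints per trajectory.
    """
    layout = layout or VariableLayout()
    mask = np.zeros(layout.n_variables, dtype=bool)
    plane_set = set(config.signature_planes)
    joint_set = {JOINTS[j] for j in config.signature_joints}
    T = layout.n_timepoints
    half = 0.5 * 100.0 / (T - 1)
    t = np.arange(1, T + 1)
    pct = (t - 1) * 100.0 / (T - 1)
    in_window = np.zeros(T, dtype=bool)
    for lo, hi in config.signature_windows:
        in_window |= (pct + half >= lo) & (pct - half <= hi)
    for joint in joint_set:
        for plane in plane_set:
            mask[layout.trajectory_slice(joint, plane)] = in_window
    return mask


# ---------------------------------------------------------------------------
# Trial synthesis


@dataclass
class RawTrial:
    """One continuous synthetic recording with ground-truth contact events."""

    participant_id: str
    trial_label: str
    time: np.ndarray
    joint_angles: np.ndarray  # (n_samples, 18, 3), RAW_JOINTS order, degrees
    foot_height_left: np.ndarray
    foot_height_right: np.ndarray
    toe_height_left: np.ndarray
    toe_height_right: np.ndarray
    true_touchdowns: np.ndarray  # sample indices
    true_touchdown_sides: list[str]  # 'L' / 'R', parallel to true_touchdowns

    @property
    def n_samples(self) -> int:
        return self.time.shape[0]


def _trial_stream(config: CohortConfig, profile_index: int, trial_label: str,
                  seed_offset: int) -> np.random.Generator:
    label_code = zlib.crc32(trial_label.encode()) % (2**16)
    return np.random.default_rng(
        [config.seed, 307, profile_index, label_code, seed_offset]
    )


def synthesize_trial(profile: ParticipantProfile, config: CohortConfig,
                     trial_label: str = "CR", seed_offset: int = 0) -> RawTrial:
    """Render one continuous noisy recording for a participant.

    Joint angles are the shared waveform plus the participant's bumps plus
    white measurement noise; bump amplitudes additionally wobble from step
    to step. Foot/toe heights get a stance plateau and a swing arc so that
    2 cm-above-minimum thresholding detects the planted contacts.
    """
    if config.trial_duration < 3 * config.mean_step_duration:
        raise TooShortError(
            f"trial_duration {config.trial_duration} s is shorter than 3 steps"
        )
    rng = _trial_stream(config, profile.index, trial_label, seed_offset)
    fs = config.sampling_rate
    n_samples = int(round(config.trial_duration * fs))
    t = np.arange(n_samples) / fs

    # Step schedule: generate a few steps of padding before 0 and beyond the
    # trial end so every sample falls inside a well-defined step for both legs.
    mean_dur = config.mean_step_duration * (1.0 + profile.cadence_offset)
    durations = []
    boundaries = [-2.0 * mean_dur]
    while boundaries[-1] < config.trial_duration + 2.0 * mean_dur:
        d = mean_dur * (1.0 + config.step_duration_jitter * rng.standard_normal())
        d = max(d, 0.4 * mean_dur)
        durations.append(d)
        boundaries.append(boundaries[-1] + d)
    boundaries = np.asarray(boundaries)
    durations = np.asarray(durations)
    n_steps = len(durations)
    # side of the leg touching down at each boundary; alternates, 'L' first
    sides = ["L" if i % 2 == 0 else "R" for i in range(n_steps)]
    bump_gain = 1.0 + config.bump_cycle_jitter * rng.standard_normal(n_steps)

    step_of = np.searchsorted(boundaries, t, side="right") - 1
    u = (t - boundaries[step_of]) / durations[step_of]
    left_standing = np.asarray([s == "L" for s in sides])[step_of]
    side_sign = np.where(left_standing, -1.0, 1.0)  # -1 during left-standing steps
    gain = bump_gain[step_of]

    angles = np.empty((n_samples, N_JOINTS, N_PLANES))
    bumps = profile.signature_bumps
    for j, joint in enumerate(RAW_JOINTS):
        for p in range(N_PLANES):
            if joint in SPINE_JOINTS:
                row = profile.fourier_coefficients[_series_index(joint, p)]
                canon = _eval_series(row, u)
                canon = canon + _bump_values(bumps, j, p, u, gain)
                if PLANES[p] != "flexion":
                    canon = canon * side_sign
                angles[:, j, p] = canon
            else:
                base_name, lr = joint.split("-")
                row = profile.fourier_coefficients[_series_index(base_name, p)]
                standing_here = left_standing if lr == "L" else ~left_standing
                stride_phase = np.where(standing_here, u / 2.0, 0.5 + u / 2.0)
                vals = _eval_series(row, stride_phase)
                # canonical joint index of the role this leg currently plays
                base_i = EXTREMITY_BASES.index(base_name)
                st_joint = len(SPINE_JOINTS) + 2 * base_i
                role_joint = np.where(standing_here, st_joint, st_joint + 1)
                for role in (st_joint, st_joint + 1):
                    m = role_joint == role
                    if m.any():
                        vals[m] += _bump_values(bumps, role, p, u[m], gain[m])
                angles[:, j, p] = vals
    angles += rng.normal(0.0, config.noise_sd, size=angles.shape)

    heights = _height_channels(t, boundaries, durations, sides, config, rng)
    foot_l, foot_r, toe_l, toe_r = heights

    touchdown_idx = []
    touchdown_sides = []
    for i in range(n_steps):
        contact_time = boundaries[i] + min(0.0, config.strike_offset_s)
        idx = int(np.ceil(contact_time * fs - 1e-9))
        if 0 <= idx < n_samples:
            touchdown_idx.append(idx)
            touchdown_sides.append(sides[i])

    return RawTrial(
        participant_id=profile.participant_id,
        trial_label=trial_label,
        time=t,
        joint_angles=angles,
        foot_height_left=foot_l,
        foot_height_right=foot_r,
        toe_height_left=toe_l,
        toe_height_right=toe_r,
        true_touchdowns=np.asarray(touchdown_idx, dtype=int),
        true_touchdown_sides=touchdown_sides,
    )


def _height_channels(t, boundaries, durations, sides, config, rng):
    """Vertical foot/toe positions with stance plateaus and swing arcs."""
    n = t.shape[0]
    out = {}
    for leg in ("L", "R"):
        for marker, peak, offset in (
            ("foot", FOOT_SWING_HEIGHT, 0.0),
            ("toe", TOE_SWING_HEIGHT, config.strike_offset_s),
        ):
            h = np.full(n, PLATEAU_HEIGHT)
            # contact intervals of this leg: start at its touchdowns (+marker
            # offset), end after the stance fraction of the initiating step
            own = [i for i, s in enumerate(sides) if s == leg]
            for pos, i in enumerate(own):
                td = boundaries[i] + offset
                to = boundaries[i] + STANCE_FRACTION * durations[i] + offset
                # swing from this take-off to the next ipsilateral touchdown
                if pos + 1 < len(own):
                    nxt = boundaries[own[pos + 1]] + offset
                    m = (t > to) & (t < nxt)
                    if m.any():
                        w = (t[m] - to) / (nxt - to)
                        h[m] = PLATEAU_HEIGHT + peak * np.sqrt(np.sin(np.pi * w))
            # before the first recorded touchdown / after the last one the
            # plateau default is kept (leg treated as grounded)
            h += rng.normal(0.0, config.height_noise_sd, size=n)
            out[(leg, marker)] = np.clip(h, 0.0, None)
    return out[("L", "foot")], out[("R", "foot")], out[("L", "toe")], out[("R", "toe")]


# ---------------------------------------------------------------------------
# Cohort-level convenience and I/O


def synthesize_cohort(config: CohortConfig) -> tuple[list[ParticipantProfile], dict]:
    """Generate CR, WR and TR trials for every participant.

    Returns the profiles and a mapping ``{participant_id: {label: RawTrial}}``.
    """
    profiles = make_cohort(config)
    trials = {
        prof.participant_id: {
            label: synthesize_trial(prof, config, label, seed_offset=k)
            for k, label in enumerate(TRIAL_LABELS)
        }
        for prof in profiles
    }
    return profiles, trials


def _channel_names() -> list[str]:
    names = [f"{j}_{p}" for j in RAW_JOINTS for p in PLANES]
    names += ["foot_height_L", "foot_height_R", "toe_height_L", "toe_height_R"]
    return names


def write_trial_csv(trial: RawTrial, csv_path, sidecar_path=None,
                    config: CohortConfig | None = None) -> None:
    """Persist a trial as long-format CSV plus a JSON ground-truth sidecar."""
    angle_cols = trial.joint_angles.reshape(trial.n_samples, -1)
    heights = np.column_stack(
        [trial.foot_height_left, trial.foot_height_right,
         trial.toe_height_left, trial.toe_height_right]
    )
    wide = np.column_stack([angle_cols, heights])
    names = _channel_names()
    frame = pd.DataFrame(
        {
            "time_s": np.repeat(trial.time, len(names)),
            "participant": trial.participant_id,
            "trial": trial.trial_label,
            "channel": np.tile(names, trial.n_samples),
            "value": wide.reshape(-1),
        }
    )
    frame.to_csv(csv_path, index=False, float_format="%.8g")
    if sidecar_path is not None:
        sidecar = {
            "participant": trial.participant_id,
            "trial": trial.trial_label,
            "true_touchdowns": trial.true_touchdowns.tolist(),
            "true_touchdown_sides": list(trial.true_touchdown_sides),
        }
        if config is not None:
            cfg = {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in vars(config).items()
            }
            sidecar["config"] = cfg
        with open(sidecar_path, "w") as fh:
            json.dump(sidecar, fh, indent=1, sort_keys=True)


def read_trial_csv(csv_path, sidecar_path=None) -> RawTrial:
    """Reload a long-format trial CSV written by :func:`write_trial_csv`."""
    frame = pd.read_csv(csv_path)
    names = _channel_names()
    pivot = frame.pivot_table(index="time_s", columns="channel", values="value",
                              sort=True)
    pivot = pivot[names]
    values = pivot.to_numpy()
    n = values.shape[0]
    angles = values[:, : N_JOINTS * N_PLANES].reshape(n, N_JOINTS, N_PLANES)
    foot_l, foot_r, toe_l, toe_r = values[:, -4:].T
    touchdowns = np.empty(0, dtype=int)
    td_sides: list[str] = []
    if sidecar_path is not None:
        with open(sidecar_path) as fh:
            sidecar = json.load(fh)
        touchdowns = np.asarray(sidecar["true_touchdowns"], dtype=int)
        td_sides = list(sidecar["true_touchdown_sides"])
    return RawTrial(
        participant_id=str(frame["participant"].iloc[0]),
        trial_label=str(frame["trial"].iloc[0]),
        time=pivot.index.to_numpy(),
        joint_angles=angles,
        foot_height_left=foot_l.copy(),
        foot_height_right=foot_r.copy(),
        toe_height_left=toe_l.copy(),
        toe_height_right=toe_r.copy(),
        true_touchdowns=touchdowns,
        true_touchdown_sides=td_sides,
    )


def reduced_config(config: CohortConfig, **overrides) -> CohortConfig:
    """Copy a config with overrides (convenience for scaled-down runs)."""
    return replace(config, **overrides)
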