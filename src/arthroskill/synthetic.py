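"""Synthetic arthroscopy-trial generator.

Emulates the structure of simulator recordings so the whole pipeline is
exercisable without human-subject data: a tool tip moves through a small
set of task waypoints on minimum-jerk segments (maximally smooth, the
ideal reference), physiological tremor is added as 1–8-Hz band-limited
noise on position and orientation, the tool orientation follows the path
tangent, and instrument trials carry a bending-force channel with a
smooth ~1-N bump at each switch-press (waypoint arrival) plus
non-negative sensor noise.

Expertise presets: the *ideal* reference trial has zero tremor and
nominal pace and force; *experts* add small tremor, a mild slowdown and
slight force overshoot; the *novice* preset is the expert preset with
the excess (tremor amplitude, slowdown, force overshoot and noise)
scaled by ``effect_size``, so ``effect_size = 1`` makes the two groups
statistically identical — the null case for calibration tests — while
larger values reproduce the larger fluctuation, longer duration and
larger forces expected of novices.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import signal
from scipy.spatial.transform import Rotation

from .data_model import (
    CohortManifest,
    Expertise,
    ManifestEntry,
    ToolRole,
    TrialRecording,
    write_manifest,
    write_trial,
)
from .preprocessing import lowpass

__all__ = [
    "MotionProfile",
    "profile_for",
    "generate_trial",
    "simulate_cohort",
    "generate_cohort",
    "TASK_WAYPOINTS",
]

SAMPLING_HZ = 20.0
TREMOR_BAND_HZ = (1.0, 8.0)  # physiological tremor band, survives the filter clamp

#: instrument waypoints per task (metres, lab frame, +z up): portal entry,
#: task targets (two switches for the probing tasks; grasp point held, then
#: extraction for the grasping task), return to portal.
TASK_WAYPOINTS: dict[int, list[tuple[float, float, float]]] = {
    1: [(0.0, 0.0, 0.0), (0.03, 0.02, 0.05), (0.035, -0.01, 0.0), (0.0, 0.0, 0.0)],
    2: [(0.0, 0.0, 0.0), (0.05, 0.04, 0.06), (0.06, -0.03, 0.04), (0.0, 0.0, 0.0)],
    3: [
        (0.0, 0.0, 0.0),
        (0.04, 0.02, 0.02),
        (0.04, 0.02, 0.02),
        (0.0, 0.01, -0.02),
        (0.0, 0.0, 0.0),
    ],
}
#: the arthroscope plays a secondary role: same waypoint geometry at
#: reduced amplitude (small repositioning around the viewing pose)
ARTHROSCOPE_SCALE = 0.4

# expert preset (novice = expert with the excess scaled by effect_size);
# tremor amplitudes are at the sub-millimetre scale of a braced tool tip so
# that expert normalized metrics land near 1 and novices several-fold higher
EXPERT_JITTER_POS = 2.0e-4  # m RMS positional tremor
EXPERT_JITTER_ANG = 5.0e-3  # rad RMS orientation tremor
EXPERT_DURATION_FACTOR = 1.2
EXPERT_FORCE_PEAK = 1.1  # N (slight overshoot of the 1-N switch force)
EXPERT_FORCE_NOISE = 0.02  # N RMS
IDEAL_FORCE_PEAK = 1.0  # N, clean switch actuation
BASE_DURATION_S = 10.0  # ideal-pace task completion time
#: subject-to-subject spread of tremor amplitude: multiplier 1 + N(0, sigma),
#: floored at 0.2.  Symmetric about the preset so that at effect_size = 1 the
#: two groups are exchangeable with near-symmetric metric distributions and
#: the normality-routed group test stays calibrated (the generator's
#: null-calibration contract).
SUBJECT_SIGMA = 0.3
SUBJECT_MULT_FLOOR = 0.2


@dataclass(frozen=True)
class MotionProfile:
    """Parametrization of one synthetic trial."""

    waypoints: Sequence[tuple[float, float, float]]
    base_duration: float = BASE_DURATION_S  # s, at duration_factor 1
    duration_factor: float = 1.0  # >= 1, slowdown
    jitter_pos: float = 0.0  # m RMS band-limited positional tremor
    jitter_ang: float = 0.0  # rad RMS orientation tremor
    force_peak: float = IDEAL_FORCE_PEAK  # N at each switch press
    force_noise: float = 0.0  # N RMS
    fs: float = SAMPLING_HZ
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.waypoints) < 2:
            raise ValueError("need at least 2 waypoints")
        if self.duration_factor < 1:
            raise ValueError("duration_factor must be >= 1")
        if min(self.jitter_pos, self.jitter_ang, self.force_noise) < 0:
            raise ValueError("jitter/noise amplitudes must be >= 0")
        if self.fs <= 0 or self.base_duration <= 0:
            raise ValueError("fs and base_duration must be positive")


def profile_for(
    expertise: Expertise | str,
    task_id: int,
    tool_role: ToolRole | str = ToolRole.INSTRUMENT,
    effect_size: float = 4.0,
    seed: int = 0,
    base_duration: float = BASE_DURATION_S,
) -> MotionProfile:
    """Preset profile for an expertise level on a task.

    ``effect_size`` is the novice-to-expert tremor ratio; it also scales
    the novice's slowdown and force excess so that ``effect_size = 1``
    collapses the novice preset onto the expert one.
    """
    expertise = Expertise(expertise)
    tool_role = ToolRole(tool_role)
    if effect_size < 1:
        raise ValueError("effect_size must be >= 1")
    wps = np.asarray(TASK_WAYPOINTS[task_id], dtype=float)
    if tool_role == ToolRole.ARTHROSCOPE:
        wps = wps * ARTHROSCOPE_SCALE
    waypoints = [tuple(p) for p in wps]
    if expertise == Expertise.IDEAL:
        return MotionProfile(
            waypoints=waypoints,
            base_duration=base_duration,
            duration_factor=1.0,
            jitter_pos=0.0,
            jitter_ang=0.0,
            force_peak=IDEAL_FORCE_PEAK,
            force_noise=0.0,
            seed=seed,
        )
    if expertise == Expertise.EXPERT:
        scale = 1.0
    else:  # novice
        scale = effect_size
    return MotionProfile(
        waypoints=waypoints,
        base_duration=base_duration,
        duration_factor=EXPERT_DURATION_FACTOR * (1.0 + 0.15 * (scale - 1.0)),
        jitter_pos=EXPERT_JITTER_POS * scale,
        jitter_ang=EXPERT_JITTER_ANG * scale,
        force_peak=EXPERT_FORCE_PEAK * (1.0 + 0.1 * (scale - 1.0)),
        force_noise=EXPERT_FORCE_NOISE * scale,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# trajectory construction
# ---------------------------------------------------------------------------

def _minimum_jerk_path(
    waypoints: np.ndarray, time: np.ndarray, duration: float
) -> np.ndarray:
    """Piecewise minimum-jerk interpolation: rest-to-rest straight segments."""
    n_seg = waypoints.shape[0] - 1
    seg_t = duration / n_seg
    idx = np.minimum((time // seg_t).astype(int), n_seg - 1)
    tau = np.clip((time - idx * seg_t) / seg_t, 0.0, 1.0)
    s = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
    return waypoints[idx] + s[:, None] * (waypoints[idx + 1] - waypoints[idx])


def _bandlimited_noise(
    rng: np.random.Generator, n: int, fs: float, rms: float, channels: int = 1
) -> np.ndarray:
    """Zero-mean noise filtered to the tremor band, scaled to a target RMS.

    The white-noise draw happens regardless of ``rms`` so that paired
    profiles differing only in amplitude share the same realization.
    """
    white = rng.standard_normal((channels, n))
    lo, hi = TREMOR_BAND_HZ
    nyq = fs / 2.0
    hi = min(hi, 0.95 * nyq)
    b, a = signal.butter(2, [lo / nyq, hi / nyq], btype="bandpass")
    shaped = signal.filtfilt(b, a, white, axis=-1, padlen=min(n - 1, 12))
    std = shaped.std(axis=-1, keepdims=True)
    std[std == 0] = 1.0
    out = shaped / std * rms
    return out.T  # (n, channels)


def _heading_from_tangent(pos: np.ndarray, time: np.ndarray, fs: float) -> np.ndarray:
    """Smooth yaw/pitch angles following the path tangent (roll fixed at 0)."""
    tangent = np.gradient(pos, time, axis=0)
    speed = np.linalg.norm(tangent, axis=1)
    moving = speed > 1e-9
    n = pos.shape[0]
    yaw = np.zeros(n)
    pitch = np.zeros(n)
    if moving.any():
        yaw_m = np.arctan2(tangent[moving, 1], tangent[moving, 0])
        pitch_m = np.arctan2(
            -tangent[moving, 2], np.hypot(tangent[moving, 0], tangent[moving, 1])
        )
        idx = np.flatnonzero(moving)
        yaw[idx] = np.unwrap(yaw_m)
        pitch[idx] = pitch_m
        # hold heading through dwells / endpoints
        filled = np.interp(np.arange(n), idx, yaw[idx])
        yaw = filled
        pitch = np.interp(np.arange(n), idx, pitch[idx])
    if n >= 12:  # smooth heading changeovers so per-step rotations stay small
        yaw = lowpass(yaw, 2.0, fs)
        pitch = lowpass(pitch, 2.0, fs)
    return np.column_stack([yaw, pitch])


def generate_trial(
    profile: MotionProfile,
    expertise: Expertise | str,
    tool_role: ToolRole | str,
    subject_id: str = "synthetic",
    task_id: int = 1,
) -> TrialRecording:
    """Generate one reproducible synthetic trial from a motion profile.

    The ideal level forces zero tremor/noise and nominal pace regardless
    of the profile's amplitudes.  Instrument trials carry a force
    channel; arthroscope trials do not.
    """
    expertise = Expertise(expertise)
    tool_role = ToolRole(tool_role)
    if expertise == Expertise.IDEAL:
        profile = replace(
            profile,
            duration_factor=1.0,
            jitter_pos=0.0,
            jitter_ang=0.0,
            force_peak=min(profile.force_peak, IDEAL_FORCE_PEAK),
            force_noise=0.0,
        )
    rng = np.random.default_rng(profile.seed)
    duration = profile.base_duration * profile.duration_factor
    n = int(round(duration * profile.fs)) + 1
    time = np.arange(n) / profile.fs
    waypoints = np.asarray(profile.waypoints, dtype=float)

    pos = _minimum_jerk_path(waypoints, time, duration)
    pos = pos + _bandlimited_noise(rng, n, profile.fs, profile.jitter_pos, channels=3)

    heading = _heading_from_tangent(pos, time, profile.fs)
    base_rot = Rotation.from_euler(
        "zyx", np.column_stack([heading, np.zeros(n)])
    )
    tremor_vec = _bandlimited_noise(rng, n, profile.fs, profile.jitter_ang, channels=3)
    rot = base_rot * Rotation.from_rotvec(tremor_vec)
    quat = rot.as_quat(scalar_first=True)
    # hemisphere continuity (cosmetic; antipodal pairs are equivalent)
    flips = np.cumprod(np.sign(np.einsum("ij,ij->i", quat[:-1], quat[1:])))
    quat[1:] *= np.where(flips == 0, 1.0, flips)[:, None]

    force = None
    if tool_role == ToolRole.INSTRUMENT:
        n_seg = waypoints.shape[0] - 1
        arrivals = duration * (np.arange(1, n_seg + 1)) / n_seg
        bump_sigma = 0.4  # s, press dwell overlaps the approach/retract motion
        force = np.zeros(n)
        for ta in arrivals[:-1] if n_seg > 1 else arrivals:
            force += profile.force_peak * np.exp(-0.5 * ((time - ta) / bump_sigma) ** 2)
        noise = _bandlimited_noise(rng, n, profile.fs, profile.force_noise)[:, 0]
        force = np.clip(force + np.abs(noise), 0.0, None)

    return TrialRecording(
        subject_id=subject_id,
        expertise=expertise,
        task_id=task_id,
        tool_role=tool_role,
        time=time,
        position=pos,
        orientation=quat,
        force=force,
    )


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def simulate_cohort(
    n_novice: int,
    n_expert: int,
    task_id: int = 1,
    tool_roles: Sequence[ToolRole | str] = (ToolRole.INSTRUMENT, ToolRole.ARTHROSCOPE),
    effect_size: float = 4.0,
    seed: int = 0,
) -> list[TrialRecording]:
    """Generate an in-memory cohort: one ideal trial per (task, tool) plus one
    trial per subject per tool role.

    Subjects vary around their expertise preset (symmetric tremor-amplitude
    multiplier ``1 + N(0, SUBJECT_SIGMA)``, floored at
    :data:`SUBJECT_MULT_FLOOR`), so within-group variance is nonzero.
    Fully reproducible from ``seed``.
    """
    if n_novice < 1 or n_expert < 1:
        raise ValueError("need at least one subject per group")
    roles = [ToolRole(r) for r in tool_roles]
    rng = np.random.default_rng(seed)
    trials: list[TrialRecording] = []
    for role in roles:
        prof = profile_for(
            Expertise.IDEAL, task_id, role, seed=int(rng.integers(2**31))
        )
        trials.append(
            generate_trial(prof, Expertise.IDEAL, role, subject_id="ideal", task_id=task_id)
        )
    subjects = [(f"nov{i + 1:02d}", Expertise.NOVICE) for i in range(n_novice)]
    subjects += [(f"exp{i + 1:02d}", Expertise.EXPERT) for i in range(n_expert)]
    for subject_id, level in subjects:
        mult = max(SUBJECT_MULT_FLOOR, 1.0 + float(rng.normal(0.0, SUBJECT_SIGMA)))
        for role in roles:
            prof = profile_for(
                level, task_id, role, effect_size=effect_size,
                seed=int(rng.integers(2**31)),
            )
            prof = replace(
                prof,
                jitter_pos=prof.jitter_pos * mult,
                jitter_ang=prof.jitter_ang * mult,
                force_noise=prof.force_noise * mult,
            )
            trials.append(
                generate_trial(prof, level, role, subject_id=subject_id, task_id=task_id)
            )
    return trials


def generate_cohort(
    n_novice: int,
    n_expert: int,
    out_dir,
    task_id: int = 1,
    tool_roles: Sequence[ToolRole | str] = (ToolRole.INSTRUMENT, ToolRole.ARTHROSCOPE),
    effect_size: float = 4.0,
    seed: int = 0,
) -> CohortManifest:
    """Generate a cohort, write trial CSVs plus a YAML manifest, return the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    trials = simulate_cohort(
        n_novice, n_expert, task_id=task_id, tool_roles=tool_roles,
        effect_size=effect_size, seed=seed,
    )
    entries = []
    for trial in trials:
        fname = (
            f"{trial.subject_id}_task{trial.task_id}_{trial.tool_role.value}.csv"
        )
        write_trial(trial, out_dir / fname)
        entries.append(
            ManifestEntry(
                subject_id=trial.subject_id,
                expertise=trial.expertise,
                task_id=trial.task_id,
                tool_role=trial.tool_role,
                path=fname,
                valid=True,
            )
        )
    manifest = CohortManifest(entries=entries, units="m", gravity_axis="z", root=out_dir)
    manifest.validate()
    write_manifest(manifest, out_dir / "manifest.yaml")
    return manifest
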