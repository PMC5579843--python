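"""Domain types and on-disk formats for tracked surgical-tool trials.

A *trial* is one uniformly sampled recording of a tool's tip pose — 3-D
position plus a unit quaternion orientation — and, for sensorized
instruments, the scalar bending-force magnitude at the tip.  Trials are
stored as plain CSV (columns ``t,x,y,z,qw,qx,qy,qz[,f]``); a cohort is
described by a YAML manifest assigning each trial file a subject,
expertise level, task and tool role, together with a single
ideal-performance reference trial per (task, tool) used for metric
normalization.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

__all__ = [
    "Expertise",
    "ToolRole",
    "TrialRecording",
    "ManifestEntry",
    "CohortManifest",
    "TrialFormatError",
    "TrialValidityError",
    "read_trial",
    "write_trial",
    "read_manifest",
    "write_manifest",
]

#: relative tolerance on sampling-interval uniformity
DT_RTOL = 1e-6
#: quaternion norms further than this from 1 are rejected on read
QUAT_NORM_TOL = 1e-3

TRIAL_COLUMNS = ("t", "x", "y", "z", "qw", "qx", "qy", "qz")
FORCE_COLUMN = "f"


class TrialFormatError(ValueError):
    """A trial file does not have the expected columns/layout."""


class TrialValidityError(ValueError):
    """A trial violates a physical-validity invariant (timing, quaternions, force)."""


class Expertise(str, enum.Enum):
    NOVICE = "novice"
    EXPERT = "expert"
    IDEAL = "ideal"


class ToolRole(str, enum.Enum):
    INSTRUMENT = "instrument"
    ARTHROSCOPE = "arthroscope"


@dataclass(frozen=True)
class TrialRecording:
    """One tool's pose/force trace for one subject performing one task.

    Attributes
    ----------
    subject_id : str
        Opaque subject identifier.
    expertise : Expertise
        Group label; ``ideal`` marks the single reference trial.
    task_id : int
        Task number, 1–3.
    tool_role : ToolRole
        ``instrument`` (force-sensorized) or ``arthroscope`` (pose only).
    time : (n,) float array, seconds
        Strictly increasing, uniform step.
    position : (n, 3) float array, metres
        Tip position in the lab frame; +z opposes gravity by convention.
    orientation : (n, 4) float array
        Unit quaternions, scalar-first ``(w, x, y, z)``.
    force : (n,) float array or None, newtons
        Bending-force magnitude; ``None`` for the arthroscope.
    """

    subject_id: str
    expertise: Expertise
    task_id: int
    tool_role: ToolRole
    time: np.ndarray
    position: np.ndarray
    orientation: np.ndarray
    force: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "time", np.asarray(self.time, dtype=float))
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        object.__setattr__(self, "orientation", np.asarray(self.orientation, dtype=float))
        if self.force is not None:
            object.__setattr__(self, "force", np.asarray(self.force, dtype=float))
        self.validate()

    # -- derived quantities -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.time.shape[0]

    @property
    def dt(self) -> float:
        """Uniform sampling interval in seconds."""
        return float(self.time[1] - self.time[0])

    @property
    def fs(self) -> float:
        """Sampling frequency in Hz."""
        return 1.0 / self.dt

    @property
    def duration(self) -> float:
        """Task completion time T = t[n-1] - t[0]; invariant to time-origin shifts."""
        return float(self.time[-1] - self.time[0])

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        n = self.time.shape[0]
        if self.time.ndim != 1 or n < 2:
            raise TrialValidityError("trial needs at least 2 samples of 1-D time")
        if not np.all(np.isfinite(self.time)):
            raise TrialValidityError("non-finite timestamps")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            bad = int(np.flatnonzero(dt <= 0)[0]) + 1
            raise TrialValidityError(
                f"time not strictly increasing at sample index {bad}"
            )
        dev = np.abs(dt - dt[0])
        if np.any(dev > DT_RTOL * dt[0]):
            bad = int(np.flatnonzero(dev > DT_RTOL * dt[0])[0]) + 1
            raise TrialValidityError(
                f"non-uniform sampling interval at sample index {bad}"
            )
        if self.position.shape != (n, 3):
            raise TrialValidityError(
                f"position shape {self.position.shape} != ({n}, 3)"
            )
        if self.orientation.shape != (n, 4):
            raise TrialValidityError(
                f"orientation shape {self.orientation.shape} != ({n}, 4)"
            )
        if not (np.all(np.isfinite(self.position)) and np.all(np.isfinite(self.orientation))):
            raise TrialValidityError("non-finite pose samples")
        norms = np.linalg.norm(self.orientation, axis=1)
        off = np.abs(norms - 1.0)
        if np.any(off > QUAT_NORM_TOL):
            bad = int(np.argmax(off))
            raise TrialValidityError(
                f"quaternion norm {norms[bad]:.6f} at sample {bad} off unit by > {QUAT_NORM_TOL}"
            )
        if self.task_id not in (1, 2, 3):
            raise TrialValidityError(f"task_id must be 1, 2 or 3, got {self.task_id!r}")
        if self.force is not None:
            if self.tool_role == ToolRole.ARTHROSCOPE:
                raise TrialValidityError("arthroscope trials carry no force channel")
            if self.force.shape != (n,):
                raise TrialValidityError("force length does not match time")
            if not np.all(np.isfinite(self.force)):
                raise TrialValidityError("non-finite force samples")
            if np.any(self.force < 0):
                raise TrialValidityError("negative bending-force magnitude")

    def with_unit_quaternions(self) -> "TrialRecording":
        """Return a copy with quaternions renormalized exactly to unit length."""
        norms = np.linalg.norm(self.orientation, axis=1, keepdims=True)
        return replace(self, orientation=self.orientation / norms)


@dataclass
class ManifestEntry:
    subject_id: str
    expertise: Expertise
    task_id: int
    tool_role: ToolRole
    path: str
    valid: bool = True


@dataclass
class CohortManifest:
    """Cohort description: trial entries plus per-(task, tool) ideal references.

    ``units`` declares the length unit of the trial files ('m' or 'mm');
    positions are converted to metres on read.  ``gravity_axis`` names the
    position component treated as height for the potential-energy metric.
    """

    entries: list[ManifestEntry] = field(default_factory=list)
    units: str = "m"
    gravity_axis: str = "z"
    root: Optional[Path] = None  # directory trial paths are relative to

    def __post_init__(self) -> None:
        if self.units not in ("m", "mm"):
            raise ValueError(f"units must be 'm' or 'mm', got {self.units!r}")
        if self.gravity_axis not in ("x", "y", "z"):
            raise ValueError(f"gravity_axis must be one of x, y, z")

    def validate(self) -> None:
        seen_ideal: dict[tuple[int, ToolRole], str] = {}
        seen_subject: set[tuple[str, int, ToolRole]] = set()
        for e in self.entries:
            key = (e.task_id, e.tool_role)
            if e.expertise == Expertise.IDEAL:
                if key in seen_ideal:
                    raise ValueError(
                        f"duplicate ideal reference for task {e.task_id}, {e.tool_role.value}"
                    )
                seen_ideal[key] = e.subject_id
            else:
                skey = (e.subject_id, e.task_id, e.tool_role)
                if skey in seen_subject:
                    raise ValueError(
                        f"duplicate subject {e.subject_id!r} for task {e.task_id}, "
                        f"{e.tool_role.value}"
                    )
                seen_subject.add(skey)
        for e in self.entries:
            key = (e.task_id, e.tool_role)
            if e.expertise != Expertise.IDEAL and key not in seen_ideal:
                raise ValueError(
                    f"no ideal reference for task {e.task_id}, {e.tool_role.value}"
                )

    def ideal_entry(self, task_id: int, tool_role: ToolRole) -> ManifestEntry:
        for e in self.entries:
            if (
                e.expertise == Expertise.IDEAL
                and e.task_id == task_id
                and e.tool_role == tool_role
            ):
                return e
        raise KeyError(f"no ideal reference for task {task_id}, {tool_role.value}")

    def resolve(self, entry: ManifestEntry) -> Path:
        p = Path(entry.path)
        if not p.is_absolute() and self.root is not None:
            p = self.root / p
        return p

    def load_trial(self, entry: ManifestEntry) -> TrialRecording:
        return read_trial(
            self.resolve(entry),
            subject_id=entry.subject_id,
            expertise=entry.expertise,
            task_id=entry.task_id,
            tool_role=entry.tool_role,
            units=self.units,
        )


# ---------------------------------------------------------------------------
# Trial CSV I/O
# ---------------------------------------------------------------------------

def read_trial(
    path,
    subject_id: str = "unknown",
    expertise: Expertise | str = Expertise.NOVICE,
    task_id: int = 1,
    tool_role: ToolRole | str = ToolRole.INSTRUMENT,
    units: str = "m",
) -> TrialRecording:
    """Read a trial CSV (``t,x,y,z,qw,qx,qy,qz[,f]``) into a :class:`TrialRecording`.

    Positions recorded in millimetres (``units='mm'``) are converted to
    metres.  Quaternions within 1e-3 of unit norm are renormalized; worse
    deviations raise :class:`TrialValidityError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trial file not found: {path}")
    with open(path, "r") as fh:
        header = fh.readline().strip().split(",")
        data = np.loadtxt(fh, delimiter=",", ndmin=2)
    missing = [c for c in TRIAL_COLUMNS if c not in header]
    if missing:
        raise TrialFormatError(f"{path}: missing column(s) {', '.join(missing)}")
    if data.shape[1] != len(header):
        raise TrialFormatError(f"{path}: row width does not match header")
    col = {name: data[:, i] for i, name in enumerate(header)}
    scale = 1e-3 if units == "mm" else 1.0
    position = np.column_stack([col["x"], col["y"], col["z"]]) * scale
    orientation = np.column_stack([col["qw"], col["qx"], col["qy"], col["qz"]])
    force = col.get(FORCE_COLUMN)
    trial = TrialRecording(
        subject_id=subject_id,
        expertise=Expertise(expertise),
        task_id=task_id,
        tool_role=ToolRole(tool_role),
        time=col["t"],
        position=position,
        orientation=orientation,
        force=force,
    )
    return trial.with_unit_quaternions()


def write_trial(trial: TrialRecording, path) -> None:
    """Write a trial as CSV with fixed header order and full float precision.

    Identical trials produce byte-identical files; the force column is
    omitted for force-less (arthroscope) trials.
    """
    path = Path(path)
    cols = [trial.time, *trial.position.T, *trial.orientation.T]
    header = list(TRIAL_COLUMNS)
    if trial.force is not None:
        cols.append(trial.force)
        header.append(FORCE_COLUMN)
    buf = io.StringIO()
    buf.write(",".join(header) + "\n")
    np.savetxt(buf, np.column_stack(cols), fmt="%.17g", delimiter=",")
    path.write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# Manifest I/O (YAML)
# ---------------------------------------------------------------------------

def read_manifest(path) -> CohortManifest:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    doc = yaml.safe_load(path.read_text())
    entries = [
        ManifestEntry(
            subject_id=str(e["subject"]),
            expertise=Expertise(e["level"]),
            task_id=int(e["task"]),
            tool_role=ToolRole(e["tool"]),
            path=str(e["path"]),
            valid=bool(e.get("valid", True)),
        )
        for e in doc.get("trials", [])
    ]
    manifest = CohortManifest(
        entries=entries,
        units=doc.get("units", "m"),
        gravity_axis=doc.get("gravity_axis", "z"),
        root=path.parent,
    )
    manifest.validate()
    return manifest


def write_manifest(manifest: CohortManifest, path) -> None:
    path = Path(path)
    doc = {
        "units": manifest.units,
        "gravity_axis": manifest.gravity_axis,
        "trials": [
            {
                "subject": e.subject_id,
                "level": e.expertise.value,
                "task": e.task_id,
                "tool": e.tool_role.value,
                "path": e.path,
                "valid": e.valid,
            }
            for e in manifest.entries
        ],
    }
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
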