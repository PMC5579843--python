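"""Energy-expenditure metrics and their ideal-trial normalization.

Four per-trial scalars summarize how much mechanical energy a trainee
spends while manipulating a tracked tool:

* **EP** — potential: total variation of the tip height signal,
  ``sum_k |h_{k+1} - h_k|`` (mass and g dropped as common scale factors;
  units: metres).
* **ETK** — translational kinetic: total variation of the squared tip
  speed, ``sum_k |v_{k+1}^2 - v_k^2|`` (m/2 dropped; units: (m/s)^2).
* **ERK** — rotational kinetic: total variation of the squared angular
  speed ``s = wx^2 + wy^2 + wz^2`` (I/2 dropped; units: (rad/s)^2).  The
  change integral is taken in absolute value — without it the integral of
  ds/dt telescopes to s(T) - s(0) ~ 0 for any trial that starts and ends
  at rest, which would make the metric vacuous.
* **W** — work: midpoint bending-force magnitude times unsigned tip path
  increment, summed (units: N·m).  Absent for the arthroscope, which is
  not force-sensorized.

Because every subject uses the same instruments, instrument mass, moment
of inertia and g are common factors; dropping them leaves the reduced
units above and cancels entirely once each metric is divided by the
corresponding value of a single ideal-performance reference trial.  A
normalized value of 1 means ideal-equivalent expenditure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .data_model import TrialRecording
from .preprocessing import DEFAULT_CUTOFF_HZ, derive_kinematics, lowpass

__all__ = [
    "EnergyMetrics",
    "NormalizedMetrics",
    "potential_metric",
    "translational_kinetic_metric",
    "rotational_kinetic_metric",
    "work_metric",
    "compute_metrics",
    "normalize",
]


@dataclass(frozen=True)
class EnergyMetrics:
    """Raw (un-normalized) energy metrics for one trial."""

    ep: float  # metres
    etk: float  # (m/s)^2
    erk: float  # (rad/s)^2
    w: Optional[float]  # N*m, None when the trial has no force channel
    duration: float  # seconds, task completion time T

    def __post_init__(self) -> None:
        vals = [self.ep, self.etk, self.erk, self.duration]
        if self.w is not None:
            vals.append(self.w)
        if any(v < 0 for v in vals):
            raise ValueError("energy metrics must be non-negative")


@dataclass(frozen=True)
class NormalizedMetrics:
    """Ideal-relative metric ratios; 1 means identical-to-ideal expenditure."""

    ep_n: float
    etk_n: float
    erk_n: float
    w_n: Optional[float]

    def __post_init__(self) -> None:
        vals = [self.ep_n, self.etk_n, self.erk_n]
        if self.w_n is not None:
            vals.append(self.w_n)
        if any(v < 0 for v in vals):
            raise ValueError("normalized metrics must be non-negative")


def _total_variation(series: np.ndarray) -> float:
    return float(np.sum(np.abs(np.diff(series))))


def potential_metric(height: np.ndarray) -> float:
    """Sum of absolute height changes (metres): total variation of height."""
    height = np.asarray(height, dtype=float)
    if height.shape[0] < 2:
        raise ValueError("need at least 2 height samples")
    if not np.all(np.isfinite(height)):
        raise ValueError("non-finite height samples")
    return _total_variation(height)


def translational_kinetic_metric(speed_sq: np.ndarray) -> float:
    """Sum of absolute changes of squared speed ((m/s)^2)."""
    speed_sq = np.asarray(speed_sq, dtype=float)
    if speed_sq.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if np.any(speed_sq < 0) or not np.all(np.isfinite(speed_sq)):
        raise ValueError("squared speed must be finite and non-negative")
    return _total_variation(speed_sq)


def rotational_kinetic_metric(omega: np.ndarray, time: np.ndarray) -> float:
    """Sum of absolute changes of squared angular speed ((rad/s)^2).

    Discrete form of the change integral of ``s = wx^2 + wy^2 + wz^2``
    with the integrand in absolute value.
    """
    omega = np.asarray(omega, dtype=float)
    time = np.asarray(time, dtype=float)
    if omega.ndim != 2 or omega.shape[1] != 3:
        raise ValueError("omega must be (n, 3)")
    if omega.shape[0] != time.shape[0]:
        raise ValueError("omega and time lengths differ")
    s = np.einsum("ij,ij->i", omega, omega)
    return _total_variation(s)


def work_metric(force: np.ndarray, path_increment: np.ndarray) -> float:
    """Scalar work (N*m): midpoint force magnitude times unsigned path step."""
    force = np.asarray(force, dtype=float)
    path_increment = np.asarray(path_increment, dtype=float)
    if force.shape[0] != path_increment.shape[0] + 1:
        raise ValueError("path_increment must have one fewer sample than force")
    if np.any(force < 0) or not np.all(np.isfinite(force)):
        raise ValueError("force must be finite and non-negative")
    midpoint = 0.5 * (force[:-1] + force[1:])
    return float(np.sum(midpoint * path_increment))


def compute_metrics(
    trial: TrialRecording,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    gravity_axis: str = "z",
) -> EnergyMetrics:
    """Full metric pipeline for one trial: filter, differentiate, total-variation sums.

    The force channel is low-passed with the same cutoff as position;
    negative filter undershoot (the raw channel is a non-negative
    magnitude) is clipped to zero.
    """
    kin = derive_kinematics(trial, cutoff_hz=cutoff_hz, gravity_axis=gravity_axis)
    ep = potential_metric(kin.height)
    etk = translational_kinetic_metric(kin.speed_sq)
    erk = rotational_kinetic_metric(kin.omega, kin.time)
    w: Optional[float] = None
    if trial.force is not None:
        filtered = np.clip(lowpass(trial.force, cutoff_hz, trial.fs), 0.0, None)
        w = work_metric(filtered, kin.path_increment)
    return EnergyMetrics(ep=ep, etk=etk, erk=erk, w=w, duration=trial.duration)


def normalize(metrics: EnergyMetrics, ideal: EnergyMetrics) -> NormalizedMetrics:
    """Divide each metric by its ideal-trial value.

    A component present in only one operand is absent from the result; an
    ideal component of zero cannot normalize and raises ``ValueError``
    naming the component.
    """

    def ratio(value: Optional[float], ref: Optional[float], name: str) -> Optional[float]:
        if value is None or ref is None:
            return None
        if ref == 0:
            raise ValueError(
                f"ideal {name} is zero: an ideal trial with no {name} expenditure "
                "cannot normalize"
            )
        return value / ref

    return NormalizedMetrics(
        ep_n=ratio(metrics.ep, ideal.ep, "ep"),
        etk_n=ratio(metrics.etk, ideal.etk, "etk"),
        erk_n=ratio(metrics.erk, ideal.erk, "erk"),
        w_n=ratio(metrics.w, ideal.w, "w"),
    )
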