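"""Filtering and differentiation of pose signals.

Raw 20-Hz pose traces are zero-phase low-pass filtered (4th-order
Butterworth, forward-backward) and differentiated into the velocity
quantities the energy metrics consume: squared tip speed, body-frame
angular velocity from quaternion increments, the height coordinate along
the gravity axis, and per-step path increments.

A configured cutoff at or above the Nyquist frequency is clamped to
0.99 * fs/2 with a logged warning rather than rejected, so a nominal
12-Hz cutoff remains well-defined at 20-Hz sampling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.spatial.transform import Rotation

from .data_model import TrialRecording

__all__ = [
    "KinematicDerivatives",
    "lowpass",
    "linear_velocity",
    "angular_velocity",
    "derive_kinematics",
    "DEFAULT_CUTOFF_HZ",
]

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF_HZ = 12.0
FILTER_ORDER = 4
#: minimum series length accepted by :func:`lowpass` (filter warm-up)
MIN_FILTER_SAMPLES = 12

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


@dataclass(frozen=True)
class KinematicDerivatives:
    """Velocity-level quantities derived from one trial.

    speed_sq : (n,) (m/s)^2 — squared magnitude of translational tip velocity
    omega : (n, 3) rad/s — body-frame angular velocity (wx, wy, wz)
    height : (n,) m — signed coordinate along the gravity axis
    path_increment : (n-1,) m — Euclidean tip displacement per step
    time : (n,) s
    """

    speed_sq: np.ndarray
    omega: np.ndarray
    height: np.ndarray
    path_increment: np.ndarray
    time: np.ndarray

    def __post_init__(self) -> None:
        n = self.time.shape[0]
        if self.speed_sq.shape != (n,) or self.omega.shape != (n, 3):
            raise ValueError("derivative lengths inconsistent with time base")
        if self.height.shape != (n,) or self.path_increment.shape != (n - 1,):
            raise ValueError("derivative lengths inconsistent with time base")
        if np.any(self.speed_sq < 0):
            raise ValueError("squared speed must be non-negative")


def lowpass(series: np.ndarray, cutoff_hz: float, fs: float) -> np.ndarray:
    """Zero-phase Butterworth low-pass filter (order 4, forward-backward).

    DC gain is 1; cutoffs at or above 0.99 * Nyquist are clamped there and
    a warning is logged.  Series shorter than the filter warm-up
    (:data:`MIN_FILTER_SAMPLES`) are rejected.
    """
    series = np.asarray(series, dtype=float)
    if fs <= 0 or cutoff_hz <= 0:
        raise ValueError("fs and cutoff_hz must be positive")
    if series.shape[-1] < MIN_FILTER_SAMPLES:
        raise ValueError(
            f"series length {series.shape[-1]} below filter warm-up "
            f"({MIN_FILTER_SAMPLES} samples)"
        )
    if not np.all(np.isfinite(series)):
        raise ValueError("non-finite samples in series")
    nyq = fs / 2.0
    if cutoff_hz >= 0.99 * nyq:
        logger.warning(
            "cutoff %.3g Hz at or above Nyquist %.3g Hz; clamped to %.3g Hz",
            cutoff_hz,
            nyq,
            0.99 * nyq,
        )
        cutoff_hz = 0.99 * nyq
    b, a = signal.butter(FILTER_ORDER, cutoff_hz / nyq)
    padlen = min(3 * (max(len(a), len(b)) - 1), series.shape[-1] - 1)
    return signal.filtfilt(b, a, series, axis=-1, padlen=padlen)


def linear_velocity(position: np.ndarray, time: np.ndarray) -> np.ndarray:
    """Tip velocity (m/s) by central differences, one-sided at the endpoints.

    Exact for affine trajectories; interior samples of a quadratic are also
    exact (central difference of a parabola).
    """
    position = np.asarray(position, dtype=float)
    time = np.asarray(time, dtype=float)
    if time.shape[0] < 3:
        raise ValueError("need at least 3 samples to differentiate")
    return np.gradient(position, time, axis=0)


def angular_velocity(orientation: np.ndarray, time: np.ndarray) -> np.ndarray:
    """Body-frame angular velocity (rad/s) from quaternion increments.

    Per step, ``omega_k = 2 * vec(log(q_k^-1 q_{k+1})) / dt`` (rotation
    vector of the relative rotation divided by the step); the final sample
    replicates the last step so the output length matches the input.
    Antipodal quaternions (q and -q) describe the same attitude and give
    identical rates.  A single step subtending a rotation of pi or more is
    aliased and rejected.
    """
    q = np.asarray(orientation, dtype=float)
    time = np.asarray(time, dtype=float)
    n = q.shape[0]
    if n < 2:
        raise ValueError("need at least 2 orientation samples")
    dt = np.diff(time)
    rot = Rotation.from_quat(q, scalar_first=True)
    rel = rot[:-1].inv() * rot[1:]
    rotvec = rel.as_rotvec()
    angles = np.linalg.norm(rotvec, axis=1)
    if np.any(angles >= np.pi - 1e-12):
        bad = int(np.argmax(angles >= np.pi - 1e-12))
        raise ValueError(
            f"rotation of {angles[bad]:.3f} rad in one step at index {bad}: "
            "aliased (>= pi per sample)"
        )
    omega = rotvec / dt[:, None]
    return np.vstack([omega, omega[-1]])


def derive_kinematics(
    trial: TrialRecording,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    gravity_axis: str = "z",
    filter_orientation: bool = False,
) -> KinematicDerivatives:
    """Filter a trial's position channels and differentiate into velocities.

    Orientation channels are differentiated unfiltered by default
    (``filter_orientation=True`` low-passes each quaternion component and
    renormalizes before differentiation).
    """
    fs = trial.fs
    pos = np.column_stack(
        [lowpass(trial.position[:, i], cutoff_hz, fs) for i in range(3)]
    )
    quat = trial.orientation
    if filter_orientation:
        quat = np.column_stack(
            [lowpass(quat[:, i], cutoff_hz, fs) for i in range(4)]
        )
        quat = quat / np.linalg.norm(quat, axis=1, keepdims=True)
    vel = linear_velocity(pos, trial.time)
    speed_sq = np.einsum("ij,ij->i", vel, vel)
    omega = angular_velocity(quat, trial.time)
    height = pos[:, _AXIS_INDEX[gravity_axis]]
    path_increment = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    return KinematicDerivatives(
        speed_sq=speed_sq,
        omega=omega,
        height=height,
        path_increment=path_increment,
        time=trial.time,
    )
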