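import logging

import numpy as np
import pytest

from arthroskill import Expertise, ToolRole, TrialRecording

# the 12-Hz-above-Nyquist clamp warning is by design and would flood test logs
logging.getLogger("arthroskill.preprocessing").setLevel(logging.ERROR)

FS = 20.0


def make_trial(
    position,
    orientation=None,
    force=None,
    fs=FS,
    tool_role=ToolRole.INSTRUMENT,
    expertise=Expertise.NOVICE,
    subject_id="s1",
    task_id=1,
    t0=0.0,
):
    """Assemble a TrialRecording from raw arrays, defaulting orientation to identity."""
    position = np.asarray(position, dtype=float)
    n = position.shape[0]
    time = t0 + np.arange(n) / fs
    if orientation is None:
        orientation = np.tile([1.0, 0.0, 0.0, 0.0], (n, 1))
    return TrialRecording(
        subject_id=subject_id,
        expertise=expertise,
        task_id=task_id,
        tool_role=ToolRole(tool_role),
        time=time,
        position=position,
        orientation=np.asarray(orientation, dtype=float),
        force=None if force is None else np.asarray(force, dtype=float),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def smooth_trial(rng):
    """A gently curving 10-s instrument trial with slow (<0.5 Hz) content."""
    n = 201
    t = np.arange(n) / FS
    pos = np.column_stack(
        [
            0.03 * np.sin(2 * np.pi * 0.3 * t),
            0.02 * np.sin(2 * np.pi * 0.4 * t + 0.5),
            0.04 * np.sin(2 * np.pi * 0.2 * t + 1.0),
        ]
    )
    angle = 0.5 * np.sin(2 * np.pi * 0.3 * t)
    orientation = np.column_stack(
        [np.cos(angle / 2), np.sin(angle / 2), np.zeros(n), np.zeros(n)]
    )
    force = 1.0 + 0.5 * np.sin(2 * np.pi * 0.4 * t) ** 2
    return make_trial(pos, orientation, force)
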