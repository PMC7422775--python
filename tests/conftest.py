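import math

import numpy as np
import pytest

from vigilfield.io import (
    REQUIRED_AU_KEYS,
    FrameRecord,
    ThresholdGrid,
    TrialRecord,
    assemble_session,
)


def make_frame(
    i: int,
    t: float | None = None,
    valid: bool = True,
    gaze=(0.0, 0.0),
    head=(0.0, 0.0, 600.0),
    rot=(0.0, 0.0, 0.0),
    au=None,
    frame_rate: float = 5.0,
) -> FrameRecord:
    """One frame with sensible defaults; au overrides merge over zeros."""
    base_au = {k: 0.0 for k in REQUIRED_AU_KEYS}
    if au:
        base_au.update(au)
    return FrameRecord(
        frame_index=i,
        timestamp=t if t is not None else i / frame_rate,
        valid=valid,
        confidence=0.98 if valid else 0.1,
        gaze_x=gaze[0],
        gaze_y=gaze[1],
        head_x=head[0],
        head_y=head[1],
        head_z=head[2],
        head_yaw=rot[0],
        head_pitch=rot[1],
        head_roll=rot[2],
        au=base_au,
    )


def make_trial(
    i: int,
    onset: float,
    responded: bool = True,
    latency: float | None = 0.5,
    location_id: int = 0,
    stimulus_db: float = 25.0,
) -> TrialRecord:
    return TrialRecord(
        trial_index=i,
        location_id=location_id,
        stimulus_db=stimulus_db,
        onset_time=onset,
        responded=responded,
        latency=latency if responded else None,
    )


@pytest.fixture
def flat_grid():
    return ThresholdGrid.from_db([30.0] * 24)


@pytest.fixture
def toy_session(flat_grid):
    """60 constant frames at 5 Hz (12 s) with four trials."""
    frames = [make_frame(i) for i in range(60)]
    trials = [
        make_trial(0, 1.0, True, 0.4, location_id=0, stimulus_db=25.0),
        make_trial(1, 4.0, False, None, location_id=1, stimulus_db=26.0),
        make_trial(2, 7.0, True, 0.6, location_id=2, stimulus_db=27.0),
        make_trial(3, 10.0, True, 0.5, location_id=3, stimulus_db=28.0),
    ]
    return assemble_session(frames, trials, flat_grid, frame_rate=5.0, subject_id="T0", eye="OD")


def sn_brute_force(points) -> float:
    """Exhaustive O(n^2) Sn oracle: pure-Python pairwise enumeration."""
    from statistics import median

    pts = [tuple(map(float, np.atleast_1d(p))) for p in points]
    inner = []
    for i, pi in enumerate(pts):
        dists = [math.dist(pi, pj) for j, pj in enumerate(pts) if j != i]
        inner.append(median(dists))
    return float(median(inner))
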