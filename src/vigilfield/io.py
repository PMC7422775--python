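"""Reading, writing and validation of session data.

A visual field assessment session couples three tables:

* a frame-feature table in the OpenFace 2.0 CSV dialect — one row per
  webcam frame, carrying gaze angles, head pose and facial action-unit
  (AU) intensities;
* a trial log — one row per stimulus presentation (location, level in
  dB, response flag, response latency);
* a threshold grid — the 24 per-location differential light sensitivity
  (DLS) estimates of the central 24-2 locations, in dB.

The reader applies a frame-validity rule (detection-success flag plus a
confidence floor) so that frames where no face was tracked never enter
biomarker computations, and converts gaze angles from the upstream
radian dialect to degrees visual angle.
"""
from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "ValidationError",
    "FrameRecord",
    "TrialRecord",
    "ThresholdGrid",
    "SessionData",
    "REQUIRED_AU_KEYS",
    "standard_24_grid_coords",
    "read_frame_table",
    "write_frame_table",
    "read_trial_log",
    "write_trial_log",
    "read_threshold_grid",
    "write_threshold_grid",
    "assemble_session",
    "read_session",
    "write_session",
]

#: AU channels required on every frame record (FACS labels).
REQUIRED_AU_KEYS = ("AU01", "AU02", "AU04", "AU15", "AU25", "AU26", "AU45")

#: Required columns of the OpenFace 2.0 frame table. ``timestamp`` is
#: optional: when absent it is reconstructed from frame index and rate.
FRAME_TABLE_COLUMNS = (
    "frame",
    "confidence",
    "success",
    "gaze_angle_x",
    "gaze_angle_y",
    "pose_Tx",
    "pose_Ty",
    "pose_Tz",
    "pose_Rx",
    "pose_Ry",
    "pose_Rz",
    "AU01_r",
    "AU02_r",
    "AU04_r",
    "AU15_r",
    "AU25_r",
    "AU26_r",
    "AU45_r",
)

TRIAL_LOG_COLUMNS = ("trial", "location_id", "stimulus_db", "onset_s", "responded", "latency_s")

THRESHOLD_GRID_COLUMNS = ("location_id", "x_deg", "y_deg", "dls_db")


class FormatError(ValueError):
    """A file does not conform to the documented CSV dialect."""


class ValidationError(ValueError):
    """Parsed data violate a domain invariant."""


def standard_24_grid_coords() -> tuple[np.ndarray, np.ndarray]:
    """Coordinates (degrees) of the central 24 locations of the 24-2 grid.

    A 4 x 6 lattice spanning +/-15 degrees horizontally and +/-9 degrees
    vertically, on the standard 6-degree spacing.
    """
    xs = np.array([-15.0, -9.0, -3.0, 3.0, 9.0, 15.0])
    ys = np.array([-9.0, -3.0, 3.0, 9.0])
    gx, gy = np.meshgrid(xs, ys)
    return gx.ravel(), gy.ravel()


@dataclass(frozen=True)
class FrameRecord:
    """Derived features of one webcam frame.

    Gaze angles are degrees visual angle, head translation millimetres,
    head rotation degrees, AU intensities non-negative arbitrary units.
    When ``valid`` is False the feature fields may be NaN and the frame
    is excluded from every biomarker computation.
    """

    frame_index: int
    timestamp: float
    valid: bool
    confidence: float
    gaze_x: float = math.nan
    gaze_y: float = math.nan
    head_x: float = math.nan
    head_y: float = math.nan
    head_z: float = math.nan
    head_yaw: float = math.nan
    head_pitch: float = math.nan
    head_roll: float = math.nan
    au: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValidationError(f"frame_index must be >= 0, got {self.frame_index}")
        if self.valid:
            missing = [k for k in REQUIRED_AU_KEYS if k not in self.au]
            if missing:
                raise ValidationError(f"valid frame missing AU channels: {missing}")
            for k, v in self.au.items():
                if not math.isnan(v) and v < 0:
                    raise ValidationError(f"AU intensity must be >= 0: {k}={v}")


@dataclass(frozen=True)
class TrialRecord:
    """One stimulus presentation of a perimetric test."""

    trial_index: int
    location_id: int
    stimulus_db: float
    onset_time: float
    responded: bool
    latency: float | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.stimulus_db):
            raise ValidationError(f"trial {self.trial_index}: stimulus_db not finite")
        if self.responded:
            if self.latency is None:
                raise ValidationError(f"trial {self.trial_index}: responded without latency")
            if not (self.latency > 0):
                raise ValidationError(
                    f"trial {self.trial_index}: latency must be > 0, got {self.latency}"
                )
        elif self.latency is not None:
            raise ValidationError(f"trial {self.trial_index}: latency present without response")


@dataclass(frozen=True)
class ThresholdGrid:
    """Per-location DLS threshold estimates on the central 24-2 grid.

    Values are stored canonically in dB; :mod:`vigilfield.perimetry`
    provides the exact dB <-> cd/m^2 interconversion.
    """

    location_ids: tuple[int, ...]
    x_deg: tuple[float, ...]
    y_deg: tuple[float, ...]
    db: tuple[float, ...]

    N_LOCATIONS = 24

    def __post_init__(self) -> None:
        n = len(self.location_ids)
        if n != self.N_LOCATIONS:
            raise ValidationError(f"threshold grid needs exactly {self.N_LOCATIONS} locations, got {n}")
        if len(set(self.location_ids)) != n:
            raise ValidationError("duplicate location_id in threshold grid")
        if not (len(self.x_deg) == len(self.y_deg) == len(self.db) == n):
            raise ValidationError("threshold grid field lengths disagree")

    @classmethod
    def from_db(cls, db_values: Sequence[float], location_ids: Sequence[int] | None = None) -> "ThresholdGrid":
        """Build a grid on the standard 24-location geometry from dB values."""
        xs, ys = standard_24_grid_coords()
        if location_ids is None:
            location_ids = range(cls.N_LOCATIONS)
        return cls(
            location_ids=tuple(int(i) for i in location_ids),
            x_deg=tuple(float(x) for x in xs),
            y_deg=tuple(float(y) for y in ys),
            db=tuple(float(v) for v in db_values),
        )

    def db_at(self, location_id: int) -> float:
        try:
            return self.db[self.location_ids.index(location_id)]
        except ValueError:
            raise KeyError(f"location_id {location_id} not in threshold grid") from None

    def db_array(self) -> np.ndarray:
        return np.asarray(self.db, dtype=float)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "location_id": self.location_ids,
                "x_deg": self.x_deg,
                "y_deg": self.y_deg,
                "dls_db": self.db,
            }
        )


@dataclass(frozen=True)
class SessionData:
    """One visual field assessment: frame stream + trial log + thresholds."""

    subject_id: str
    eye: str
    frame_rate: float
    frames: tuple[FrameRecord, ...]
    trials: tuple[TrialRecord, ...]
    thresholds: ThresholdGrid

    def __post_init__(self) -> None:
        if not (self.frame_rate > 0):
            raise ValidationError(f"frame_rate must be > 0, got {self.frame_rate}")
        ts = [f.timestamp for f in self.frames]
        if any(b < a for a, b in zip(ts, ts[1:])):
            raise ValidationError("frame timestamps must be non-decreasing")
        if self.frames:
            tol = 1.0 / self.frame_rate
            lo, hi = ts[0] - tol, ts[-1] + tol
            bad = [t.trial_index for t in self.trials if not (lo <= t.onset_time <= hi)]
            if bad:
                raise ValidationError(f"trial onsets outside frame time span: trials {bad}")

    @property
    def valid_frames(self) -> tuple[FrameRecord, ...]:
        return tuple(f for f in self.frames if f.valid)

    @property
    def valid_fraction(self) -> float:
        return (len(self.valid_frames) / len(self.frames)) if self.frames else math.nan


# ---------------------------------------------------------------------------
# readers / writers


def _read_csv(path: str | Path, allow_empty: bool = False) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, skipinitialspace=True)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: file is empty") from None
    df.columns = [c.strip() for c in df.columns]
    if df.empty and not allow_empty:
        raise FormatError(f"{path}: no data rows")
    return df


def _require_columns(df: pd.DataFrame, required: Iterable[str], path: str | Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def read_frame_table(
    path: str | Path,
    confidence_floor: float = 0.75,
    gaze_in_radians: bool = True,
    frame_rate: float = 5.0,
) -> list[FrameRecord]:
    """Read an OpenFace-dialect frame-feature table.

    Rows whose detection-success flag is 0 or whose confidence falls
    below ``confidence_floor`` are kept but marked invalid.  Gaze angles
    are converted from radians to degrees unless ``gaze_in_radians`` is
    False (the upstream tool emits radians; biomarkers are defined in
    degrees visual angle).  ``frame_rate`` is only used to reconstruct
    timestamps when a ``timestamp`` column is absent.
    """
    df = _read_csv(path)
    _require_columns(df, FRAME_TABLE_COLUMNS, path)
    if "timestamp" in df.columns:
        timestamps = df["timestamp"].to_numpy(dtype=float)
    else:
        timestamps = df["frame"].to_numpy(dtype=float) / float(frame_rate)
        logger.info("%s: no timestamp column; reconstructed from frame index at %g Hz", path, frame_rate)

    gaze_scale = 180.0 / math.pi if gaze_in_radians else 1.0
    records: list[FrameRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        valid = bool(int(getattr(row, "success")) == 1) and float(row.confidence) >= confidence_floor
        au = {k: float(getattr(row, f"{k}_r")) for k in REQUIRED_AU_KEYS}
        if not valid:
            au = {k: v for k, v in au.items() if not math.isnan(v)}
        records.append(
            FrameRecord(
                frame_index=int(getattr(row, "frame")),
                timestamp=float(timestamps[i]),
                valid=valid,
                confidence=float(row.confidence),
                gaze_x=float(row.gaze_angle_x) * gaze_scale,
                gaze_y=float(row.gaze_angle_y) * gaze_scale,
                head_x=float(row.pose_Tx),
                head_y=float(row.pose_Ty),
                head_z=float(row.pose_Tz),
                head_yaw=float(row.pose_Ry),
                head_pitch=float(row.pose_Rx),
                head_roll=float(row.pose_Rz),
                au=au,
            )
        )
    n_valid = sum(r.valid for r in records)
    logger.info("%s: %d frames read, %d valid (%.1f%%)", path, len(records), n_valid, 100 * n_valid / len(records))
    return records


def write_frame_table(frames: Sequence[FrameRecord], path: str | Path, gaze_in_radians: bool = True) -> None:
    """Write frames in the same dialect :func:`read_frame_table` reads."""
    gaze_scale = math.pi / 180.0 if gaze_in_radians else 1.0
    rows = []
    for f in frames:
        row = {
            "frame": f.frame_index,
            "timestamp": f.timestamp,
            "confidence": f.confidence,
            "success": int(f.valid),
            "gaze_angle_x": f.gaze_x * gaze_scale,
            "gaze_angle_y": f.gaze_y * gaze_scale,
            "pose_Tx": f.head_x,
            "pose_Ty": f.head_y,
            "pose_Tz": f.head_z,
            "pose_Rx": f.head_pitch,
            "pose_Ry": f.head_yaw,
            "pose_Rz": f.head_roll,
        }
        for k in REQUIRED_AU_KEYS:
            row[f"{k}_r"] = f.au.get(k, math.nan)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_trial_log(path: str | Path) -> list[TrialRecord]:
    """Read a trial log CSV; records come back sorted by onset time."""
    df = _read_csv(path, allow_empty=True)  # a session may have no trials
    _require_columns(df, TRIAL_LOG_COLUMNS, path)
    df = df.sort_values("onset_s", kind="stable")
    records = []
    for row in df.itertuples(index=False):
        responded = bool(int(row.responded))
        latency = float(row.latency_s) if not pd.isna(row.latency_s) else None
        if responded and latency is None:
            raise ValidationError(f"{path}: trial {row.trial} responded but latency empty")
        records.append(
            TrialRecord(
                trial_index=int(row.trial),
                location_id=int(row.location_id),
                stimulus_db=float(row.stimulus_db),
                onset_time=float(row.onset_s),
                responded=responded,
                latency=latency,
            )
        )
    return records


def write_trial_log(trials: Sequence[TrialRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "trial": [t.trial_index for t in trials],
            "location_id": [t.location_id for t in trials],
            "stimulus_db": [t.stimulus_db for t in trials],
            "onset_s": [t.onset_time for t in trials],
            "responded": [int(t.responded) for t in trials],
            "latency_s": [t.latency if t.latency is not None else "" for t in trials],
        }
    ).to_csv(path, index=False)


def read_threshold_grid(path: str | Path) -> ThresholdGrid:
    df = _read_csv(path)
    _require_columns(df, THRESHOLD_GRID_COLUMNS, path)
    return ThresholdGrid(
        location_ids=tuple(int(v) for v in df["location_id"]),
        x_deg=tuple(float(v) for v in df["x_deg"]),
        y_deg=tuple(float(v) for v in df["y_deg"]),
        db=tuple(float(v) for v in df["dls_db"]),
    )


def write_threshold_grid(grid: ThresholdGrid, path: str | Path) -> None:
    grid.to_dataframe().to_csv(path, index=False)


def assemble_session(
    frames: Sequence[FrameRecord],
    trials: Sequence[TrialRecord],
    thresholds: ThresholdGrid,
    frame_rate: float = 5.0,
    subject_id: str = "anon",
    eye: str = "OD",
) -> SessionData:
    """Assemble and validate a :class:`SessionData` from its parts."""
    session = SessionData(
        subject_id=subject_id,
        eye=eye,
        frame_rate=frame_rate,
        frames=tuple(frames),
        trials=tuple(trials),
        thresholds=thresholds,
    )
    logger.info(
        "session %s/%s: %d frames (%.1f%% valid), %d trials",
        subject_id,
        eye,
        len(session.frames),
        100 * session.valid_fraction if session.frames else float("nan"),
        len(session.trials),
    )
    return session


def write_session(session: SessionData, directory: str | Path) -> Path:
    """Write a session as frames.csv + trials.csv + thresholds.csv + session.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_frame_table(session.frames, directory / "frames.csv")
    write_trial_log(session.trials, directory / "trials.csv")
    write_threshold_grid(session.thresholds, directory / "thresholds.csv")
    meta = {"subject_id": session.subject_id, "eye": session.eye, "frame_rate": session.frame_rate}
    (directory / "session.json").write_text(json.dumps(meta, indent=2))
    return directory


def read_session(directory: str | Path, confidence_floor: float = 0.75) -> SessionData:
    """Read back a session directory written by :func:`write_session`."""
    directory = Path(directory)
    meta = json.loads((directory / "session.json").read_text())
    frames = read_frame_table(
        directory / "frames.csv",
        confidence_floor=confidence_floor,
        frame_rate=meta["frame_rate"],
    )
    trials = read_trial_log(directory / "trials.csv")
    thresholds = read_threshold_grid(directory / "thresholds.csv")
    return assemble_session(
        frames,
        trials,
        thresholds,
        frame_rate=meta["frame_rate"],
        subject_id=meta["subject_id"],
        eye=meta["eye"],
    )
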