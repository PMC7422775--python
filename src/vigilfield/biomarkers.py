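"""The seven compliance biomarkers and their weighted composite.

Three dispersion biomarkers use the Rousseeuw-Croux Sn estimator — the
median over observations of the median Euclidean distance to every
other observation:

    Sn = c_n * med_i ( med_{j != i} |d_ij| )

applied to per-frame gaze coordinates (degrees), head translation (mm)
and head rotation (yaw/pitch/roll, degrees).  Sn is non-parametric,
needs no normality assumption and has a 50% breakdown point, so a short
burst of wild frames barely moves it.  The finite-sample bias factor
c_n is fixed at 1.

Three expression biomarkers are mean per-frame sums of facial action
unit (AU) intensities: sadness = AU4 + AU15, surprise = AU1 + AU2 +
AU25 + AU26, blink = AU45.  The seventh biomarker is the mean response
latency over responded trials.

The composite standardizes each biomarker as a z-score across the
analysis cohort and takes a weighted linear sum, with weights
proportional to each biomarker's Pearson correlation with measurement
error, normalized to sum to one.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr

from .io import FrameRecord, SessionData, TrialRecord

logger = logging.getLogger(__name__)

__all__ = [
    "SADNESS_AUS",
    "SURPRISE_AUS",
    "BLINK_AUS",
    "BIOMARKER_NAMES",
    "VIDEO_BIOMARKER_NAMES",
    "BiomarkerVector",
    "CompositeModel",
    "sn_dispersion",
    "gaze_variability",
    "head_location_variability",
    "head_rotation_variability",
    "mean_au_sum",
    "mean_response_latency",
    "session_biomarkers",
    "windowed_biomarkers",
    "fit_composite_model",
    "composite_score",
    "composite_scores",
]

SADNESS_AUS = ("AU04", "AU15")
SURPRISE_AUS = ("AU01", "AU02", "AU25", "AU26")
BLINK_AUS = ("AU45",)

BIOMARKER_NAMES = (
    "gaze_variability",
    "head_location_variability",
    "head_rotation_variability",
    "mean_sadness",
    "mean_surprise",
    "blink_rate",
    "mean_response_latency",
)
#: The six biomarkers computable from video alone (latency excluded).
VIDEO_BIOMARKER_NAMES = BIOMARKER_NAMES[:-1]


@dataclass(frozen=True)
class BiomarkerVector:
    """The seven scalar biomarkers for a session or a trial window.

    A field is None when the underlying data were insufficient (e.g.
    fewer than two valid frames for a dispersion, no responded trial
    for the latency).
    """

    gaze_variability: float | None = None
    head_location_variability: float | None = None
    head_rotation_variability: float | None = None
    mean_sadness: float | None = None
    mean_surprise: float | None = None
    blink_rate: float | None = None
    mean_response_latency: float | None = None

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v is not None and f.name != "mean_response_latency" and v < 0:
                raise ValueError(f"{f.name} must be >= 0, got {v}")

    def as_dict(self) -> dict[str, float | None]:
        return {name: getattr(self, name) for name in BIOMARKER_NAMES}


def sn_dispersion(points: Sequence[Sequence[float]] | np.ndarray, c_n: float = 1.0) -> float | None:
    """Rousseeuw-Croux Sn dispersion of d-dimensional points.

    Returns ``c_n * med_i(med_{j!=i} |d_ij|)`` with Euclidean d_ij and
    the even-count median taken as the mean of the two central order
    statistics (for both the inner and outer median).  Returns None for
    fewer than two points (insufficient data); raises for non-finite
    input.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    n = pts.shape[0]
    if n < 2:
        return None
    if not np.all(np.isfinite(pts)):
        raise ValueError("sn_dispersion requires finite coordinates")
    d = squareform(pdist(pts))
    # row-wise off-diagonal entries: each inner median runs over n-1 distances
    offdiag = d[~np.eye(n, dtype=bool)].reshape(n, n - 1)
    inner = np.median(offdiag, axis=1)
    return float(c_n * np.median(inner))


def _valid(frames: Iterable[FrameRecord]) -> list[FrameRecord]:
    return [f for f in frames if f.valid]


def gaze_variability(session: SessionData | Sequence[FrameRecord]) -> float | None:
    """Sn dispersion of valid-frame (x, y) gaze coordinates, in degrees."""
    frames = _valid(session.frames if isinstance(session, SessionData) else session)
    if len(frames) < 2:
        return None
    return sn_dispersion([(f.gaze_x, f.gaze_y) for f in frames])


def head_location_variability(session: SessionData | Sequence[FrameRecord]) -> float | None:
    """Sn dispersion of valid-frame (x, y, z) head translation, in mm."""
    frames = _valid(session.frames if isinstance(session, SessionData) else session)
    if len(frames) < 2:
        return None
    return sn_dispersion([(f.head_x, f.head_y, f.head_z) for f in frames])


def head_rotation_variability(session: SessionData | Sequence[FrameRecord]) -> float | None:
    """Sn dispersion of valid-frame (yaw, pitch, roll) head rotation, degrees."""
    frames = _valid(session.frames if isinstance(session, SessionData) else session)
    if len(frames) < 2:
        return None
    return sn_dispersion([(f.head_yaw, f.head_pitch, f.head_roll) for f in frames])


def mean_au_sum(frames: Iterable[FrameRecord], au_labels: Sequence[str]) -> float | None:
    """Mean over valid frames of the per-frame sum of the listed AU intensities."""
    frames = _valid(frames)
    if not frames:
        return None
    sums = [sum(f.au[k] for k in au_labels) for f in frames]
    return float(np.mean(sums))


def mean_response_latency(trials: Iterable[TrialRecord]) -> float | None:
    """Mean latency over responded trials; missed trials contribute nothing."""
    latencies = [t.latency for t in trials if t.responded and t.latency is not None]
    if not latencies:
        return None
    return float(np.mean(latencies))


def session_biomarkers(session: SessionData) -> BiomarkerVector:
    """All seven biomarkers of a whole session."""
    frames = session.valid_frames
    return BiomarkerVector(
        gaze_variability=gaze_variability(frames),
        head_location_variability=head_location_variability(frames),
        head_rotation_variability=head_rotation_variability(frames),
        mean_sadness=mean_au_sum(frames, SADNESS_AUS),
        mean_surprise=mean_au_sum(frames, SURPRISE_AUS),
        blink_rate=mean_au_sum(frames, BLINK_AUS),
        mean_response_latency=mean_response_latency(session.trials),
    )


def windowed_biomarkers(
    session: SessionData,
    trial: TrialRecord,
    window_frames: int = 20,
    response_window_s: float = 1.5,
) -> BiomarkerVector:
    """Video biomarkers from one trial plus the frames directly preceding it.

    Frames with timestamps in ``[onset - window_frames/frame_rate, trial
    end]`` are used, where the trial ends at response (or after
    ``response_window_s`` for a miss).  At the start of a session the
    window simply truncates.  The latency biomarker is never computed at
    trial resolution (it is undefined for missed trials).
    """
    if trial not in session.trials:
        raise ValueError(f"trial {trial.trial_index} does not belong to this session")
    t0 = trial.onset_time - window_frames / session.frame_rate
    t1 = trial.onset_time + (trial.latency if trial.latency is not None else response_window_s)
    frames = [f for f in session.valid_frames if t0 <= f.timestamp <= t1]
    if len(frames) < 2:
        return BiomarkerVector(
            mean_sadness=mean_au_sum(frames, SADNESS_AUS),
            mean_surprise=mean_au_sum(frames, SURPRISE_AUS),
            blink_rate=mean_au_sum(frames, BLINK_AUS),
        )
    return BiomarkerVector(
        gaze_variability=gaze_variability(frames),
        head_location_variability=head_location_variability(frames),
        head_rotation_variability=head_rotation_variability(frames),
        mean_sadness=mean_au_sum(frames, SADNESS_AUS),
        mean_surprise=mean_au_sum(frames, SURPRISE_AUS),
        blink_rate=mean_au_sum(frames, BLINK_AUS),
    )


# ---------------------------------------------------------------------------
# composite


class DegenerateWeightsError(ValueError):
    """The correlation weights cannot be normalized (sum of rho <= 0)."""


@dataclass(frozen=True)
class CompositeModel:
    """Standardization constants and correlation weights for the composite."""

    names: tuple[str, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]
    rho: tuple[float, ...]
    weights: tuple[float, ...]
    c_n: float = 1.0

    def __post_init__(self) -> None:
        s = sum(self.weights)
        if not math.isclose(s, 1.0, abs_tol=1e-12):
            raise ValueError(f"composite weights must sum to 1, got {s}")

    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "means": list(self.means),
            "sds": list(self.sds),
            "rho": list(self.rho),
            "weights": list(self.weights),
            "c_n": self.c_n,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CompositeModel":
        return cls(
            names=tuple(d["names"]),
            means=tuple(d["means"]),
            sds=tuple(d["sds"]),
            rho=tuple(d["rho"]),
            weights=tuple(d["weights"]),
            c_n=d.get("c_n", 1.0),
        )


def fit_composite_model(biomarker_matrix: pd.DataFrame, target: Sequence[float]) -> CompositeModel:
    """Fit standardization constants and correlation weights.

    ``biomarker_matrix`` has one row per session/eye and one column per
    biomarker; ``target`` is the per-row measurement error.  Weights are
    omega_i = rho_i / sum_j rho_j with rho_i the Pearson correlation of
    column i with the target, kept signed; a non-positive rho sum raises
    :class:`DegenerateWeightsError`.
    """
    X = pd.DataFrame(biomarker_matrix)
    y = np.asarray(target, dtype=float)
    if len(X) < 3:
        raise ValueError(f"need >= 3 rows to fit the composite, got {len(X)}")
    if len(X) != len(y):
        raise ValueError("biomarker matrix and target lengths differ")
    means, sds, rho = [], [], []
    for col in X.columns:
        v = X[col].to_numpy(dtype=float)
        if np.all(np.isnan(v)):
            raise ValueError(f"biomarker column {col!r} is entirely missing")
        sd = float(np.std(v, ddof=1))
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"biomarker column {col!r} has zero variance")
        means.append(float(np.mean(v)))
        sds.append(sd)
        rho.append(float(pearsonr(v, y)[0]))
    rho_sum = float(np.sum(rho))
    if rho_sum <= 0:
        raise DegenerateWeightsError(f"sum of correlations is {rho_sum:.4g} <= 0")
    weights = np.asarray(rho) / rho_sum
    weights /= weights.sum()  # exact renormalization against rounding
    return CompositeModel(
        names=tuple(str(c) for c in X.columns),
        means=tuple(means),
        sds=tuple(sds),
        rho=tuple(rho),
        weights=tuple(float(w) for w in weights),
    )


def composite_score(model: CompositeModel, vector: BiomarkerVector | Mapping[str, float]) -> float:
    """Weighted sum of z-scored biomarkers: sum_i omega_i * (X_i - m_i)/s_i."""
    values = vector.as_dict() if isinstance(vector, BiomarkerVector) else dict(vector)
    total = 0.0
    for name, m, s, w in zip(model.names, model.means, model.sds, model.weights):
        x = values.get(name)
        if x is None or (isinstance(x, float) and math.isnan(x)):
            if w != 0:
                raise ValueError(f"biomarker {name!r} is missing but has weight {w:.4g}")
            continue
        total += w * (float(x) - m) / s
    return total


def composite_scores(model: CompositeModel, biomarker_matrix: pd.DataFrame) -> pd.Series:
    """Vectorized :func:`composite_score` over a biomarker table."""
    X = pd.DataFrame(biomarker_matrix)
    z = (X[list(model.names)] - np.asarray(model.means)) / np.asarray(model.sds)
    return z.mul(np.asarray(model.weights)).sum(axis=1)
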