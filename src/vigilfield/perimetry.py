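"""Perimetric quantities: dB scale, mean sensitivity, errors, visible trials.

The perimetric decibel scale is an attenuation scale relative to the
instrument's maximum stimulus luminance: ``dB = 10*log10(3183.1 / DLS)``
with DLS in cd/m^2, so higher dB means a dimmer stimulus was detected,
i.e. better sensitivity.  Mean sensitivity (MS) is the arithmetic mean
of the 24 per-location dB thresholds and is the test's summary score;
test-retest error is the absolute difference in MS between two
assessments of the same eye.

``extract_visible_trials`` implements the suprathreshold ("visible")
trial rule used for lapse detection: a trial is visible when its
stimulus was more than ``margin_db`` (default 3 dB, a doubling of
luminance) brighter than the location's final threshold estimate — far
above the ~1 dB spread of a typical frequency-of-seeing curve, so a
miss on such a trial indicates a lapse rather than sensory failure.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import SessionData, ThresholdGrid, TrialRecord, standard_24_grid_coords

__all__ = [
    "MAX_LUMINANCE_CDM2",
    "dls_to_db",
    "db_to_dls",
    "grid_from_luminance",
    "grid_luminance",
    "mean_sensitivity",
    "test_retest_error",
    "VisibleTrialSet",
    "extract_visible_trials",
    "hit_rate",
]

#: Reference (0 dB) stimulus luminance in cd/m^2.
MAX_LUMINANCE_CDM2 = 3183.1


def dls_to_db(dls):
    """Convert differential light sensitivity in cd/m^2 to dB.

    Raises ``ValueError`` for non-positive luminance.
    """
    dls = np.asarray(dls, dtype=float)
    if np.any(dls <= 0):
        raise ValueError("DLS must be > 0 cd/m^2")
    out = 10.0 * np.log10(MAX_LUMINANCE_CDM2 / dls)
    return float(out) if out.ndim == 0 else out


def db_to_dls(db):
    """Inverse of :func:`dls_to_db`; exact round trip."""
    db = np.asarray(db, dtype=float)
    out = MAX_LUMINANCE_CDM2 / 10.0 ** (db / 10.0)
    return float(out) if out.ndim == 0 else out


def grid_from_luminance(dls_values, location_ids=None) -> ThresholdGrid:
    """Build a :class:`ThresholdGrid` from cd/m^2 values on the standard grid."""
    return ThresholdGrid.from_db(dls_to_db(np.asarray(dls_values, dtype=float)), location_ids)


def grid_luminance(grid: ThresholdGrid) -> np.ndarray:
    """Per-location thresholds of ``grid`` in cd/m^2."""
    return db_to_dls(grid.db_array())


def mean_sensitivity(grid: ThresholdGrid) -> float:
    """Arithmetic mean of the 24 dB thresholds (MS)."""
    return float(np.mean(grid.db_array()))


def test_retest_error(ms1: float, ms2: float) -> float:
    """Absolute MS difference between two assessments of the same eye (dB)."""
    if not (np.isfinite(ms1) and np.isfinite(ms2)):
        raise ValueError("mean sensitivities must be finite")
    return abs(float(ms1) - float(ms2))


@dataclass(frozen=True)
class VisibleTrialSet:
    """Suprathreshold trials of one session with their hit/miss outcomes."""

    trials: tuple[TrialRecord, ...]
    threshold_db: tuple[float, ...]
    margin_db_rule: float

    def __post_init__(self) -> None:
        for t, th in zip(self.trials, self.threshold_db):
            if not (th - t.stimulus_db > self.margin_db_rule):
                raise ValueError(
                    f"trial {t.trial_index} violates the >{self.margin_db_rule} dB visibility rule"
                )

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def margins(self) -> np.ndarray:
        """threshold_dB - stimulus_dB per member (dB below threshold = brighter)."""
        return np.array([th - t.stimulus_db for t, th in zip(self.trials, self.threshold_db)])

    @property
    def hits(self) -> np.ndarray:
        return np.array([t.responded for t in self.trials], dtype=bool)

    @property
    def n_hits(self) -> int:
        return int(self.hits.sum())

    @property
    def n_misses(self) -> int:
        return len(self) - self.n_hits

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": [t.trial_index for t in self.trials],
                "location_id": [t.location_id for t in self.trials],
                "stimulus_db": [t.stimulus_db for t in self.trials],
                "threshold_db": self.threshold_db,
                "margin_db": self.margins,
                "outcome": np.where(self.hits, "hit", "miss"),
            }
        )


def extract_visible_trials(session: SessionData, margin_db: float = 3.0) -> VisibleTrialSet:
    """Trials presented strictly more than ``margin_db`` brighter than threshold.

    Uses the session's own final threshold estimates as the best guess
    of the true threshold at each location.  The inequality is strict:
    a trial at exactly ``margin_db`` below threshold is excluded.
    """
    members: list[TrialRecord] = []
    thresholds: list[float] = []
    for t in session.trials:
        th = session.thresholds.db_at(t.location_id)  # KeyError if absent
        if th - t.stimulus_db > margin_db:
            members.append(t)
            thresholds.append(th)
    return VisibleTrialSet(tuple(members), tuple(thresholds), margin_db)


def hit_rate(visible: VisibleTrialSet) -> float | None:
    """Proportion of visible trials responded to; None for an empty set."""
    if len(visible) == 0:
        return None
    return visible.n_hits / len(visible)
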