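"""Statistical association between compliance biomarkers and measurement error.

Two analyses:

* **Test-by-test** — Pearson correlation between each session-level
  biomarker (averaged over an eye's repeat assessments) and that eye's
  test-retest error in mean sensitivity, plus the same for the weighted
  composite.  Scatter slopes are geometric-mean (reduced major axis)
  regressions: slope = sign(r) * SD(error) / SD(biomarker) through the
  centroid.

* **Trial-by-trial** — each video biomarker recomputed per visible
  (suprathreshold) trial from a short window of frames, then a binomial
  logistic regression of hit/miss on the raw biomarker value, with a
  likelihood-ratio chi-squared test (1 df) against the constant-only
  model.  Binned hit rates over four log-spaced bins with Wilson 95%
  intervals summarize the curve.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import pearsonr
from statsmodels.stats.proportion import proportion_confint
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .biomarkers import (
    BIOMARKER_NAMES,
    VIDEO_BIOMARKER_NAMES,
    CompositeModel,
    composite_scores,
    fit_composite_model,
    session_biomarkers,
    windowed_biomarkers,
)
from .io import SessionData
from .perimetry import extract_visible_trials, mean_sensitivity, test_retest_error

logger = logging.getLogger(__name__)

__all__ = [
    "BiomarkerAssociation",
    "AssociationResult",
    "LapseModelResult",
    "build_cohort_table",
    "testretest_association",
    "trialwise_dataset",
    "fit_lapse_model",
]


@dataclass(frozen=True)
class BiomarkerAssociation:
    """Pearson correlation and GM-regression line for one biomarker."""

    name: str
    r: float
    p: float
    slope: float
    intercept: float

    def to_dict(self) -> dict:
        return {"name": self.name, "r": self.r, "p": self.p, "slope": self.slope, "intercept": self.intercept}


@dataclass(frozen=True)
class AssociationResult:
    """Test-by-test association of biomarkers with test-retest MS error."""

    cohort_label: str
    n_eyes: int
    per_biomarker: tuple[BiomarkerAssociation, ...]
    composite: BiomarkerAssociation
    composite_model: CompositeModel
    excluded: tuple = ()

    def __getitem__(self, name: str) -> BiomarkerAssociation:
        for a in self.per_biomarker:
            if a.name == name:
                return a
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {
            "cohort_label": self.cohort_label,
            "n_eyes": self.n_eyes,
            "per_biomarker": [a.to_dict() for a in self.per_biomarker],
            "composite": self.composite.to_dict(),
            "composite_model": self.composite_model.to_dict(),
            "excluded": list(self.excluded),
        }


def _gm_regression(x: np.ndarray, y: np.ndarray, r: float) -> tuple[float, float]:
    """Geometric-mean (reduced major axis) slope and intercept.

    slope = sign(r) * SD(y)/SD(x); the line passes through the means,
    so the slope's sign always matches the correlation's.
    """
    slope = float(np.sign(r) if r != 0 else 1.0) * float(np.std(y, ddof=1) / np.std(x, ddof=1))
    intercept = float(np.mean(y) - slope * np.mean(x))
    return slope, intercept


def build_cohort_table(sessions_by_eye: Mapping[str, Sequence[SessionData]]) -> pd.DataFrame:
    """Per-eye biomarkers and test-retest error from assembled sessions.

    Each entry maps an eye key to its one or two assessments.  Biomarker
    estimates from repeat assessments are mean-averaged into a single
    value per eye; the error is the absolute MS difference between the
    two assessments (NaN when only one exists).
    """
    rows = []
    for key, sessions in sessions_by_eye.items():
        if not 1 <= len(sessions) <= 2:
            raise ValueError(f"eye {key!r}: expected 1 or 2 sessions, got {len(sessions)}")
        vecs = [session_biomarkers(s).as_dict() for s in sessions]
        row: dict = {"eye_key": key}
        for name in BIOMARKER_NAMES:
            vals = [v[name] for v in vecs if v[name] is not None]
            row[name] = float(np.mean(vals)) if vals else np.nan
        ms = [mean_sensitivity(s.thresholds) for s in sessions]
        row["ms1"] = ms[0]
        row["ms2"] = ms[1] if len(ms) > 1 else np.nan
        row["error_db"] = test_retest_error(ms[0], ms[1]) if len(ms) > 1 else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("eye_key")


def testretest_association(
    biomarkers: pd.DataFrame,
    error: Sequence[float],
    cohort_label: str = "healthy",
    exclude: Sequence = (),
) -> AssociationResult:
    """Correlate per-eye biomarkers (and their composite) with MS error.

    ``exclude`` lists row labels to drop before analysis — a manual
    outlier hook; every exclusion is logged.  Requires >= 4 eyes after
    exclusion.
    """
    X = pd.DataFrame(biomarkers).copy()
    y = pd.Series(np.asarray(error, dtype=float), index=X.index, name="error_db")
    if len(exclude):
        logger.warning("excluding %d eye(s) from %s association: %s", len(exclude), cohort_label, list(exclude))
        X = X.drop(index=list(exclude))
        y = y.drop(index=list(exclude))
    if len(X) < 4:
        raise ValueError(f"need >= 4 eyes, got {len(X)}")
    cols = [c for c in X.columns if c in BIOMARKER_NAMES]
    per = []
    for col in cols:
        x = X[col].to_numpy(dtype=float)
        if np.std(x, ddof=1) == 0:
            raise ValueError(f"biomarker column {col!r} has zero variance")
        r, p = pearsonr(x, y.to_numpy())
        slope, intercept = _gm_regression(x, y.to_numpy(), r)
        per.append(BiomarkerAssociation(col, float(r), float(p), slope, intercept))
    model = fit_composite_model(X[cols], y)
    scores = composite_scores(model, X[cols]).to_numpy()
    r, p = pearsonr(scores, y.to_numpy())
    slope, intercept = _gm_regression(scores, y.to_numpy(), r)
    composite = BiomarkerAssociation("composite", float(r), float(p), slope, intercept)
    return AssociationResult(
        cohort_label=cohort_label,
        n_eyes=len(X),
        per_biomarker=tuple(per),
        composite=composite,
        composite_model=model,
        excluded=tuple(exclude),
    )


def trialwise_dataset(
    sessions: Sequence[SessionData],
    margin_db: float = 3.0,
    window_frames: int = 20,
) -> pd.DataFrame:
    """One row per visible trial, pooled over all sessions.

    Columns: identifiers, stimulus/threshold/margin, the six video
    biomarkers computed from that trial's window, and ``hit`` (1/0).
    Rows with any missing biomarker are dropped (count logged).  The
    latency biomarker is excluded by construction — it is undefined on
    the missed trials the analysis is about.
    """
    rows = []
    for session in sessions:
        visible = extract_visible_trials(session, margin_db=margin_db)
        if len(visible) == 0:
            logger.warning("session %s/%s has no visible trials", session.subject_id, session.eye)
            continue
        for trial, th in zip(visible.trials, visible.threshold_db):
            vec = windowed_biomarkers(session, trial, window_frames=window_frames)
            row = {
                "subject_id": session.subject_id,
                "eye": session.eye,
                "trial": trial.trial_index,
                "location_id": trial.location_id,
                "stimulus_db": trial.stimulus_db,
                "threshold_db": th,
                "margin_db": th - trial.stimulus_db,
                "hit": int(trial.responded),
            }
            row.update({name: vec.as_dict()[name] for name in VIDEO_BIOMARKER_NAMES})
            rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    complete = df.dropna(subset=list(VIDEO_BIOMARKER_NAMES))
    dropped = len(df) - len(complete)
    if dropped:
        logger.info("dropped %d visible trial(s) with incomplete biomarkers", dropped)
    return complete.reset_index(drop=True)


@dataclass(frozen=True)
class LapseModelResult:
    """Logistic lapse model for one biomarker plus a binned summary."""

    biomarker: str
    n_trials: int
    intercept: float | None
    slope: float | None
    slope_ci: tuple[float, float] | None
    p_value: float | None
    separation: bool
    bins: pd.DataFrame = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "biomarker": self.biomarker,
            "n_trials": self.n_trials,
            "intercept": self.intercept,
            "slope": self.slope,
            "slope_ci": list(self.slope_ci) if self.slope_ci else None,
            "p_value": self.p_value,
            "separation": self.separation,
            "bins": self.bins.to_dict(orient="records") if self.bins is not None else None,
        }


def _log_spaced_bins(values: np.ndarray, outcomes: np.ndarray, n_bins: int) -> pd.DataFrame:
    """Binned hit rates over log-spaced bins of the positive value range."""
    pos = values > 0
    n_nonpos = int((~pos).sum())
    if n_nonpos:
        logger.info("%d non-positive biomarker value(s) assigned to the first bin", n_nonpos)
    vmin, vmax = values[pos].min(), values[pos].max()
    edges = np.logspace(np.log10(vmin), np.log10(vmax), n_bins + 1)
    idx = np.clip(np.digitize(values, edges[1:-1]), 0, n_bins - 1)
    idx[~pos] = 0
    rows = []
    for b in range(n_bins):
        mask = idx == b
        n = int(mask.sum())
        hits = int(outcomes[mask].sum())
        if n > 0:
            rate = hits / n
            lo, hi = proportion_confint(hits, n, alpha=0.05, method="wilson")
        else:
            rate, lo, hi = np.nan, np.nan, np.nan
        rows.append(
            {
                "bin": b,
                "edge_lo": edges[b],
                "edge_hi": edges[b + 1],
                "n": n,
                "hit_rate": rate,
                "ci_lo": lo,
                "ci_hi": hi,
            }
        )
    return pd.DataFrame(rows)


def fit_lapse_model(table: pd.DataFrame, biomarker: str, n_bins: int = 4) -> LapseModelResult:
    """Logistic regression of hit/miss on one raw biomarker.

    Fits by maximum likelihood, reports the likelihood-ratio
    chi-squared p-value (1 df) against the intercept-only model, and a
    4-bin log-spaced hit-rate summary with Wilson 95% CIs.  Degenerate
    outcomes (an outcome class with < 2 members, or perfect separation)
    yield a flagged result with no p-value.
    """
    if biomarker not in table.columns:
        raise KeyError(biomarker)
    sub = table[[biomarker, "hit"]].dropna()
    x = sub[biomarker].to_numpy(dtype=float)
    y = sub["hit"].to_numpy(dtype=int)
    n = len(sub)
    bins = _log_spaced_bins(x, y, n_bins) if n else None

    def _flagged() -> LapseModelResult:
        return LapseModelResult(biomarker, n, None, None, None, None, True, bins)

    if min((y == 0).sum(), (y == 1).sum()) < 2:
        return _flagged()
    # perfect separation: one class entirely above the other on x
    if max(x[y == 0].min(), x[y == 1].min()) > min(x[y == 0].max(), x[y == 1].max()):
        return _flagged()
    X = sm.add_constant(x)
    try:
        fit = sm.Logit(y, X).fit(disp=0, maxiter=100, tol=1e-8)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        return _flagged()
    if not np.all(np.isfinite(fit.params)):
        return _flagged()
    ci = fit.conf_int()[1]
    return LapseModelResult(
        biomarker=biomarker,
        n_trials=n,
        intercept=float(fit.params[0]),
        slope=float(fit.params[1]),
        slope_ci=(float(ci[0]), float(ci[1])),
        p_value=float(fit.llr_pvalue),
        separation=False,
        bins=bins,
    )
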