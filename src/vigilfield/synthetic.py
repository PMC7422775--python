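"""Synthetic sessions and cohorts with full ground truth.

The generator emulates the statistical structure the analyses assume,
so every pipeline stage can be exercised end to end without real data:

* A latent two-state Markov **compliance process** (attentive/lapsed)
  runs at the frame rate.  Its lapsed-state occupancy is set by a
  subject-level **compliance trait** in [0, 1].
* The 5 Hz **frame stream** draws gaze/head channels as Gaussian jitter
  around subject baselines, with dispersion scales and AU intensity
  means that depend on the latent state (lapsed frames are noisier and
  more expressive); AU emissions are truncated at zero.
* The **trial log** interleaves the 24 grid locations; each location
  runs its own standard ZEST, and responses come from a
  frequency-of-seeing observer whose detections are suppressed with a
  configured probability while lapsed.  Final thresholds are the ZEST
  posterior means, so test-retest MS error emerges mechanistically from
  the lapse process rather than being injected.
* A **cohort** draws one trait per subject; the trait raises both
  expected biomarker magnitudes and expected test-retest error, making
  the composite-error association recoverable by design.

A fast shortcut (``fast_ms_noise_sd``) replaces the ZEST runs with
trait-scaled Gaussian MS noise for cheap unit tests.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .analysis import build_cohort_table
from .io import (
    REQUIRED_AU_KEYS,
    FrameRecord,
    SessionData,
    ThresholdGrid,
    TrialRecord,
    assemble_session,
)
from .zest import PsychometricModel, StoppingRule, ZestConfig, _observe_detail, select_stimulus, zest_update

logger = logging.getLogger(__name__)

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "SubjectTruth",
    "CohortResult",
    "markov_states",
    "stationary_lapse_occupancy",
    "generate_session",
    "generate_cohort",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    Units: seconds, dB, degrees, millimetres, AU arbitrary units.
    The per-frame Markov chain leaves the lapsed state with probability
    ``leave_lapse_prob`` per frame (mean lapse bout 4 s at 5 Hz); the
    entry probability is derived from the trait-dependent stationary
    occupancy ``min + (max - min) * trait``.
    """

    seed: int = 0
    n_subjects: int = 40
    sessions_per_subject: int = 2
    frame_rate: float = 5.0
    trials_per_location: int = 6
    trial_spacing_s: float = 1.8
    trial_spacing_jitter_s: float = 0.3
    response_window_s: float = 1.5
    invalid_frame_prob: float = 0.01

    # true sensitivity
    mean_threshold_db: float = 28.0
    between_subject_threshold_sd: float = 1.0
    between_location_threshold_sd: float = 1.5

    # frequency-of-seeing observer
    fos_sigma_db: float = 1.0
    guess_rate: float = 0.03
    base_lapse_rate: float = 0.03

    # compliance process
    trait_low: float = 0.0
    trait_high: float = 1.0
    min_lapse_occupancy: float = 0.02
    max_lapse_occupancy: float = 0.45
    leave_lapse_prob: float = 0.05
    miss_inflation: float = 0.6

    # emissions: attentive baseline + trait gain; lapsed multiplies/adds
    gaze_sd_base: float = 0.5
    gaze_sd_trait_gain: float = 1.5
    head_loc_sd_base: float = 2.0
    head_loc_sd_trait_gain: float = 6.0
    head_rot_sd_base: float = 0.5
    head_rot_sd_trait_gain: float = 1.5
    lapsed_dispersion_multiplier: float = 3.0
    au_sd: float = 0.25
    sadness_au_base: float = 0.15
    sadness_au_trait_gain: float = 0.6
    surprise_au_base: float = 0.15
    surprise_au_trait_gain: float = 0.6
    blink_au_base: float = 0.3
    blink_au_trait_gain: float = 0.8
    au_lapsed_boost: float = 0.8
    latency_base_s: float = 0.45
    latency_trait_gain_s: float = 0.30
    latency_sd_s: float = 0.10
    latency_lapsed_boost_s: float = 0.25

    # ZEST engine used to estimate thresholds from the generated trials
    zest_domain_lo: float = 0.0
    zest_domain_hi: float = 40.0
    zest_domain_step: float = 0.5

    # shortcut: skip the ZEST runs and inject Gaussian MS noise instead
    fast_ms_noise_sd: float | None = None
    fast_ms_noise_trait_gain: float = 0.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError(f"n_subjects must be >= 1, got {self.n_subjects}")
        if self.sessions_per_subject not in (1, 2):
            raise ValueError("sessions_per_subject must be 1 or 2")
        if not (0 <= self.min_lapse_occupancy <= self.max_lapse_occupancy < 1):
            raise ValueError("lapse occupancies must satisfy 0 <= min <= max < 1")
        if not (0 < self.leave_lapse_prob <= 1):
            raise ValueError("leave_lapse_prob must lie in (0, 1]")
        if not (0 <= self.miss_inflation <= 1):
            raise ValueError("miss_inflation must lie in [0, 1]")
        if self.lapsed_dispersion_multiplier < 1:
            raise ValueError("lapsed dispersion must be >= attentive dispersion")

    def replace(self, **kwargs) -> "GeneratorConfig":
        return dataclasses.replace(self, **kwargs)

    def psychometric_model(self) -> PsychometricModel:
        return PsychometricModel(self.fos_sigma_db, self.guess_rate, self.base_lapse_rate)


@dataclass(frozen=True)
class SubjectTruth:
    subject_id: str
    trait: float
    true_thresholds_db: np.ndarray


@dataclass(frozen=True)
class GroundTruth:
    """Latent variables behind one generated session."""

    trait: float
    true_thresholds_db: np.ndarray
    frame_states: np.ndarray  # 0 attentive, 1 lapsed, per frame
    trial_states: np.ndarray  # per trial, sampled at onset
    forced_miss: np.ndarray  # detection suppressed by a lapse
    visible_trial_count: int  # vs the session's final estimated thresholds


@dataclass(frozen=True)
class CohortResult:
    config: GeneratorConfig
    subjects: tuple[SubjectTruth, ...]
    sessions: dict[str, list[SessionData]]  # keyed by subject_id
    truths: dict[str, list[GroundTruth]]
    table: pd.DataFrame  # one row per eye: biomarkers (averaged), ms1, ms2, error_db, trait

    def all_sessions(self) -> list[SessionData]:
        return [s for key in self.sessions for s in self.sessions[key]]


def stationary_lapse_occupancy(config: GeneratorConfig, trait: float) -> float:
    return config.min_lapse_occupancy + (config.max_lapse_occupancy - config.min_lapse_occupancy) * trait


def _transition_probs(config: GeneratorConfig, trait: float) -> tuple[float, float]:
    """(p_enter, p_leave) for the attentive->lapsed / lapsed->attentive moves."""
    occ = stationary_lapse_occupancy(config, trait)
    p_leave = config.leave_lapse_prob
    p_enter = occ * p_leave / (1.0 - occ) if occ > 0 else 0.0
    return min(p_enter, 1.0), p_leave


def markov_states(n: int, p_enter: float, p_leave: float, rng: np.random.Generator) -> np.ndarray:
    """Simulate the two-state chain; initial state from its stationary law."""
    states = np.zeros(n, dtype=np.int8)
    denom = p_enter + p_leave
    occ = p_enter / denom if denom > 0 else 0.0
    u = rng.random(n)
    state = 1 if u[0] < occ else 0
    states[0] = state
    for i in range(1, n):
        if state == 0:
            state = 1 if u[i] < p_enter else 0
        else:
            state = 0 if u[i] < p_leave else 1
        states[i] = state
    return states


def _trial_schedule(config: GeneratorConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """(onset times, location ids): interleaved rounds over the 24 locations."""
    locations = []
    for _ in range(config.trials_per_location):
        locations.extend(rng.permutation(ThresholdGrid.N_LOCATIONS))
    locations = np.asarray(locations)
    gaps = config.trial_spacing_s + rng.uniform(
        -config.trial_spacing_jitter_s, config.trial_spacing_jitter_s, size=len(locations)
    )
    onsets = np.cumsum(gaps) + 2.0  # testing starts after a short settling period
    return onsets, locations


def _emit_frames(
    config: GeneratorConfig,
    trait: float,
    states: np.ndarray,
    rng: np.random.Generator,
) -> list[FrameRecord]:
    n = len(states)
    lapsed = states.astype(bool)
    mult = np.where(lapsed, config.lapsed_dispersion_multiplier, 1.0)

    gaze_sd = (config.gaze_sd_base + config.gaze_sd_trait_gain * trait) * mult
    head_sd = (config.head_loc_sd_base + config.head_loc_sd_trait_gain * trait) * mult
    rot_sd = (config.head_rot_sd_base + config.head_rot_sd_trait_gain * trait) * mult

    gaze = rng.normal(0.0, 1.0, (n, 2)) * gaze_sd[:, None]
    head = np.array([0.0, 0.0, 600.0]) + rng.normal(0.0, 1.0, (n, 3)) * head_sd[:, None]
    rot = rng.normal(0.0, 1.0, (n, 3)) * rot_sd[:, None]

    boost = np.where(lapsed, config.au_lapsed_boost, 0.0)
    au_means = {
        "AU04": config.sadness_au_base + config.sadness_au_trait_gain * trait + boost,
        "AU15": config.sadness_au_base + config.sadness_au_trait_gain * trait + boost,
        "AU01": config.surprise_au_base + config.surprise_au_trait_gain * trait + boost,
        "AU02": config.surprise_au_base + config.surprise_au_trait_gain * trait + boost,
        "AU25": config.surprise_au_base + config.surprise_au_trait_gain * trait + boost,
        "AU26": config.surprise_au_base + config.surprise_au_trait_gain * trait + boost,
        "AU45": config.blink_au_base + config.blink_au_trait_gain * trait + boost,
    }
    au_draws = {
        k: np.clip(rng.normal(mu, config.au_sd), 0.0, None) for k, mu in au_means.items()
    }
    invalid = rng.random(n) < config.invalid_frame_prob
    confidence = rng.uniform(0.85, 1.0, n)

    frames = []
    dt = 1.0 / config.frame_rate
    for i in range(n):
        valid = not invalid[i]
        frames.append(
            FrameRecord(
                frame_index=i,
                timestamp=i * dt,
                valid=valid,
                confidence=float(confidence[i]) if valid else 0.0,
                gaze_x=float(gaze[i, 0]),
                gaze_y=float(gaze[i, 1]),
                head_x=float(head[i, 0]),
                head_y=float(head[i, 1]),
                head_z=float(head[i, 2]),
                head_yaw=float(rot[i, 0]),
                head_pitch=float(rot[i, 1]),
                head_roll=float(rot[i, 2]),
                au={k: float(au_draws[k][i]) for k in REQUIRED_AU_KEYS},
            )
        )
    return frames


def generate_session(
    config: GeneratorConfig,
    subject: SubjectTruth,
    rng: np.random.Generator,
    eye: str = "OD",
) -> tuple[SessionData, GroundTruth]:
    """Generate one assessment of ``subject``: frames, trials, thresholds.

    Responses drive per-location ZEST states online; the returned
    session's threshold grid holds the final posterior means (or, in
    fast mode, the true thresholds plus injected Gaussian MS noise).
    """
    onsets, locations = _trial_schedule(config, rng)
    duration = onsets[-1] + config.response_window_s + 2.0
    n_frames = int(np.ceil(duration * config.frame_rate)) + 1

    p_enter, p_leave = _transition_probs(config, subject.trait)
    states = markov_states(n_frames, p_enter, p_leave, rng)
    frames = _emit_frames(config, subject.trait, states, rng)

    model = config.psychometric_model()
    domain = np.round(
        np.arange(config.zest_domain_lo, config.zest_domain_hi + config.zest_domain_step / 2, config.zest_domain_step),
        10,
    )
    zest_cfg = ZestConfig(domain=domain, stopping=StoppingRule(max_trials=config.trials_per_location))
    location_states = {loc: zest_cfg.initial_state() for loc in range(ThresholdGrid.N_LOCATIONS)}

    lat_mean_base = config.latency_base_s + config.latency_trait_gain_s * subject.trait
    trials: list[TrialRecord] = []
    trial_states = np.zeros(len(onsets), dtype=np.int8)
    forced_miss = np.zeros(len(onsets), dtype=bool)
    for i, (onset, loc) in enumerate(zip(onsets, locations)):
        frame_idx = min(int(onset * config.frame_rate), n_frames - 1)
        lapsed = bool(states[frame_idx])
        trial_states[i] = int(lapsed)
        if config.fast_ms_noise_sd is None:
            stimulus = select_stimulus(location_states[loc], "posterior_mean")
        else:
            stimulus = float(np.round(subject.true_thresholds_db[loc] + rng.normal(0, 2)) )
        responded, forced = _observe_detail(
            float(subject.true_thresholds_db[loc]), stimulus, model, rng, lapsed, config.miss_inflation
        )
        forced_miss[i] = forced
        latency = None
        if responded:
            mean = lat_mean_base + (config.latency_lapsed_boost_s if lapsed else 0.0)
            latency = float(max(0.05, rng.normal(mean, config.latency_sd_s)))
        if config.fast_ms_noise_sd is None:
            location_states[loc] = zest_update(location_states[loc], stimulus, responded, model, 1.0)
        trials.append(
            TrialRecord(
                trial_index=i,
                location_id=int(loc),
                stimulus_db=float(stimulus),
                onset_time=float(onset),
                responded=responded,
                latency=latency,
            )
        )

    if config.fast_ms_noise_sd is None:
        est = np.array([location_states[loc].mean for loc in range(ThresholdGrid.N_LOCATIONS)])
    else:
        sd = config.fast_ms_noise_sd * (1.0 + config.fast_ms_noise_trait_gain * subject.trait)
        est = subject.true_thresholds_db + rng.normal(0.0, sd, ThresholdGrid.N_LOCATIONS)
    grid = ThresholdGrid.from_db(est)

    session = assemble_session(
        frames,
        trials,
        grid,
        frame_rate=config.frame_rate,
        subject_id=subject.subject_id,
        eye=eye,
    )
    visible = sum(
        1 for t in trials if grid.db_at(t.location_id) - t.stimulus_db > 3.0
    )
    truth = GroundTruth(
        trait=subject.trait,
        true_thresholds_db=subject.true_thresholds_db,
        frame_states=states,
        trial_states=trial_states,
        forced_miss=forced_miss,
        visible_trial_count=visible,
    )
    return session, truth


def generate_cohort(config: GeneratorConfig) -> CohortResult:
    """Generate a cohort of repeat-tested eyes with a per-eye summary table.

    Subject traits are uniform on [trait_low, trait_high].  Randomness
    flows from ``config.seed`` through spawned per-subject/per-session
    substreams, so identical configs reproduce bit-identical cohorts.
    """
    root = np.random.SeedSequence(config.seed)
    subject_seeds = root.spawn(config.n_subjects)
    subjects: list[SubjectTruth] = []
    sessions: dict[str, list[SessionData]] = {}
    truths: dict[str, list[GroundTruth]] = {}
    for j, seq in enumerate(subject_seeds):
        subject_rng = np.random.default_rng(seq)
        trait = float(subject_rng.uniform(config.trait_low, config.trait_high))
        base = config.mean_threshold_db + subject_rng.normal(0, config.between_subject_threshold_sd)
        thresholds = base + subject_rng.normal(
            0, config.between_location_threshold_sd, ThresholdGrid.N_LOCATIONS
        )
        thresholds = np.clip(thresholds, config.zest_domain_lo, config.zest_domain_hi)
        subject = SubjectTruth(subject_id=f"S{j:03d}", trait=trait, true_thresholds_db=thresholds)
        subjects.append(subject)
        sessions[subject.subject_id] = []
        truths[subject.subject_id] = []
        for k, session_seq in enumerate(seq.spawn(config.sessions_per_subject)):
            session_rng = np.random.default_rng(session_seq)
            s, t = generate_session(config, subject, session_rng)
            sessions[subject.subject_id].append(s)
            truths[subject.subject_id].append(t)

    table = build_cohort_table(sessions)
    table["trait"] = [s.trait for s in subjects]
    logger.info(
        "generated cohort: %d subjects x %d session(s), %d trials/session",
        config.n_subjects,
        config.sessions_per_subject,
        ThresholdGrid.N_LOCATIONS * config.trials_per_location,
    )
    return CohortResult(
        config=config,
        subjects=tuple(subjects),
        sessions=sessions,
        truths=truths,
        table=table,
    )
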