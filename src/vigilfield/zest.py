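"""ZEST threshold estimation with per-trial compliance weighting.

ZEST (Zippy Estimation by Sequential Testing) maintains a posterior
probability mass over a discrete grid of candidate thresholds T.  The
observer's detection probability for a stimulus at level s dB is a
cumulative-Gaussian frequency-of-seeing (FOS) curve

    p(seen | T, s) = gamma + (1 - gamma - lapse) * Phi((T - s) / sigma)

with guess rate gamma, (stationary) lapse rate, and spread sigma
(~1 dB at healthy locations).  After each trial the posterior is
multiplied by the response likelihood and renormalized; the next
stimulus is placed at the posterior mean (or at the minimum expected
entropy), and the final estimate is the posterior mean.

Compliance weighting raises each trial's likelihood term to a power
alpha in [0, 1] — the estimated reliability of that response.  alpha=1
is the ordinary Bayes update; alpha=0 discards the trial entirely;
intermediate values give partial credit.  All accumulation happens in
log space, where the weight simply multiplies the log-likelihood.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp, ndtr

__all__ = [
    "PsychometricModel",
    "ZestState",
    "ZestConfig",
    "StoppingRule",
    "StoppingStatus",
    "ComplianceWeight",
    "ZestResult",
    "zest_update",
    "zest_update_batch",
    "select_stimulus",
    "stopping_met",
    "simulate_observer",
    "run_threshold_estimation",
    "alpha_from_compliance",
]


@dataclass(frozen=True)
class PsychometricModel:
    """Cumulative-Gaussian frequency-of-seeing curve."""

    sigma: float = 1.0
    guess_rate: float = 0.03
    lapse_rate: float = 0.03

    def __post_init__(self) -> None:
        if not (self.sigma > 0):
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if not (0 <= self.guess_rate < 1 and 0 <= self.lapse_rate < 1):
            raise ValueError("guess and lapse rates must lie in [0, 1)")
        if self.guess_rate + self.lapse_rate >= 1:
            raise ValueError("guess_rate + lapse_rate must be < 1")

    def p_seen(self, threshold, stimulus):
        """Detection probability; broadcasts over thresholds and stimuli."""
        threshold = np.asarray(threshold, dtype=float)
        return self.guess_rate + (1.0 - self.guess_rate - self.lapse_rate) * ndtr(
            (threshold - stimulus) / self.sigma
        )


@dataclass(frozen=True)
class ComplianceWeight:
    """A per-trial likelihood weight alpha in [0, 1] and its source estimate."""

    alpha: float
    theta: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")


@dataclass(frozen=True)
class ZestState:
    """Posterior mass over a discrete threshold domain, kept in log space."""

    domain: np.ndarray
    log_posterior: np.ndarray
    history: tuple[tuple[float, bool, float], ...] = ()  # (stimulus, responded, alpha)

    @classmethod
    def from_prior(cls, domain: Sequence[float], prior: Sequence[float] | None = None) -> "ZestState":
        domain = np.asarray(domain, dtype=float)
        if prior is None:
            lp = np.zeros_like(domain)
        else:
            prior = np.asarray(prior, dtype=float)
            if prior.shape != domain.shape:
                raise ValueError("prior and domain shapes differ")
            if np.any(prior < 0) or prior.sum() <= 0:
                raise ValueError("prior must be non-negative with positive mass")
            with np.errstate(divide="ignore"):
                lp = np.log(prior)
        lp = lp - logsumexp(lp)
        return cls(domain=domain, log_posterior=lp)

    @property
    def posterior(self) -> np.ndarray:
        return np.exp(self.log_posterior)

    @property
    def mean(self) -> float:
        return float(np.sum(self.domain * self.posterior))

    @property
    def mode(self) -> float:
        return float(self.domain[int(np.argmax(self.log_posterior))])

    @property
    def sd(self) -> float:
        p = self.posterior
        mu = np.sum(self.domain * p)
        return float(np.sqrt(np.sum(p * (self.domain - mu) ** 2)))

    @property
    def entropy(self) -> float:
        """Shannon entropy of the posterior, in nats."""
        p = self.posterior
        nz = p > 0
        return float(-np.sum(p[nz] * np.log(p[nz])))

    @property
    def n_trials(self) -> int:
        return len(self.history)


def _log_likelihood(model: PsychometricModel, domain: np.ndarray, stimulus: float, responded: bool) -> np.ndarray:
    p = model.p_seen(domain, stimulus)
    with np.errstate(divide="ignore"):
        return np.log(p) if responded else np.log1p(-p)


def _as_alpha(alpha: float | ComplianceWeight) -> float:
    a = alpha.alpha if isinstance(alpha, ComplianceWeight) else float(alpha)
    if not (0.0 <= a <= 1.0):
        raise ValueError(f"alpha must lie in [0, 1], got {a}")
    return a


def zest_update(
    state: ZestState,
    stimulus: float,
    responded: bool,
    model: PsychometricModel,
    alpha: float | ComplianceWeight = 1.0,
) -> ZestState:
    """One compliance-weighted Bayes update, returning a new state.

    The posterior becomes proportional to ``prior * p(r | s, T)**alpha``.
    With alpha=1 this is the ordinary ZEST update; with alpha=0 the
    posterior is unchanged and only the history grows.
    """
    a = _as_alpha(alpha)
    if a == 0.0:  # zero weight: posterior untouched (and no 0 * -inf)
        return replace(
            state, history=state.history + ((float(stimulus), bool(responded), 0.0),)
        )
    lp = state.log_posterior + a * _log_likelihood(model, state.domain, stimulus, responded)
    norm = logsumexp(lp)
    if not np.isfinite(norm):
        raise FloatingPointError(
            "posterior mass vanished after update; domain does not cover the data"
        )
    return replace(
        state,
        log_posterior=lp - norm,
        history=state.history + ((float(stimulus), bool(responded), a),),
    )


def zest_update_batch(
    state: ZestState,
    stimuli: Sequence[float],
    responses: Sequence[bool],
    model: PsychometricModel,
    alphas: Sequence[float] | None = None,
) -> ZestState:
    """Apply a whole trial history in one normalization.

    The weighted likelihood factorizes over trials, so this equals the
    sequential application of :func:`zest_update` (to rounding).
    """
    if alphas is None:
        alphas = [1.0] * len(stimuli)
    lp = state.log_posterior.copy()
    hist = list(state.history)
    for s, r, a in zip(stimuli, responses, alphas):
        a = _as_alpha(a)
        if a > 0.0:
            lp = lp + a * _log_likelihood(model, state.domain, s, r)
        hist.append((float(s), bool(r), a))
    norm = logsumexp(lp)
    if not np.isfinite(norm):
        raise FloatingPointError("posterior mass vanished in batch update")
    return replace(state, log_posterior=lp - norm, history=tuple(hist))


def select_stimulus(state: ZestState, rule: str = "posterior_mean", model: PsychometricModel | None = None) -> float:
    """Next stimulus level, snapped to the domain grid.

    ``posterior_mean`` is the classic ZEST placement.  ``min_entropy``
    sweeps the domain and picks the level minimizing the expected
    posterior entropy after the next response (requires ``model``).
    """
    if rule == "posterior_mean":
        target = state.mean
        return float(state.domain[int(np.argmin(np.abs(state.domain - target)))])
    if rule == "min_entropy":
        if model is None:
            raise ValueError("min_entropy placement requires a psychometric model")
        best, best_h = None, np.inf
        post = state.posterior
        for s in state.domain:
            p_seen_each = model.p_seen(state.domain, s)
            p_resp = float(np.sum(post * p_seen_each))
            h = 0.0
            for resp, pr in ((True, p_resp), (False, 1.0 - p_resp)):
                if pr <= 0:
                    continue
                w = post * (p_seen_each if resp else 1.0 - p_seen_each)
                w_sum = w.sum()
                if w_sum <= 0:
                    continue
                w = w / w_sum
                nz = w > 0
                h += pr * float(-np.sum(w[nz] * np.log(w[nz])))
            if h < best_h:
                best, best_h = float(s), h
        return best
    raise ValueError(f"unknown placement rule {rule!r}")


@dataclass(frozen=True)
class StoppingRule:
    """Stop on posterior SD, posterior entropy, and/or a trial budget."""

    max_trials: int | None = None
    sd_threshold: float | None = None
    entropy_threshold: float | None = None


@dataclass(frozen=True)
class StoppingStatus:
    stop: bool
    did_not_complete: bool = False

    def __bool__(self) -> bool:
        return self.stop


def stopping_met(state: ZestState, rule: StoppingRule) -> StoppingStatus:
    """Whether testing should stop, flagging 'did not complete'.

    The flag is set when the trial budget is exhausted while a
    certainty criterion (SD or entropy) remains unmet — the outcome a
    conspicuously non-compliant observer would be scored with.
    """
    certain = True
    any_certainty = False
    if rule.sd_threshold is not None:
        any_certainty = True
        certain = certain and state.sd <= rule.sd_threshold
    if rule.entropy_threshold is not None:
        any_certainty = True
        certain = certain and state.entropy <= rule.entropy_threshold
    if any_certainty and certain:
        return StoppingStatus(stop=True)
    if rule.max_trials is not None and state.n_trials >= rule.max_trials:
        return StoppingStatus(stop=True, did_not_complete=any_certainty)
    return StoppingStatus(stop=False)


def simulate_observer(
    truth: float,
    stimulus: float,
    model: PsychometricModel,
    rng: np.random.Generator,
    lapsed: bool = False,
    lapse_inflation: float = 1.0,
) -> bool:
    """Draw one response from a frequency-of-seeing observer.

    While ``lapsed``, a detection is suppressed (turned into a miss)
    with probability ``lapse_inflation`` on top of the stationary lapse
    rate of the model.
    """
    responded, _ = _observe_detail(truth, stimulus, model, rng, lapsed, lapse_inflation)
    return responded


def _observe_detail(
    truth: float,
    stimulus: float,
    model: PsychometricModel,
    rng: np.random.Generator,
    lapsed: bool,
    lapse_inflation: float,
) -> tuple[bool, bool]:
    """(responded, forced_miss): forced_miss marks a lapse-suppressed detection."""
    seen = bool(rng.random() < float(model.p_seen(truth, stimulus)))
    if seen and lapsed and rng.random() < lapse_inflation:
        return False, True
    return seen, False


def default_domain(lo: float = 0.0, hi: float = 40.0, step: float = 0.5) -> np.ndarray:
    return np.round(np.arange(lo, hi + step / 2, step), 10)


@dataclass(frozen=True)
class ZestConfig:
    """Everything a threshold run needs besides the observer."""

    domain: np.ndarray = field(default_factory=default_domain)
    prior: np.ndarray | None = None
    placement: str = "posterior_mean"
    stopping: StoppingRule = field(default_factory=lambda: StoppingRule(max_trials=30))
    estimator: str = "mean"  # or "mode"

    def initial_state(self) -> ZestState:
        return ZestState.from_prior(self.domain, self.prior)


@dataclass(frozen=True)
class ZestResult:
    estimate: float
    state: ZestState
    trace: pd.DataFrame
    did_not_complete: bool


def run_threshold_estimation(
    truth: float,
    model: PsychometricModel,
    config: ZestConfig,
    rng: np.random.Generator,
    alpha_stream: Iterable[float | ComplianceWeight] | None = None,
    lapse_stream: Iterable[bool] | None = None,
    lapse_inflation: float = 1.0,
) -> ZestResult:
    """Run a full simulated threshold estimation against one observer.

    ``alpha_stream`` yields the compliance weight applied to each trial
    (default: all ones, i.e. standard ZEST).  ``lapse_stream`` yields
    the observer's latent lapsed flag per trial; while lapsed,
    detections are suppressed with probability ``lapse_inflation``.
    """
    state = config.initial_state()
    alphas: Iterator = iter(alpha_stream) if alpha_stream is not None else iter(())
    lapses: Iterator = iter(lapse_stream) if lapse_stream is not None else iter(())
    rows = []
    status = stopping_met(state, config.stopping)
    while not status.stop:
        stimulus = select_stimulus(state, config.placement, model)
        lapsed = bool(next(lapses, False))
        responded = simulate_observer(truth, stimulus, model, rng, lapsed, lapse_inflation)
        alpha = _as_alpha(next(alphas, 1.0))
        state = zest_update(state, stimulus, responded, model, alpha)
        rows.append(
            {
                "trial": state.n_trials,
                "stimulus_db": stimulus,
                "responded": responded,
                "alpha": alpha,
                "lapsed": lapsed,
                "posterior_mean": state.mean,
                "posterior_sd": state.sd,
            }
        )
        status = stopping_met(state, config.stopping)
    estimate = state.mean if config.estimator == "mean" else state.mode
    return ZestResult(
        estimate=float(estimate),
        state=state,
        trace=pd.DataFrame(rows),
        did_not_complete=status.did_not_complete,
    )


def alpha_from_compliance(theta: float, k: float = 2.0, theta0: float = 1.5) -> ComplianceWeight:
    """Map a compliance estimate (e.g. composite z-score) to a weight.

    Logistic in theta: alpha = 1 / (1 + exp(k * (theta - theta0))),
    monotone non-increasing, 0.5 at theta0, approaching 1 for strongly
    compliant (very negative) estimates.  k > 0 sets the steepness.
    """
    if not np.isfinite(theta):
        raise ValueError(f"theta must be finite, got {theta}")
    if not (k > 0):
        raise ValueError(f"k must be > 0, got {k}")
    with np.errstate(over="ignore"):
        a = 1.0 / (1.0 + np.exp(k * (float(theta) - theta0)))
    return ComplianceWeight(alpha=float(np.clip(a, 0.0, 1.0)), theta=float(theta))
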