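"""Bayesian adaptive staircase (QUEST) and two-stage stimulus individualization.

QUEST maintains a discrete posterior over candidate thresholds of a Weibull
psychometric function and places each trial at the current posterior
estimate.  The individualization procedure is the standard two-stage design
for SFG figure detection: stage 1 adapts the figure coherence level at a
fixed total of 20 tones per chord until detection accuracy reaches ~85%
(the low-noise operating point); stage 2 keeps that coherence and adds
background tones until accuracy drops to ~65% (high-noise).  Both stages
run one block of 80 trials, extended in blocks of 20 while the posterior
standard deviation exceeds the median spacing of the admissible stimulus
levels.

Published SFG experiments rarely document their exact staircase constants;
the defaults here (Weibull slope 3.5, guess rate 0.2, lapse 0.02) are
standard yes/no QUEST settings and are fully configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidParameterError, UndefinedStatisticError
from .stimulus import ToneCloudSpec, TONES_PER_CHORD

__all__ = [
    "PsychometricParams",
    "QuestState",
    "StaircaseConfig",
    "IndividualizedParams",
    "weibull_p_yes",
    "quest_init",
    "quest_update",
    "quest_recommend",
    "quest_sd",
    "run_stage1_coherence",
    "run_stage2_background",
    "snr_metrics",
    "individualize",
]


@dataclass(frozen=True)
class PsychometricParams:
    """Weibull psychometric function for a yes/no detection task.

    ``threshold`` is the intensity at which p(yes) equals ``target_p``.
    With ``log_domain=False`` the intensity axis is linear and positive
    (e.g. coherence level, SNR); with ``log_domain=True`` intensities are
    log-transformed (e.g. log-SNR) and the function is the same Weibull
    expressed in the log domain (a Gumbel).
    """

    threshold: float
    slope: float = 3.5
    guess: float = 0.2
    lapse: float = 0.02
    target_p: float = 0.85
    log_domain: bool = False

    def __post_init__(self):
        if not (0 <= self.guess < self.target_p < 1 - self.lapse <= 1):
            raise InvalidParameterError(
                "need 0 <= guess < target_p < 1 - lapse <= 1")
        if self.slope <= 0:
            raise InvalidParameterError("slope must be positive")

    @property
    def _k(self) -> float:
        """Scale constant pinning p(threshold) = target_p."""
        frac = (self.target_p - self.guess) / (1 - self.guess - self.lapse)
        return (-math.log1p(-frac)) ** (1.0 / self.slope)


def weibull_p_yes(intensity, params: PsychometricParams,
                  threshold=None) -> np.ndarray | float:
    """p(yes) at `intensity` for a Weibull observer/likelihood.

    `threshold` overrides ``params.threshold`` (vectorized over candidate
    thresholds for posterior updates).
    """
    thr = params.threshold if threshold is None else threshold
    x = np.asarray(intensity, dtype=float)
    thr = np.asarray(thr, dtype=float)
    if params.log_domain:
        ratio = np.exp(x - thr)
    else:
        ratio = np.divide(x, thr, out=np.zeros(np.broadcast_shapes(x.shape, thr.shape)),
                          where=thr > 0)
        ratio = np.where(x <= 0, 0.0, ratio)
    p = params.guess + (1 - params.guess - params.lapse) * (
        1.0 - np.exp(-((params._k * ratio) ** params.slope)))
    if np.ndim(p) == 0:
        return float(p)
    return p


@dataclass
class QuestState:
    grid: np.ndarray            # ordered candidate thresholds
    posterior: np.ndarray       # probability mass, sums to 1
    params: PsychometricParams  # threshold field unused (grid supplies it)
    history: list = field(default_factory=list)  # (intensity, response)

    def copy(self) -> "QuestState":
        return QuestState(grid=self.grid, posterior=self.posterior.copy(),
                          params=self.params, history=list(self.history))


def quest_init(params: PsychometricParams, prior_mean: float, prior_sd: float,
               grid_range: tuple[float, float], grid_grain: float) -> QuestState:
    """Posterior initialized to a discretized Gaussian prior."""
    if grid_grain <= 0:
        raise InvalidParameterError("grid grain must be positive")
    lo, hi = grid_range
    if hi <= lo:
        raise InvalidParameterError("empty threshold grid range")
    if prior_sd <= 0:
        raise InvalidParameterError("prior sd must be positive")
    grid = np.arange(lo, hi + 0.5 * grid_grain, grid_grain)
    if grid.size == 0:
        raise InvalidParameterError("empty threshold grid")
    log_prior = -0.5 * ((grid - prior_mean) / prior_sd) ** 2
    post = np.exp(log_prior - log_prior.max())
    post /= post.sum()
    return QuestState(grid=grid, posterior=post, params=params)


def quest_update(state: QuestState, intensity: float, response: bool) -> QuestState:
    """Bayes update of the threshold posterior after one trial."""
    if not np.isfinite(intensity):
        raise InvalidParameterError("intensity must be finite")
    p_yes = weibull_p_yes(intensity, state.params, threshold=state.grid)
    like = p_yes if response else 1.0 - p_yes
    post = state.posterior * like
    total = post.sum()
    if total <= 0:  # numerically impossible history; fall back to likelihood
        post = np.asarray(like, dtype=float)
        total = post.sum()
    post = post / total
    new = state.copy()
    new.posterior = post
    new.history.append((float(intensity), bool(response)))
    return new


def quest_recommend(state: QuestState, rule: str = "mean",
                    quantile: float = 0.5) -> float:
    """Next-trial intensity: posterior mean (default), mode, or quantile."""
    if rule == "mean":
        return float(np.sum(state.grid * state.posterior))
    if rule == "mode":
        return float(state.grid[int(np.argmax(state.posterior))])
    if rule == "quantile":
        cdf = np.cumsum(state.posterior)
        return float(state.grid[int(np.searchsorted(cdf, quantile))])
    raise InvalidParameterError(f"unknown placement rule {rule!r}")


def quest_mean(state: QuestState) -> float:
    return float(np.sum(state.grid * state.posterior))


def quest_sd(state: QuestState) -> float:
    m = quest_mean(state)
    var = float(np.sum((state.grid - m) ** 2 * state.posterior))
    return math.sqrt(max(var, 0.0))


@dataclass(frozen=True)
class StaircaseConfig:
    base_trials: int = 80
    extension_block: int = 20
    max_trials: int = 200
    placement: str = "mean"
    track: str = "hit"  # "hit": staircase tracks p(yes | figure)
    total_tones: int = TONES_PER_CHORD
    coherence_bounds: tuple[int, int] = (2, 18)
    max_added_background: int = 40
    slope: float = 3.5
    guess: float = 0.2
    lapse: float = 0.02

    def __post_init__(self):
        if self.base_trials <= 0:
            raise InvalidParameterError("base_trials must be positive")
        if self.max_trials < self.base_trials:
            raise InvalidParameterError("max_trials must be >= base_trials")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class StaircaseResult:
    estimate: float            # posterior mean on the staircase's intensity axis
    value: int                 # integer stimulus parameter (coherence / added tones)
    n_trials: int
    converged: bool            # posterior SD <= median admissible step at stop
    state: QuestState
    log: list                  # per-trial dicts


def _run_staircase(present_trial, intensity_for_value, value_from_estimate,
                   quest_state, cfg: StaircaseConfig, median_step: float,
                   rng: np.random.Generator, stage: str) -> StaircaseResult:
    """Shared staircase loop.

    `present_trial(value, figure, rng) -> bool` runs one trial and returns
    the observer's yes/no; `intensity_for_value` maps the integer stimulus
    value to the staircase's intensity axis; `value_from_estimate` maps a
    posterior estimate back to an integer stimulus value.
    """
    state = quest_state
    log = []
    n = 0
    budget = cfg.base_trials
    while True:
        while n < budget:
            est = quest_recommend(state, cfg.placement)
            value = value_from_estimate(est)
            x = intensity_for_value(value)
            figure = bool(rng.random() < 0.5)
            response = bool(present_trial(value, figure, rng))
            if figure:  # catch trials carry no threshold information
                state = quest_update(state, x, response)
            n += 1
            log.append({"trial": n, "stage": stage, "intensity": x,
                        "value": value, "figure": figure, "response": response,
                        "posterior_mean": quest_mean(state),
                        "posterior_sd": quest_sd(state)})
        if quest_sd(state) <= median_step or budget >= cfg.max_trials:
            break
        budget = min(budget + cfg.extension_block, cfg.max_trials)
    est = quest_mean(state)
    return StaircaseResult(estimate=est, value=value_from_estimate(est),
                           n_trials=n, converged=quest_sd(state) <= median_step,
                           state=state, log=log)


def run_stage1_coherence(observer, cfg: StaircaseConfig,
                         rng: np.random.Generator,
                         prior_mean: float = 10.0, prior_sd: float = 4.0
                         ) -> StaircaseResult:
    """Adapt figure coherence toward ~85% hits at 20 tones per chord.

    The staircase intensity axis is the coherence level itself; the
    admissible levels are the integers in ``cfg.coherence_bounds``, so the
    median successive step for the stopping rule is 1.
    """
    lo, hi = cfg.coherence_bounds
    params = PsychometricParams(threshold=1.0, slope=cfg.slope, guess=cfg.guess,
                                lapse=cfg.lapse, target_p=0.85, log_domain=False)
    state = quest_init(params, prior_mean, prior_sd,
                       grid_range=(max(lo - 1, 0.5), hi + 1), grid_grain=0.05)

    def value_from_estimate(est: float) -> int:
        return int(np.clip(_round_half_up(est), lo, hi))

    def present_trial(value, figure, rng):
        spec = ToneCloudSpec(has_figure=figure,
                             coherence=value if figure else 0,
                             n_background=(cfg.total_tones - value if figure
                                           else cfg.total_tones))
        yes, _rt = observer.respond(spec, rng)
        return yes

    return _run_staircase(present_trial, lambda v: float(v),
                          value_from_estimate, state, cfg,
                          median_step=1.0, rng=rng, stage="coherence")


def run_stage2_background(observer, coherence_ln: int, cfg: StaircaseConfig,
                          rng: np.random.Generator,
                          prior_sd: float = 0.6) -> StaircaseResult:
    """Add background tones at fixed coherence toward ~65% hits.

    The staircase operates on log-SNR, SNR being the figure:background tone
    ratio.  The returned ``value`` is the integer count of *added*
    background tones relative to the low-noise stimulus.
    """
    c = int(coherence_ln)
    b0 = cfg.total_tones - c
    if b0 <= 0:
        raise InvalidParameterError("stage 2 needs at least one background tone")
    added_levels = np.arange(0, cfg.max_added_background + 1)
    log_snr_levels = np.log(c / (b0 + added_levels))
    median_step = float(np.median(np.abs(np.diff(log_snr_levels))))

    params = PsychometricParams(threshold=0.0, slope=cfg.slope, guess=cfg.guess,
                                lapse=cfg.lapse, target_p=0.65, log_domain=True)
    grid_lo = float(log_snr_levels.min() - 0.5)
    grid_hi = float(log_snr_levels.max() + 0.5)
    prior_mean = float(np.log(c / b0) - 0.3)
    state = quest_init(params, prior_mean, prior_sd,
                       grid_range=(grid_lo, grid_hi), grid_grain=0.01)

    def value_from_estimate(est: float) -> int:
        added = _round_half_up(c / math.exp(est)) - b0
        return int(np.clip(added, 0, cfg.max_added_background))

    def intensity_for_value(added: int) -> float:
        return float(np.log(c / (b0 + added)))

    def present_trial(added, figure, rng):
        spec = ToneCloudSpec(has_figure=figure,
                             coherence=c if figure else 0,
                             n_background=(b0 + added if figure
                                           else cfg.total_tones + added))
        yes, _rt = observer.respond(spec, rng)
        return yes

    return _run_staircase(present_trial, intensity_for_value,
                          value_from_estimate, state, cfg,
                          median_step=median_step, rng=rng, stage="background")


def snr_metrics(coherence: int, n_background: int) -> tuple[float, float]:
    """SNR = figure:background tone-count ratio, and its natural log."""
    if n_background <= 0:
        raise UndefinedStatisticError("SNR undefined with zero background tones")
    snr = coherence / n_background
    return snr, math.log(snr)


@dataclass
class IndividualizedParams:
    """Per-listener stimulus parameters produced by the two-stage procedure."""

    coherence_LN: int
    n_background_LN: int
    n_added_HN: int
    n_background_HN: int
    SNR_LN: float
    SNR_HN: float
    log_SNR_LN: float
    log_SNR_HN: float
    stage1_trials: int
    stage2_trials: int
    stage1_converged: bool
    stage2_converged: bool

    def to_json_dict(self) -> dict:
        return dict(self.__dict__)


def individualize(observer, cfg: StaircaseConfig,
                  rng: np.random.Generator) -> IndividualizedParams:
    """Run both staircases and derive the LN/HN stimulus parameters."""
    s1 = run_stage1_coherence(observer, cfg, rng)
    c = s1.value
    s2 = run_stage2_background(observer, c, cfg, rng)
    b_ln = cfg.total_tones - c
    b_hn = b_ln + s2.value
    snr_ln, log_ln = snr_metrics(c, b_ln)
    snr_hn, log_hn = snr_metrics(c, b_hn)
    return IndividualizedParams(
        coherence_LN=c, n_background_LN=b_ln, n_added_HN=s2.value,
        n_background_HN=b_hn, SNR_LN=snr_ln, SNR_HN=snr_hn,
        log_SNR_LN=log_ln, log_SNR_HN=log_hn,
        stage1_trials=s1.n_trials, stage2_trials=s2.n_trials,
        stage1_converged=s1.converged, stage2_converged=s2.converged)
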