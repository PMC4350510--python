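"""Behavioral agents: scripted responders and the drifting-criterion learner.

The learner is a signal-detection observer whose decision threshold drifts
with reward: on each trial it draws a noisy percept of the stimulus length,
answers by comparing the percept with its current decision criterion, and —
whenever a response is rewarded — shifts the criterion so as to make that
response more likely.  Perceptual noise and criterion drift are independent
knobs, so the agent can show genotype-graded reward responsiveness (bias)
with identical discriminability, which is exactly the dissociation the
analysis pipeline is designed to detect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .task import LONG, SHORT, TrialPlan


@dataclass(frozen=True)
class AgentParams:
    """Generative parameters of one simulated participant.

    perceptual_sensitivity
        True discriminability in d′ units; percept noise SD is its inverse.
    reward_learning_rate
        Criterion shift (decision-axis units) applied after each reward.
    criterion_start
        Initial decision threshold on the decision axis (0 = unbiased).
    criterion_decay
        Per-trial relaxation of the criterion back toward its start value
        (0 = no forgetting, the default).
    rt_log_mean, rt_log_sd
        Log-scale parameters of the lognormal reaction-time distribution
        (milliseconds).
    fast_guess_rate, lapse_rate
        Probabilities of replacing the reaction time by an anticipatory
        (<200 ms) or lapse (>3000 ms) value, to exercise the trial filter.
    """

    perceptual_sensitivity: float = 1.7
    reward_learning_rate: float = 0.0
    criterion_start: float = 0.0
    criterion_decay: float = 0.0
    rt_log_mean: float = 6.40  # exp(6.40) ~ 600 ms median
    rt_log_sd: float = 0.35
    fast_guess_rate: float = 0.02
    lapse_rate: float = 0.02

    def __post_init__(self) -> None:
        if self.perceptual_sensitivity <= 0:
            raise ValueError("perceptual_sensitivity must be positive")
        for name in ("criterion_decay", "fast_guess_rate", "lapse_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.fast_guess_rate + self.lapse_rate > 1.0:
            raise ValueError("fast_guess_rate + lapse_rate must not exceed 1")


# Stimulus means on the decision axis; with percept noise SD = 1/sensitivity,
# the observer's true d' equals perceptual_sensitivity exactly.
_STIM_MEAN = {SHORT: -0.5, LONG: +0.5}


class CriterionLearner:
    """Signal-detection observer with reward-driven criterion drift.

    Responds LONG whenever the noisy percept exceeds the current criterion.
    A reward delivered after responding LONG lowers the criterion (making
    LONG more likely next time); after responding SHORT it raises it.
    """

    def __init__(self, params: AgentParams, rng: np.random.Generator):
        self.params = params
        self.rng = rng
        self.criterion = params.criterion_start
        self._last_response: str | None = None

    def respond(self, plan: TrialPlan) -> tuple[str, float]:
        p = self.params
        percept = _STIM_MEAN[plan.stimulus] + self.rng.normal(0.0, 1.0 / p.perceptual_sensitivity)
        response = LONG if percept > self.criterion else SHORT
        self._last_response = response
        u = self.rng.random()
        if u < p.fast_guess_rate:
            rt = self.rng.uniform(50.0, 195.0)
        elif u < p.fast_guess_rate + p.lapse_rate:
            rt = self.rng.uniform(3050.0, 5000.0)
        else:
            rt = float(np.exp(self.rng.normal(p.rt_log_mean, p.rt_log_sd)))
        return response, rt

    def feedback(self, plan: TrialPlan, rewarded: bool) -> None:
        p = self.params
        if rewarded and self._last_response is not None:
            if self._last_response == LONG:
                self.criterion -= p.reward_learning_rate
            else:
                self.criterion += p.reward_learning_rate
        if p.criterion_decay:
            self.criterion += p.criterion_decay * (p.criterion_start - self.criterion)


class AlwaysCorrectResponder:
    """Answers every trial correctly with a fixed in-range reaction time."""

    def __init__(self, rt_ms: float = 600.0):
        self.rt_ms = rt_ms

    def respond(self, plan: TrialPlan) -> tuple[str, float]:
        return plan.stimulus, self.rt_ms

    def feedback(self, plan: TrialPlan, rewarded: bool) -> None:
        pass


class AlwaysIncorrectResponder:
    """Answers every trial incorrectly; never receives feedback."""

    def __init__(self, rt_ms: float = 600.0):
        self.rt_ms = rt_ms

    def respond(self, plan: TrialPlan) -> tuple[str, float]:
        return LONG if plan.stimulus == SHORT else SHORT, self.rt_ms

    def feedback(self, plan: TrialPlan, rewarded: bool) -> None:
        pass


class ScriptedResponder:
    """Replays a fixed list of (response, rt_ms) pairs, in trial order."""

    def __init__(self, script: list[tuple[str, float]]):
        self.script = list(script)
        self._i = 0
        self.feedback_log: list[bool] = []

    def respond(self, plan: TrialPlan) -> tuple[str, float]:
        response, rt = self.script[self._i]
        self._i += 1
        return response, rt

    def feedback(self, plan: TrialPlan, rewarded: bool) -> None:
        self.feedback_log.append(rewarded)
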