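"""Probabilistic reward task: reinforcement schedules and the session engine.

The task is a two-alternative line-length discrimination with asymmetric
reinforcement.  A session consists of ``n_blocks`` blocks of
``trials_per_block`` trials.  Within each block the two stimuli appear
equally often in pseudo-random order (no more than ``max_stimulus_run``
identical stimuli in a row), and a fixed number of correct responses are
scheduled for monetary reward — most on the "rich" stimulus, the rest on
the "lean" one — with no more than ``max_reward_run`` scheduled rewards on
consecutive trials.  A reward scheduled on a trial answered incorrectly is
postponed: it is delivered on a later correct, otherwise-unreinforced trial
of the same stimulus.  Feedback never follows an incorrect response.

Trials with reaction times outside [200, 3000] ms are removed before
scoring, and participants earning less than a fixed bonus threshold are
excluded from analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Protocol, Sequence

import numpy as np
import pandas as pd

SHORT = "short"
LONG = "long"
STIMULI = (SHORT, LONG)

#: Reaction-time validity window, in milliseconds (boundaries included).
RT_MIN_MS = 200.0
RT_MAX_MS = 3000.0

#: Minimum session earnings (GBP) for inclusion in the analysis.
INCLUSION_THRESHOLD_GBP = 5.00


class ScheduleError(ValueError):
    """Raised when a schedule configuration is invalid or unsatisfiable."""


class ResponderError(ValueError):
    """Raised when a responder violates the response-provider contract."""


class Responder(Protocol):
    """Contract for anything that can play the task.

    ``respond`` maps a :class:`TrialPlan` to a ``(response, rt_ms)`` pair;
    ``feedback`` is called after every trial with the plan and whether a
    reward was delivered, so learning agents can update internal state.
    """

    def respond(self, plan: "TrialPlan") -> tuple[str, float]: ...

    def feedback(self, plan: "TrialPlan", rewarded: bool) -> None: ...


@dataclass(frozen=True)
class ScheduleConfig:
    """Design constants of one session.

    Defaults reproduce the standard design: 3 blocks of 100 trials, 40
    scheduled rewards per block split 30 (rich) / 10 (lean), runs capped at
    4 identical stimuli and 3 consecutive scheduled rewards, 5 pence per
    reward.  Display timings are stored as metadata only.
    """

    n_blocks: int = 3
    trials_per_block: int = 100
    rewards_per_block: int = 40
    rich_rewards_per_block: int = 30
    lean_rewards_per_block: int = 10
    max_stimulus_run: int = 4
    max_reward_run: int = 3
    rich_stimulus: str = LONG
    reward_value: float = 0.05
    rng_seed: int = 0
    # metadata only; not used in any computation
    fixation_ms: int = 500
    stimulus_ms: int = 100
    feedback_ms: int = 1750

    def __post_init__(self) -> None:
        if self.rich_stimulus not in STIMULI:
            raise ScheduleError(f"rich_stimulus must be one of {STIMULI}")
        if self.trials_per_block % 2 != 0:
            raise ScheduleError("trials_per_block must be even (equal stimulus frequency)")
        if self.rich_rewards_per_block + self.lean_rewards_per_block != self.rewards_per_block:
            raise ScheduleError("rich + lean rewards must equal rewards_per_block")
        half = self.trials_per_block // 2
        if self.rich_rewards_per_block > half or self.lean_rewards_per_block > half:
            raise ScheduleError("per-stimulus reward count exceeds trials of that stimulus")
        if self.rewards_per_block > self.trials_per_block:
            raise ScheduleError("more rewards than trials in a block")
        if min(self.n_blocks, self.trials_per_block, self.max_stimulus_run, self.max_reward_run) < 1:
            raise ScheduleError("counts and run caps must be positive")
        # Feasibility of the run caps: r items with no run > m interleaved with
        # g other items need r <= m * (g + 1).
        if half > self.max_stimulus_run * (half + 1):
            raise ScheduleError("max_stimulus_run unsatisfiable for this trial count")
        gaps = self.trials_per_block - self.rewards_per_block
        if self.rewards_per_block > self.max_reward_run * (gaps + 1):
            raise ScheduleError("max_reward_run unsatisfiable for this reward count")

    @property
    def lean_stimulus(self) -> str:
        return LONG if self.rich_stimulus == SHORT else SHORT

    @property
    def max_earnings(self) -> float:
        return round(self.n_blocks * self.rewards_per_block * self.reward_value, 2)


@dataclass(frozen=True)
class TrialPlan:
    """One planned trial: block (1-based), trial index within block (1-based),
    stimulus identity, whether that stimulus is the rich one, and whether a
    reward is scheduled for a correct response."""

    block: int
    trial: int
    stimulus: str
    is_rich: bool
    scheduled_reward: bool


@dataclass(frozen=True)
class Schedule:
    config: ScheduleConfig
    trials: tuple[TrialPlan, ...]

    def block_trials(self, block: int) -> tuple[TrialPlan, ...]:
        return tuple(t for t in self.trials if t.block == block)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "block": [t.block for t in self.trials],
                "trial": [t.trial for t in self.trials],
                "stimulus": [t.stimulus for t in self.trials],
                "is_rich": [t.is_rich for t in self.trials],
                "scheduled_reward": [t.scheduled_reward for t in self.trials],
            }
        )


@dataclass(frozen=True)
class TrialOutcome:
    plan: TrialPlan
    response: str
    correct: bool
    rt_ms: float
    rewarded: bool
    reward_postponed: bool
    valid: bool


@dataclass(frozen=True)
class SessionResult:
    outcomes: tuple[TrialOutcome, ...]
    earnings: float
    pending_rewards_remaining: dict[str, int]
    included: bool

    @property
    def n_rewarded(self) -> int:
        return sum(o.rewarded for o in self.outcomes)

    def rewards_per_block(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for o in self.outcomes:
            counts[o.plan.block] = counts.get(o.plan.block, 0) + int(o.rewarded)
        return counts


def _constrained_binary_order(
    n_a: int, n_b: int, cap: int, rng: np.random.Generator
) -> list[int]:
    """Random sequence of n_a zeros and n_b ones with no run longer than cap.

    Sequential sampling with an exact feasibility look-ahead, so it never
    dead-ends: after placing a symbol with trailing run t, the remainder is
    arrangeable iff  r_same <= cap*(r_other+1) - t  and  r_other <= cap*(r_same+1).
    """
    remaining = [n_a, n_b]
    out: list[int] = []
    last, run = -1, 0
    for _ in range(n_a + n_b):
        candidates = []
        weights = []
        for s in (0, 1):
            if remaining[s] == 0:
                continue
            t = run + 1 if s == last else 1
            if t > cap:
                continue
            r_same = remaining[s] - 1
            r_other = remaining[1 - s]
            if r_same > cap * (r_other + 1) - t:
                continue
            if r_other > cap * (r_same + 1):
                continue
            candidates.append(s)
            weights.append(remaining[s])
        if not candidates:  # pragma: no cover - feasibility check prevents this
            raise ScheduleError("stimulus-order construction dead-ended")
        probs = np.asarray(weights, dtype=float)
        s = int(rng.choice(candidates, p=probs / probs.sum()))
        out.append(s)
        run = run + 1 if s == last else 1
        last = s
        remaining[s] -= 1
    return out


def _max_true_run(flags: Sequence[bool]) -> int:
    best = cur = 0
    for f in flags:
        cur = cur + 1 if f else 0
        best = max(best, cur)
    return best


def _place_rewards(
    stimuli: Sequence[str],
    config: ScheduleConfig,
    rng: np.random.Generator,
    max_attempts: int = 100_000,
) -> list[bool]:
    """Choose reward positions (rich/lean counts) with the reward-run cap.

    Rejection sampling with a deterministic generator and a retry budget;
    the configuration was already checked feasible, and for realistic
    designs the acceptance probability is high.
    """
    rich_idx = [i for i, s in enumerate(stimuli) if s == config.rich_stimulus]
    lean_idx = [i for i, s in enumerate(stimuli) if s != config.rich_stimulus]
    for _ in range(max_attempts):
        chosen = set(rng.choice(rich_idx, size=config.rich_rewards_per_block, replace=False))
        chosen |= set(rng.choice(lean_idx, size=config.lean_rewards_per_block, replace=False))
        flags = [i in chosen for i in range(len(stimuli))]
        if _max_true_run(flags) <= config.max_reward_run:
            return flags
    raise ScheduleError(
        "could not place rewards under the run cap within the retry budget; "
        "the configuration is likely near-unsatisfiable"
    )


def generate_schedule(config: ScheduleConfig) -> Schedule:
    """Generate a full-session schedule satisfying all design constraints.

    Blocks are generated independently; the run caps apply within a block.
    The same configuration (including seed) always yields the same schedule.
    """
    rng = np.random.default_rng(config.rng_seed)
    half = config.trials_per_block // 2
    trials: list[TrialPlan] = []
    for block in range(1, config.n_blocks + 1):
        order = _constrained_binary_order(half, half, config.max_stimulus_run, rng)
        stimuli = [STIMULI[s] for s in order]
        rewards = _place_rewards(stimuli, config, rng)
        for i, (stim, rew) in enumerate(zip(stimuli, rewards), start=1):
            trials.append(
                TrialPlan(
                    block=block,
                    trial=i,
                    stimulus=stim,
                    is_rich=(stim == config.rich_stimulus),
                    scheduled_reward=rew,
                )
            )
    return Schedule(config=config, trials=tuple(trials))


def run_session(schedule: Schedule, responder: Responder) -> SessionResult:
    """Play a schedule against a responder, applying the postponement rule.

    Per trial, at most one reward is delivered and only on a correct
    response: a scheduled reward is delivered directly; otherwise, if a
    postponed reward is pending for that stimulus, it is delivered and the
    pending count decremented.  A scheduled reward on an incorrect trial
    joins that stimulus's pending pool.  Pending rewards carry across block
    boundaries; any still pending at session end are reported, not forced.
    """
    config = schedule.config
    pending = {SHORT: 0, LONG: 0}
    outcomes: list[TrialOutcome] = []
    n_rewarded = 0
    for plan in schedule.trials:
        response, rt_ms = responder.respond(plan)
        if response not in STIMULI:
            raise ResponderError(f"responder returned invalid label {response!r}")
        if rt_ms < 0:
            raise ResponderError(f"responder returned negative reaction time {rt_ms!r}")
        correct = response == plan.stimulus
        rewarded = False
        postponed = False
        if correct:
            if plan.scheduled_reward:
                rewarded = True
            elif pending[plan.stimulus] > 0:
                pending[plan.stimulus] -= 1
                rewarded = True
                postponed = True
        elif plan.scheduled_reward:
            pending[plan.stimulus] += 1
        n_rewarded += int(rewarded)
        outcomes.append(
            TrialOutcome(
                plan=plan,
                response=response,
                correct=correct,
                rt_ms=float(rt_ms),
                rewarded=rewarded,
                reward_postponed=postponed,
                valid=RT_MIN_MS <= rt_ms <= RT_MAX_MS,
            )
        )
        responder.feedback(plan, rewarded)
    earnings = round(n_rewarded * config.reward_value, 2)
    return SessionResult(
        outcomes=tuple(outcomes),
        earnings=earnings,
        pending_rewards_remaining=dict(pending),
        included=earnings >= INCLUSION_THRESHOLD_GBP,
    )


def filter_trials(outcomes: Iterable[TrialOutcome]) -> list[TrialOutcome]:
    """Keep trials with 200 ms <= rt <= 3000 ms, preserving order.

    The removal rule targets trials *faster than* 200 ms and *slower than*
    3000 ms, so the boundary values themselves are retained.
    """
    return [o for o in outcomes if RT_MIN_MS <= o.rt_ms <= RT_MAX_MS]


def apply_earnings_exclusion(
    results: dict[str, SessionResult],
    threshold: float = INCLUSION_THRESHOLD_GBP,
) -> tuple[dict[str, SessionResult], pd.DataFrame]:
    """Split sessions into included / excluded by the earnings threshold.

    Returns the included subset (keyed as given) and a report frame listing
    every participant with earnings and inclusion status.
    """
    report = pd.DataFrame(
        {
            "participant_id": list(results),
            "earnings": [r.earnings for r in results.values()],
        }
    )
    report["included"] = report["earnings"] >= threshold
    included = {pid: r for pid, r in results.items() if r.earnings >= threshold}
    return included, report


# ---------------------------------------------------------------------------
# trial-log CSV interface

TRIAL_LOG_COLUMNS = [
    "participant_id",
    "block",
    "trial",
    "stimulus",
    "is_rich",
    "scheduled_reward",
    "response",
    "correct",
    "rt_ms",
    "rewarded",
    "valid",
]


def outcomes_to_frame(outcomes: Iterable[TrialOutcome], participant_id: str) -> pd.DataFrame:
    rows = [
        {
            "participant_id": participant_id,
            "block": o.plan.block,
            "trial": o.plan.trial,
            "stimulus": o.plan.stimulus,
            "is_rich": o.plan.is_rich,
            "scheduled_reward": o.plan.scheduled_reward,
            "response": o.response,
            "correct": o.correct,
            "rt_ms": o.rt_ms,
            "rewarded": o.rewarded,
            "valid": o.valid,
        }
        for o in outcomes
    ]
    return pd.DataFrame(rows, columns=TRIAL_LOG_COLUMNS)


def write_trial_log(frames: Iterable[pd.DataFrame], path) -> None:
    pd.concat(list(frames), ignore_index=True).to_csv(path, index=False)


def read_trial_log(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRIAL_LOG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial log missing columns: {sorted(missing)}")
    return df


def frame_to_outcomes(df: pd.DataFrame, rich_stimulus: str) -> list[TrialOutcome]:
    """Rebuild TrialOutcome objects from one participant's trial-log rows."""
    out = []
    for row in df.itertuples(index=False):
        plan = TrialPlan(
            block=int(row.block),
            trial=int(row.trial),
            stimulus=str(row.stimulus),
            is_rich=bool(row.is_rich),
            scheduled_reward=bool(row.scheduled_reward),
        )
        out.append(
            TrialOutcome(
                plan=plan,
                response=str(row.response),
                correct=bool(row.correct),
                rt_ms=float(row.rt_ms),
                rewarded=bool(row.rewarded),
                reward_postponed=False,
                valid=bool(row.valid),
            )
        )
    return out
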