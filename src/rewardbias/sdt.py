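"""Signal-detection scoring of task sessions.

Per block, valid trials are classified against the rich (more frequently
reinforced) stimulus: a *hit* is a rich-stimulus trial answered with the
rich response, a *false alarm* a lean-stimulus trial answered with the rich
response.  Rates are edge-corrected log-linearly, then

    d' = z(H) - z(F)            (discriminability)
    c  = -1/2 [z(H) + z(F)]     (criterion)

with the criterion sign-reversed at scoring time, so the reported value
+1/2 [z(H) + z(F)] is positive when responding is biased toward the rich
category.  Δresponse bias is the block-3 minus block-1 reported criterion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import norm

from .task import SessionResult, TrialOutcome, filter_trials


class ScoringError(ValueError):
    """Raised when a block has no valid trials of one stimulus."""


@dataclass(frozen=True)
class BlockScore:
    block: int
    n_valid: int
    n_rich_trials: int
    n_lean_trials: int
    hits: int
    false_alarms: int
    hit_rate: float
    fa_rate: float
    d_prime: float
    criterion: float  # sign-reversed: positive = bias toward the rich response


@dataclass(frozen=True)
class ParticipantScore:
    blocks: tuple[BlockScore, ...]
    mean_criterion: float
    mean_d_prime: float
    delta_response_bias: float  # block 3 criterion - block 1 criterion


def classify_trials(
    outcomes: Sequence[TrialOutcome], rich_stimulus: str
) -> tuple[int, int, int, int]:
    """Count (hits, misses, false_alarms, correct_rejections) on valid trials.

    The signal category is the rich stimulus by default; passing the other
    label instead scores relative to a fixed physical stimulus.
    """
    hits = misses = fas = crs = 0
    for o in outcomes:
        signal_trial = o.plan.stimulus == rich_stimulus
        rich_response = o.response == rich_stimulus
        if signal_trial and rich_response:
            hits += 1
        elif signal_trial:
            misses += 1
        elif rich_response:
            fas += 1
        else:
            crs += 1
    if hits + misses == 0 or fas + crs == 0:
        raise ScoringError("no valid trials of one stimulus; block cannot be scored")
    return hits, misses, fas, crs


def edge_corrected_rates(
    hits: int, n_rich: int, false_alarms: int, n_lean: int
) -> tuple[float, float]:
    """Log-linear (+0.5 / +1) correction, applied to every block uniformly.

    Guarantees rates strictly inside (0, 1) so the normal quantile is
    always defined, and leaves the midpoint rate 0.5 unchanged.
    """
    if not (0 <= hits <= n_rich and 0 <= false_alarms <= n_lean):
        raise ValueError("counts inconsistent with trial totals")
    return (hits + 0.5) / (n_rich + 1), (false_alarms + 0.5) / (n_lean + 1)


def sdt_measures(hit_rate: float, fa_rate: float) -> tuple[float, float]:
    """Return (d_prime, reported criterion) from corrected rates.

    The reported criterion is the sign-reversed SDT criterion,
    +1/2 [z(H) + z(F)]: positive values mean stronger bias toward the
    signal (rich) response.
    """
    for r in (hit_rate, fa_rate):
        if not 0.0 < r < 1.0:
            raise ValueError("rates must be strictly inside (0, 1); apply edge correction")
    zh = float(norm.ppf(hit_rate))
    zf = float(norm.ppf(fa_rate))
    return zh - zf, 0.5 * (zh + zf)


def score_block(
    outcomes: Sequence[TrialOutcome], rich_stimulus: str, block: int
) -> BlockScore:
    hits, misses, fas, crs = classify_trials(outcomes, rich_stimulus)
    n_rich = hits + misses
    n_lean = fas + crs
    h, f = edge_corrected_rates(hits, n_rich, fas, n_lean)
    d_prime, criterion = sdt_measures(h, f)
    return BlockScore(
        block=block,
        n_valid=len(outcomes),
        n_rich_trials=n_rich,
        n_lean_trials=n_lean,
        hits=hits,
        false_alarms=fas,
        hit_rate=h,
        fa_rate=f,
        d_prime=d_prime,
        criterion=criterion,
    )


def score_outcomes(
    outcomes: Iterable[TrialOutcome], rich_stimulus: str
) -> ParticipantScore:
    """Score a sequence of trial outcomes (RT filter applied here)."""
    valid = filter_trials(outcomes)
    blocks = sorted({o.plan.block for o in valid})
    scores = tuple(
        score_block([o for o in valid if o.plan.block == b], rich_stimulus, b)
        for b in blocks
    )
    criteria = {s.block: s.criterion for s in scores}
    first, last = min(criteria), max(criteria)
    return ParticipantScore(
        blocks=scores,
        mean_criterion=sum(s.criterion for s in scores) / len(scores),
        mean_d_prime=sum(s.d_prime for s in scores) / len(scores),
        delta_response_bias=criteria[last] - criteria[first],
    )


def score_participant(session: SessionResult, rich_stimulus: str) -> ParticipantScore:
    """Score a full session: filter invalid trials, then score each block."""
    return score_outcomes(session.outcomes, rich_stimulus)


# ---------------------------------------------------------------------------
# scores CSV interface

SCORES_COLUMNS = [
    "participant_id",
    "block",
    "n_valid",
    "hits",
    "false_alarms",
    "H",
    "F",
    "d_prime",
    "criterion",
]


def scores_to_frame(scores: dict[str, ParticipantScore]) -> pd.DataFrame:
    rows = []
    for pid, ps in scores.items():
        for b in ps.blocks:
            rows.append(
                {
                    "participant_id": pid,
                    "block": b.block,
                    "n_valid": b.n_valid,
                    "hits": b.hits,
                    "false_alarms": b.false_alarms,
                    "H": b.hit_rate,
                    "F": b.fa_rate,
                    "d_prime": b.d_prime,
                    "criterion": b.criterion,
                }
            )
    return pd.DataFrame(rows, columns=SCORES_COLUMNS)


def summary_frame(scores: dict[str, ParticipantScore]) -> pd.DataFrame:
    """Participant-level summary: per-block criterion/d' plus derived measures."""
    rows = []
    for pid, ps in scores.items():
        row: dict = {"participant_id": pid}
        for b in ps.blocks:
            row[f"criterion_b{b.block}"] = b.criterion
            row[f"d_prime_b{b.block}"] = b.d_prime
        row["mean_criterion"] = ps.mean_criterion
        row["mean_d_prime"] = ps.mean_d_prime
        row["delta_response_bias"] = ps.delta_response_bias
        rows.append(row)
    return pd.DataFrame(rows)
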