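"""Synthetic cohorts: genotypes, demographics and genotype-graded agents.

A cohort of simulated participants carries the statistical structure the
genotype-association analysis assumes: genotypes at Hardy-Weinberg
equilibrium for a configurable risk-allele frequency, demographics with no
built-in genotype correlation, and one behavioral agent per participant
whose reward-learning rate depends on genotype while perceptual sensitivity
does not.  The learning-rate separation between genotype groups is
calibrated against a Monte-Carlo table (mean and SD of the scored mean
criterion as a function of learning rate) so that large simulated samples
reproduce configurable standardized effects — by default Cohen's d = 0.66
for the AA vs GG contrast and d = 0.37 for the dominant (carriers vs GG)
contrast on mean criterion.

All randomness flows through one seed hierarchy (cohort → participant →
trial stream), so any participant is individually reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .agents import AgentParams
from .stats import GENOTYPES, RISK_DOSE
from .task import LONG, SHORT
from ._rng import seed31

#: Between-participant SD of the reward-learning rate within a genotype
#: group (decision-axis units per reward).  Sized so that stable individual
#: differences dominate session-level sampling noise (roughly 3:1 in
#: criterion variance), as expected for a trait-like measure, while keeping
#: the per-participant rates inside the near-linear region of the
#: criterion response.
DEFAULT_LEARNING_RATE_SD = 0.0028

#: Mean and SD of perceptual sensitivity (true d'), identical across
#: genotypes by construction.
DEFAULT_SENSITIVITY_MEAN = 1.7
DEFAULT_SENSITIVITY_SD = 0.30


class CalibrationError(ValueError):
    """Raised when requested effect sizes are outside the calibrated range."""


@dataclass(frozen=True)
class EffectTargets:
    """Standardized effect-size targets on mean criterion."""

    d_aa_vs_gg: float = 0.66
    d_dominant: float = 0.37


@dataclass(frozen=True)
class CohortConfig:
    n_participants: int = 164
    risk_allele_freq: float = 0.33
    #: mean reward-learning rate per genotype; None → calibrated from effect_scale
    genotype_effect: dict[str, float] | None = None
    learning_rate_sd: float = DEFAULT_LEARNING_RATE_SD
    effect_scale: EffectTargets = field(default_factory=EffectTargets)
    sensitivity_mean: float = DEFAULT_SENSITIVITY_MEAN
    sensitivity_sd: float = DEFAULT_SENSITIVITY_SD
    age_mean: float = 22.3
    age_sd: float = 4.4
    gender_proportion_male: float = 0.44
    site_labels: tuple[str, ...] = ("bangor", "cardiff")
    site_proportions: tuple[float, ...] = (0.79, 0.21)
    #: exact genotype counts override (e.g. the study's 23/62/79); drawn
    #: from Hardy-Weinberg proportions when None
    genotype_counts: dict[str, int] | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.risk_allele_freq <= 1.0:
            raise ValueError("risk_allele_freq must lie in [0, 1]")
        if self.n_participants < 1:
            raise ValueError("n_participants must be positive")
        if len(self.site_labels) != len(self.site_proportions):
            raise ValueError("site_labels and site_proportions must align")
        if abs(sum(self.site_proportions) - 1.0) > 1e-9:
            raise ValueError("site_proportions must sum to 1")
        if self.genotype_counts is not None:
            if set(self.genotype_counts) != set(GENOTYPES):
                raise ValueError("genotype_counts must cover AA, AG, GG")
            if sum(self.genotype_counts.values()) != self.n_participants:
                raise ValueError("genotype_counts must sum to n_participants")


@dataclass
class Participant:
    id: str
    genotype: str
    risk_dose: int
    site: str
    age: float
    gender: str
    params: AgentParams
    rich_stimulus: str
    seed: int
    session: object | None = None  # SessionResult, filled by the pipeline
    score: object | None = None  # ParticipantScore, filled by the pipeline

    def __post_init__(self) -> None:
        if RISK_DOSE[self.genotype] != self.risk_dose:
            raise ValueError("risk_dose inconsistent with genotype")


def sample_genotypes(n: int, p_risk: float, rng: np.random.Generator | int) -> np.ndarray:
    """Draw genotypes i.i.d. from Hardy-Weinberg proportions.

    (AA, AG, GG) probabilities are (p², 2pq, q²) with p the risk-allele
    frequency.
    """
    if not 0.0 <= p_risk <= 1.0:
        raise ValueError("p_risk must lie in [0, 1]")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    q = 1.0 - p_risk
    probs = np.array([p_risk**2, 2 * p_risk * q, q**2])
    return rng.choice(np.array(GENOTYPES), size=n, p=probs)


# ---------------------------------------------------------------------------
# effect-size calibration


def load_calibration_table() -> dict:
    """Monte-Carlo calibration table shipped with the package.

    Maps learning rate to the mean and SD of the scored participant mean
    criterion under the default agent and schedule; regenerated by
    ``scripts/calibrate_effects.py``.
    """
    with resources.files("rewardbias.data").joinpath("effect_calibration.json").open() as fh:
        return json.load(fh)


def _criterion_response(table: dict) -> tuple[float, float, float]:
    """Least-squares linear fit mean_criterion ~ a + b * learning_rate,
    plus the average session-level SD s0 across the grid."""
    lrs = np.array([row["learning_rate"] for row in table["grid"]])
    means = np.array([row["mean_criterion"] for row in table["grid"]])
    sds = np.array([row["sd_criterion"] for row in table["grid"]])
    b, a = np.polyfit(lrs, means, 1)
    return float(a), float(b), float(sds.mean())


def calibrated_genotype_effect(
    targets: EffectTargets,
    learning_rate_sd: float = DEFAULT_LEARNING_RATE_SD,
    table: dict | None = None,
) -> dict[str, float]:
    """Solve for per-genotype mean learning rates hitting the d targets.

    The AA (two-risk-allele) group is anchored at a zero learning rate —
    the no-reward-responsiveness phenotype.  The GG rate is set from the
    AA-vs-GG target via the calibrated linear criterion response; the AG
    rate is then placed so the dominant-model contrast (equal-sized
    genotype groups, carriers pooled) hits its target, accounting for the
    extra carrier variance induced by the AA/AG mean split.

    Raises :class:`CalibrationError` when a target falls outside the
    calibrated learning-rate range.
    """
    if table is None:
        table = load_calibration_table()
    a, b, s0 = _criterion_response(table)
    if b <= 0:
        raise CalibrationError("calibration table shows no criterion response")
    s_within = float(np.hypot(s0, b * learning_rate_sd))
    lr_aa = 0.0
    delta = targets.d_aa_vs_gg * s_within / b
    lr_gg = lr_aa + delta
    lr_max = max(row["learning_rate"] for row in table["grid"])
    if not 0.0 <= lr_gg <= lr_max:
        raise CalibrationError(
            f"target d={targets.d_aa_vs_gg} needs learning rate {lr_gg:.4f}, "
            f"outside the calibrated range [0, {lr_max}]"
        )
    # dominant contrast at equal genotype-group sizes n each:
    # carriers (AA∪AG, 2n) vs GG (n), pooled SD includes the carrier mixture
    # variance.  Solve for lr_AG by fixed point (variance term is small).
    lr_ag = lr_aa + 0.5 * delta
    for _ in range(50):
        mix_gap = b * (lr_ag - lr_aa)  # AA/AG mean split on the criterion scale
        var_carrier = s_within**2 + (mix_gap / 2) ** 2
        # pooled over n_c = 2n carriers and n GG subjects, large-n weights 2:1
        sd_pool = float(np.sqrt((2 * var_carrier + s_within**2) / 3))
        carrier_mean_lr = lr_gg - targets.d_dominant * sd_pool / b
        new_ag = 2 * carrier_mean_lr - lr_aa
        if abs(new_ag - lr_ag) < 1e-12:
            lr_ag = new_ag
            break
        lr_ag = new_ag
    if not lr_aa - 1e-9 <= lr_ag <= lr_gg + 1e-9:
        raise CalibrationError(
            f"dominant target d={targets.d_dominant} incompatible with the "
            f"AA-vs-GG target (AG rate {lr_ag:.4f} outside [AA, GG])"
        )
    return {"AA": lr_aa, "AG": float(min(max(lr_ag, lr_aa), lr_gg)), "GG": float(lr_gg)}


# ---------------------------------------------------------------------------
# cohort construction


def build_cohort(config: CohortConfig) -> list[Participant]:
    """Build a cohort of participants with agents assigned, sessions not run.

    Learning rates are drawn per genotype around the configured (or
    calibrated) group means with a common within-group SD; perceptual
    sensitivity is drawn from one distribution for all genotypes.  The rich
    stimulus alternates across participants (counterbalancing).
    """
    ss = np.random.SeedSequence(config.rng_seed)
    master, *children = ss.spawn(config.n_participants + 1)
    rng = np.random.default_rng(master)

    if config.genotype_counts is not None:
        genotypes = np.repeat(
            list(config.genotype_counts), list(config.genotype_counts.values())
        )
        rng.shuffle(genotypes)
    else:
        genotypes = sample_genotypes(config.n_participants, config.risk_allele_freq, rng)

    effects = config.genotype_effect
    if effects is None:
        effects = calibrated_genotype_effect(config.effect_scale, config.learning_rate_sd)
    missing = set(np.unique(genotypes)) - set(effects)
    if missing:
        raise ValueError(f"genotype_effect missing entries for {sorted(missing)}")

    participants = []
    for i, (g, child) in enumerate(zip(genotypes, children)):
        lr = float(rng.normal(effects[g], config.learning_rate_sd))
        sens = float(max(0.2, rng.normal(config.sensitivity_mean, config.sensitivity_sd)))
        age = float(np.clip(rng.normal(config.age_mean, config.age_sd), 18.0, 60.0))
        gender = "M" if rng.random() < config.gender_proportion_male else "F"
        site = str(rng.choice(list(config.site_labels), p=list(config.site_proportions)))
        participants.append(
            Participant(
                id=f"P{i + 1:04d}",
                genotype=str(g),
                risk_dose=RISK_DOSE[str(g)],
                site=site,
                age=age,
                gender=gender,
                params=AgentParams(
                    perceptual_sensitivity=sens,
                    reward_learning_rate=lr,
                ),
                rich_stimulus=LONG if i % 2 == 0 else SHORT,
                seed=seed31(child),
            )
        )
    return participants


# ---------------------------------------------------------------------------
# CSV / YAML interfaces

COHORT_COLUMNS = [
    "participant_id",
    "genotype",
    "risk_dose",
    "site",
    "age",
    "gender",
    "learning_rate",
    "sensitivity",
    "rich_stimulus",
    "seed",
]


def cohort_to_frame(participants: Sequence[Participant]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant_id": [p.id for p in participants],
            "genotype": [p.genotype for p in participants],
            "risk_dose": [p.risk_dose for p in participants],
            "site": [p.site for p in participants],
            "age": [p.age for p in participants],
            "gender": [p.gender for p in participants],
            "learning_rate": [p.params.reward_learning_rate for p in participants],
            "sensitivity": [p.params.perceptual_sensitivity for p in participants],
            "rich_stimulus": [p.rich_stimulus for p in participants],
            "seed": [p.seed for p in participants],
        },
        columns=COHORT_COLUMNS,
    )


def frame_to_cohort(df: pd.DataFrame) -> list[Participant]:
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            Participant(
                id=str(row.participant_id),
                genotype=str(row.genotype),
                risk_dose=int(row.risk_dose),
                site=str(row.site),
                age=float(row.age),
                gender=str(row.gender),
                params=AgentParams(
                    perceptual_sensitivity=float(row.sensitivity),
                    reward_learning_rate=float(row.learning_rate),
                ),
                rich_stimulus=str(row.rich_stimulus),
                seed=int(row.seed),
            )
        )
    return out


def config_from_yaml(path) -> CohortConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "effect_scale" in raw and isinstance(raw["effect_scale"], dict):
        raw["effect_scale"] = EffectTargets(**raw["effect_scale"])
    if "site_labels" in raw:
        raw["site_labels"] = tuple(raw["site_labels"])
    if "site_proportions" in raw:
        raw["site_proportions"] = tuple(raw["site_proportions"])
    known = set(CohortConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown cohort config keys: {sorted(unknown)}")
    return CohortConfig(**raw)
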