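"""End-to-end study pipeline on synthetic cohorts.

Orchestrates cohort construction → schedule generation → session simulation
→ trial filtering and earnings exclusion → signal-detection scoring → the
full genotype-association analysis sequence: demographic checks (site,
gender, age), Hardy-Weinberg test, discriminability ANCOVA with age as a
covariate, criterion mixed ANOVA under additive and dominant genotype
codings, per-block one-way ANOVA with corrected pairwise contrasts and
Cohen's d, Δresponse-bias ANOVA, per-block one-sample t-tests per genotype
group, and analytic power calculations.  Everything is reproducible from
(config, seed), and excluded participants / invalid trials never reach the
statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import sdt, stats, task
from .agents import CriterionLearner
from .cohort import CohortConfig, Participant, build_cohort, cohort_to_frame
from .sdt import score_participant
from .stats import PowerSpec, TestResult
from .task import ScheduleConfig, SessionResult, generate_schedule, run_session
from ._rng import seed31


@dataclass(frozen=True)
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    codings: tuple[str, ...] = ("additive", "dominant")
    correction: str = "bonferroni"
    earnings_threshold: float = task.INCLUSION_THRESHOLD_GBP
    power_d: tuple[float, ...] = (0.38, 0.37)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for c in self.codings:
            if c not in ("additive", "dominant"):
                raise ValueError(f"unknown coding {c!r}")


class PipelineError(RuntimeError):
    """Stage-labeled pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def study_design_config(rng_seed: int = 0) -> RunConfig:
    """Preset mirroring the original study design: 164 participants with
    genotype counts 23 / 62 / 79 (AA / AG / GG), default task schedule."""
    return RunConfig(
        cohort=CohortConfig(
            n_participants=164,
            genotype_counts={"AA": 23, "AG": 62, "GG": 79},
            rng_seed=rng_seed,
        ),
        rng_seed=rng_seed,
    )


# ---------------------------------------------------------------------------
# simulation stages


def run_agent_session(
    params, schedule_config: ScheduleConfig, rich_stimulus: str, seed: int
) -> SessionResult:
    """One agent, one fresh schedule, one session.

    The participant seed is split into independent streams for schedule
    construction and for the agent's percept/RT noise.
    """
    sched_stream, agent_stream = np.random.SeedSequence(seed).spawn(2)
    cfg = replace(
        schedule_config,
        rng_seed=seed31(sched_stream),
        rich_stimulus=rich_stimulus,
    )
    agent = CriterionLearner(params, np.random.default_rng(agent_stream))
    return run_session(generate_schedule(cfg), agent)


def simulate_sessions(
    participants: Sequence[Participant], schedule_config: ScheduleConfig
) -> None:
    """Run each participant's agent through their own schedule, in place.

    Every participant gets an individual schedule (from their own seed)
    with their counterbalanced rich stimulus.
    """
    for p in participants:
        p.session = run_agent_session(p.params, schedule_config, p.rich_stimulus, p.seed)


def score_sessions(participants: Sequence[Participant]) -> None:
    for p in participants:
        if p.session is None:
            raise PipelineError("score", f"participant {p.id} has no session")
        p.score = score_participant(p.session, p.rich_stimulus)


def simulate_cohort(config: RunConfig) -> tuple[list[Participant], pd.DataFrame]:
    """Cohort → sessions → exclusion → scores.  Returns the *included*
    participants and the exclusion report."""
    try:
        participants = build_cohort(config.cohort)
    except Exception as e:
        raise PipelineError("cohort", str(e)) from e
    try:
        simulate_sessions(participants, config.schedule)
    except Exception as e:
        raise PipelineError("session", str(e)) from e
    sessions = {p.id: p.session for p in participants}
    included_ids, report = task.apply_earnings_exclusion(sessions, config.earnings_threshold)
    included = [p for p in participants if p.id in included_ids]
    try:
        score_sessions(included)
    except Exception as e:
        raise PipelineError("score", str(e)) from e
    return included, report


# ---------------------------------------------------------------------------
# analysis


def _grouped(values: dict[str, float], genotypes: dict[str, str], scheme: str) -> dict[str, list[float]]:
    gl = list(genotypes.values())
    masks = stats.code_genotypes(gl, scheme)
    ids = list(values)
    out: dict[str, list[float]] = {}
    for label, mask in masks.items():
        out[label] = [values[i] for i, m in zip(ids, mask) if m]
    return out


def analyze(
    participants: Sequence[Participant], config: RunConfig
) -> dict:
    """Run the full analysis sequence on scored, included participants."""
    if any(p.score is None for p in participants):
        raise PipelineError("analyze", "participants must be scored first")
    genos = {p.id: p.genotype for p in participants}
    ages = {p.id: p.age for p in participants}
    crit = {
        p.id: np.array([b.criterion for b in p.score.blocks]) for p in participants
    }
    dprime = {
        p.id: np.array([b.d_prime for b in p.score.blocks]) for p in participants
    }
    mean_crit = {pid: float(v.mean()) for pid, v in crit.items()}
    delta = {p.id: p.score.delta_response_bias for p in participants}
    n_blocks = len(next(iter(crit.values())))

    report: dict = {"n_participants": len(participants), "tests": {}}
    tests = report["tests"]

    def add(key: str, result: TestResult | list[TestResult] | dict[str, TestResult]):
        if isinstance(result, TestResult):
            tests[key] = result.to_dict()
        elif isinstance(result, list):
            tests[key] = [r.to_dict() for r in result]
        else:
            tests[key] = {k: v.to_dict() for k, v in result.items()}

    # --- demographic / genetic sanity checks -------------------------------
    counts = {g: sum(v == g for v in genos.values()) for g in stats.GENOTYPES}
    report["genotype_counts"] = counts
    add("hwe", stats.hwe_chisq(counts["AA"], counts["AG"], counts["GG"]))

    site_table = pd.crosstab(
        pd.Series([p.site for p in participants]),
        pd.Series([p.genotype for p in participants]),
    )
    if site_table.shape[0] >= 2:
        add("site_by_genotype", stats.contingency_chisq(site_table.values, "site_by_genotype"))
    gender_table = pd.crosstab(
        pd.Series([p.gender for p in participants]),
        pd.Series([p.genotype for p in participants]),
    )
    if gender_table.shape[0] >= 2:
        add("gender_by_genotype", stats.contingency_chisq(gender_table.values, "gender_by_genotype"))
    add("age_by_genotype", stats.oneway_anova(_grouped(ages, genos, "additive"), "age_by_genotype"))
    add(
        "age_vs_dprime_block1",
        stats.age_association(
            [ages[pid] for pid in dprime], [float(dprime[pid][0]) for pid in dprime],
            "age_vs_dprime_block1",
        ),
    )

    # --- genotype effects --------------------------------------------------
    ids = list(crit)
    crit_mat = np.vstack([crit[i] for i in ids])
    dprime_mat = np.vstack([dprime[i] for i in ids])
    age_vec = [ages[i] for i in ids]
    for scheme in config.codings:
        labels = _scheme_labels(genos, ids, scheme)
        add(
            f"dprime_mixed_ancova_{scheme}",
            stats.mixed_anova(dprime_mat, labels, covariate=age_vec),
        )
        add(f"criterion_mixed_anova_{scheme}", stats.mixed_anova(crit_mat, labels))

    # per-block one-way ANOVA on criterion (additive coding)
    for b in range(n_blocks):
        block_vals = {pid: float(crit[pid][b]) for pid in ids}
        add(
            f"criterion_block{b + 1}_oneway",
            stats.oneway_anova(_grouped(block_vals, genos, "additive"), f"criterion_block{b + 1}"),
        )

    # pairwise corrected contrasts + Cohen's d on mean criterion
    groups_add = _grouped(mean_crit, genos, "additive")
    add("mean_criterion_pairwise", stats.pairwise_corrected(groups_add, config.correction))
    groups_dom = _grouped(mean_crit, genos, "dominant")
    add(
        "mean_criterion_dominant_t",
        stats.independent_t(groups_dom["AA/AG"], groups_dom["GG"], "carriers_vs_GG"),
    )
    report["cohens_d_AA_vs_GG"] = stats.cohens_d(groups_add["GG"], groups_add["AA"])
    report["cohens_d_dominant"] = stats.cohens_d(groups_dom["GG"], groups_dom["AA/AG"])

    # Δresponse bias
    add(
        "delta_bias_oneway",
        stats.oneway_anova(_grouped(delta, genos, "additive"), "delta_bias"),
    )

    # per-block one-sample t per genotype group
    one_sample: dict = {}
    for g in stats.GENOTYPES:
        g_ids = [pid for pid in ids if genos[pid] == g]
        one_sample[g] = {}
        for b in range(n_blocks):
            r = stats.one_sample_t([float(crit[pid][b]) for pid in g_ids], 0.0, f"{g}_block{b + 1}")
            one_sample[g][f"block{b + 1}"] = r.to_dict()
    tests["criterion_vs_zero"] = one_sample

    # --- power -------------------------------------------------------------
    masks = stats.code_genotypes([genos[i] for i in ids], "dominant")
    n1, n2 = int(masks["AA/AG"].sum()), int(masks["GG"].sum())
    report["power"] = {
        f"d={d}": stats.power_two_sample(PowerSpec(d, n1, n2, alpha=0.05, tails="one-sided"))
        for d in config.power_d
    }
    return report


def _scheme_labels(genos: dict[str, str], ids: list[str], scheme: str) -> list[str]:
    if scheme == "additive":
        return [genos[i] for i in ids]
    return ["AA/AG" if genos[i] in ("AA", "AG") else "GG" for i in ids]


# ---------------------------------------------------------------------------
# full runs and replicates


def run_study(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Full study reproduction; optionally writes all stage outputs.

    Written artifacts: cohort.csv, trials.csv, scores.csv, exclusions.csv,
    report.json and report.txt.
    """
    participants, exclusion_report = simulate_cohort(config)
    try:
        report = analyze(participants, config)
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError("analyze", str(e)) from e
    report["n_excluded"] = int((~exclusion_report["included"]).sum())
    report["n_trials_removed"] = int(
        sum(sum(not o.valid for o in p.session.outcomes) for p in participants)
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cohort_to_frame(participants).to_csv(out / "cohort.csv", index=False)
        task.write_trial_log(
            (task.outcomes_to_frame(p.session.outcomes, p.id) for p in participants),
            out / "trials.csv",
        )
        sdt.scores_to_frame({p.id: p.score for p in participants}).to_csv(
            out / "scores.csv", index=False
        )
        exclusion_report.to_csv(out / "exclusions.csv", index=False)
        (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
        (out / "report.txt").write_text(format_report(report))
    return report


def format_report(report: dict) -> str:
    """Human-readable text rendering of the analysis report."""
    lines = [
        f"participants analyzed: {report['n_participants']}"
        f" (excluded: {report.get('n_excluded', 0)};"
        f" invalid trials removed: {report.get('n_trials_removed', 0)})",
        f"genotype counts: {report.get('genotype_counts')}",
        "",
    ]

    def fmt(t: dict) -> str:
        df = ",".join(f"{v:g}" for v in t["df"])
        s = f"{t['statistic_name']}({df}) = {t['statistic']:.3f}, p = {t['p_value']:.4f}"
        if t.get("effect_size") is not None:
            s += f", {t['effect_size_name']} = {t['effect_size']:.3f}"
        if t.get("correction", "none") != "none":
            s += f" [{t['correction']}]"
        return s

    def walk(key: str, obj, indent: int = 0):
        pad = "  " * indent
        if isinstance(obj, dict) and "statistic" in obj:
            lines.append(f"{pad}{key}: {fmt(obj)}")
        elif isinstance(obj, dict):
            lines.append(f"{pad}{key}:")
            for k, v in obj.items():
                walk(k, v, indent + 1)
        elif isinstance(obj, list):
            lines.append(f"{pad}{key}:")
            for v in obj:
                walk(v.get("name", "?"), v, indent + 1)

    for key, obj in report["tests"].items():
        walk(key, obj)
    lines.append("")
    lines.append(f"Cohen's d (GG vs AA, mean criterion): {report['cohens_d_AA_vs_GG']:.3f}")
    lines.append(f"Cohen's d (GG vs carriers, mean criterion): {report['cohens_d_dominant']:.3f}")
    for k, v in report.get("power", {}).items():
        lines.append(f"power {k}: {v:.3f}")
    return "\n".join(lines) + "\n"


def run_replicates(
    config: RunConfig, n_reps: int, alpha: float = 0.05
) -> tuple[pd.DataFrame, dict]:
    """Repeat the study with fresh seeds; summarize key statistics.

    Returns the per-replicate frame and a summary with rejection rates
    (binomial 95% CIs) and effect-size means.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rows = []
    for rep in range(n_reps):
        seed = config.rng_seed + rep
        cfg = replace(config, rng_seed=seed, cohort=replace(config.cohort, rng_seed=seed))
        rep_report = run_study(cfg)
        t = rep_report["tests"]
        rows.append(
            {
                "replicate": rep,
                "seed": seed,
                "between_p_additive": t["criterion_mixed_anova_additive"]["between"]["p_value"],
                "between_p_dominant": t["criterion_mixed_anova_dominant"]["between"]["p_value"],
                "dprime_between_p_additive": t["dprime_mixed_ancova_additive"]["between"]["p_value"],
                "dominant_t_p": t["mean_criterion_dominant_t"]["p_value"],
                "cohens_d_AA_vs_GG": rep_report["cohens_d_AA_vs_GG"],
                "cohens_d_dominant": rep_report["cohens_d_dominant"],
            }
        )
    df = pd.DataFrame(rows)
    summary: dict = {"n_reps": n_reps, "alpha": alpha}
    for col in df.columns:
        if col.endswith("_p") or "_p_" in col:
            k = int((df[col] < alpha).sum())
            lo, hi = _binom_ci(k, n_reps)
            summary[f"reject_{col}"] = {"rate": k / n_reps, "ci95": [lo, hi]}
        elif col.startswith("cohens_d"):
            summary[f"mean_{col}"] = float(df[col].mean())
    return df, summary


def _binom_ci(k: int, n: int) -> tuple[float, float]:
    from scipy.stats import beta

    lo = float(beta.ppf(0.025, k, n - k + 1)) if k > 0 else 0.0
    hi = float(beta.ppf(0.975, k + 1, n - k)) if k < n else 1.0
    return lo, hi
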