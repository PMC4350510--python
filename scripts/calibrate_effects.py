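"""Regenerate the effect-size calibration table.

Monte-Carlo sweep over agent reward-learning rates: for each rate, many
participants (with perceptual sensitivity drawn as in cohort construction)
play a full default session, and the mean and SD of their scored mean
criterion are tabulated.  The resulting table, shipped at
``src/rewardbias/data/effect_calibration.json``, is what
``rewardbias.cohort.calibrated_genotype_effect`` inverts to choose
per-genotype learning rates for requested standardized effects.

Usage:  python scripts/calibrate_effects.py [--sessions 400] [--seed 20140]
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

import numpy as np

from rewardbias.agents import AgentParams
from rewardbias.cohort import DEFAULT_SENSITIVITY_MEAN, DEFAULT_SENSITIVITY_SD
from rewardbias.pipeline import run_agent_session
from rewardbias.sdt import score_participant
from rewardbias.task import LONG, SHORT, ScheduleConfig
from rewardbias._rng import seed31

GRID = [-0.004, -0.002, 0.0, 0.002, 0.004, 0.006, 0.008, 0.010]


def sweep_point(lr: float, n_sessions: int, seed: int) -> tuple[float, float]:
    vals = []
    ss = np.random.SeedSequence(seed)
    for i, child in enumerate(ss.spawn(n_sessions)):
        rng = np.random.default_rng(child)
        rich = LONG if i % 2 == 0 else SHORT
        sens = max(0.2, rng.normal(DEFAULT_SENSITIVITY_MEAN, DEFAULT_SENSITIVITY_SD))
        params = AgentParams(perceptual_sensitivity=sens, reward_learning_rate=lr)
        result = run_agent_session(
            params, ScheduleConfig(), rich, seed31(child)
        )
        vals.append(score_participant(result, rich).mean_criterion)
    v = np.asarray(vals)
    return float(v.mean()), float(v.std(ddof=1))


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--sessions", type=int, default=400)
    ap.add_argument("--seed", type=int, default=20140)
    ap.add_argument(
        "--out",
        type=Path,
        default=Path(__file__).resolve().parents[1]
        / "src/rewardbias/data/effect_calibration.json",
    )
    args = ap.parse_args()

    grid = []
    for j, lr in enumerate(GRID):
        mean, sd = sweep_point(lr, args.sessions, args.seed + j)
        grid.append({"learning_rate": lr, "mean_criterion": mean, "sd_criterion": sd})
        print(f"lr={lr:+.4f}  mean={mean:+.4f}  sd={sd:.4f}")

    table = {
        "description": (
            "Scored participant mean criterion vs agent reward-learning rate, "
            "default schedule and agent, sensitivity drawn as in build_cohort"
        ),
        "n_sessions_per_point": args.sessions,
        "seed": args.seed,
        "sensitivity_mean": DEFAULT_SENSITIVITY_MEAN,
        "sensitivity_sd": DEFAULT_SENSITIVITY_SD,
        "grid": grid,
    }
    args.out.write_text(json.dumps(table, indent=1))
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
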