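"""Configuration, serialization, seeding and pipeline orchestration.

Behavioral data travel as flat CSV tables with columns
(participant_id, group, block_index, trial_index, action, reward);
configurations, designs, and reports are JSON. A full run writes its
artifacts under ``<output_dir>/runs/<config hash>/`` with every artifact
stamped by the configuration hash and the global seed, from which all
sub-seeds are derived deterministically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import pandas as pd

from .critic import (
    CriticConfig,
    CriticEnsemble,
    amortized_posterior,
    save_critic,
    train_ensemble,
)
from .design import (
    BOConfig,
    DesignSpace,
    evaluate_objective,
    optimize_design,
    sample_baseline_design,
    utility_surface,
)
from .evaluation import confusion_matrix, parameter_recovery
from .models import BehaviorBlock, Design, ExperimentData, Model
from .priors import PriorSpec, default_prior, sample_params

__all__ = [
    "RunConfig",
    "read_behavior_csv",
    "write_behavior_csv",
    "experiments_to_table",
    "table_to_experiments",
    "derive_seeds",
    "config_hash",
    "run_pipeline",
]

logger = logging.getLogger("banditboed")

BEHAVIOR_COLUMNS = ("participant_id", "group", "block_index", "trial_index",
                    "action", "reward")


@dataclass(frozen=True)
class RunConfig:
    """Everything one optimization-and-validation run needs."""

    goal: str = "MD"
    n_arms: int = 3
    n_trials: int = 30
    n_blocks: int = 2
    model: Optional[str] = None  # PE only
    seed: int = 0
    output_dir: str = "runs"
    ensemble_size: int = 10
    n_train: int = 10000
    n_validation: int = 300
    critic: CriticConfig = field(default_factory=CriticConfig)
    bo: BOConfig = field(default_factory=BOConfig)

    def __post_init__(self) -> None:
        if str(self.goal).upper() not in ("MD", "PE"):
            raise ValueError("goal must be 'MD' or 'PE'")
        if str(self.goal).upper() == "PE" and self.model is None:
            raise ValueError("parameter estimation requires a model")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def derive_seeds(global_seed: int, n: int) -> List[int]:
    """Deterministic child seeds (< 2^31) from one global seed."""
    ss = np.random.SeedSequence(global_seed)
    return [int(s) % (2 ** 31) for s in ss.generate_state(n)]


# ---------------------------------------------------------------------------
# Behavioral tables
# ---------------------------------------------------------------------------


def write_behavior_csv(table: pd.DataFrame, path: str) -> None:
    missing = [c for c in BEHAVIOR_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"table is missing columns: {missing}")
    table.loc[:, list(BEHAVIOR_COLUMNS)].to_csv(path, index=False)


def read_behavior_csv(path: str) -> pd.DataFrame:
    """Read and validate a behavioral table; errors cite 1-based file lines."""
    df = pd.read_csv(path)
    missing = [c for c in BEHAVIOR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns: {missing}")
    if len(df) == 0:
        return df.loc[:, list(BEHAVIOR_COLUMNS)]
    for col in ("block_index", "trial_index", "action", "reward"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != vals.round())
        if bad.any():
            line = int(df.index[bad][0]) + 2  # header is line 1
            raise ValueError(
                f"{path}, line {line}: column '{col}' must be an integer")
        df[col] = vals.astype(int)
    bad = ~df["reward"].isin((0, 1))
    if bad.any():
        line = int(df.index[bad][0]) + 2
        raise ValueError(f"{path}, line {line}: reward must be 0 or 1")
    bad = df["action"] < 0
    if bad.any():
        line = int(df.index[bad][0]) + 2
        raise ValueError(f"{path}, line {line}: action must be >= 0")
    for (pid, block), grp in df.groupby(["participant_id", "block_index"]):
        t = np.sort(grp["trial_index"].to_numpy())
        if not np.array_equal(t, np.arange(len(t))):
            raise ValueError(
                f"{path}: participant {pid} block {block} trial indices are "
                "not contiguous 0..T-1")
    return df.loc[:, list(BEHAVIOR_COLUMNS)]


def experiments_to_table(experiments, participant_ids=None,
                         group: str = "simulated") -> pd.DataFrame:
    rows = []
    for i, exp in enumerate(experiments):
        pid = i if participant_ids is None else participant_ids[i]
        for b, blk in enumerate(exp.blocks):
            for t in range(blk.n_trials):
                rows.append((pid, group, b, t, int(blk.actions[t]),
                             int(blk.rewards[t])))
    return pd.DataFrame(rows, columns=list(BEHAVIOR_COLUMNS))


def table_to_experiments(table: pd.DataFrame) -> dict:
    """{participant_id: ExperimentData} from a validated behavioral table."""
    out = {}
    for pid, grp in table.groupby("participant_id"):
        blocks = []
        for b in sorted(grp["block_index"].unique()):
            sub = grp[grp["block_index"] == b].sort_values("trial_index")
            blocks.append(BehaviorBlock(sub["action"].to_numpy(),
                                        sub["reward"].to_numpy()))
        out[pid] = ExperimentData(tuple(blocks))
    return out


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def run_pipeline(config: RunConfig) -> dict:
    """Optimize the design, train the final ensemble, validate, persist.

    Returns a summary dict; artifacts land in
    ``<output_dir>/runs/<hash>/{designs,critics,reports}``. Any stage failure
    leaves earlier artifacts on disk and is re-raised naming the stage.
    """
    cfg_hash = config_hash(config)
    base = os.path.join(config.output_dir, "runs", cfg_hash)
    for sub in ("designs", "critics", "reports"):
        os.makedirs(os.path.join(base, sub), exist_ok=True)
    seeds = derive_seeds(config.seed, 4)
    goal = str(config.goal).upper()
    model = None if config.model is None else Model.parse(config.model)
    prior = default_prior()
    stamp = {"config_hash": cfg_hash, "seed": config.seed}

    with open(os.path.join(base, "config.json"), "w") as fh:
        json.dump({**config.to_dict(), **stamp}, fh, indent=2, default=str)

    stage = "optimize"
    try:
        rng = np.random.default_rng(seeds[0])
        space = DesignSpace(n_blocks=config.n_blocks, n_arms=config.n_arms)

        def objective(design: Design):
            est = evaluate_objective(
                design, goal, prior, rng, model=model, sim_n=config.n_train,
                critic_config=config.critic, n_trials=config.n_trials)
            logger.info("design=%s mi=%.4f se=%.4f",
                        np.round(design.flatten(), 3).tolist(),
                        est.value, est.se)
            return est

        result = optimize_design(objective, space, config.bo, rng)
        with open(os.path.join(base, "designs", "optimal.json"), "w") as fh:
            json.dump({**result.to_dict(), **stamp}, fh, indent=2)
        surface = utility_surface(result)
        surface.grid().to_csv(os.path.join(base, "designs", "surface.csv"),
                              index=False)

        stage = "ensemble"
        ens_rng = np.random.default_rng(seeds[1])
        ensemble = train_ensemble(
            result.best_design, goal, prior, ens_rng, config.critic,
            n_members=config.ensemble_size, n_train=config.n_train,
            model=model, n_trials=config.n_trials)
        for i, member in enumerate(ensemble.members):
            save_critic(member, os.path.join(base, "critics", f"member{i}"))

        stage = "validate"
        val_rng = np.random.default_rng(seeds[2])
        report = {**stamp, "best_design": result.best_design.blocks.tolist(),
                  "best_mi": result.best_value, "best_mi_se": result.best_se}
        if goal == "MD":
            cm = confusion_matrix(result.best_design, prior, ensemble,
                                  config.n_validation, val_rng,
                                  n_trials=config.n_trials)
            report["confusion_counts"] = cm.counts.tolist()
            report["mean_diagonal"] = cm.mean_diagonal
        else:
            truths = [sample_params(model, prior, val_rng)
                      for _ in range(min(config.n_validation, 50))]
            rec = parameter_recovery(model, result.best_design, prior,
                                     ensemble, truths, val_rng,
                                     n_trials=config.n_trials)
            report["coverage"] = rec.coverage.tolist()
            report["bias"] = rec.bias.tolist()
            report["mean_posterior_sd"] = rec.mean_posterior_sd.tolist()
        with open(os.path.join(base, "reports", "validation.json"),
                  "w") as fh:
            json.dump(report, fh, indent=2)
        return report
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"pipeline failed during stage '{stage}': {exc}"
                           ) from exc
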