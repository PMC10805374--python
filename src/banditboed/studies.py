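"""Scaled-down in-silico validation studies.

Two canned comparisons of the reported optimal designs against Beta(2, 2)
baseline designs, sized to run on a desk machine:

* model discrimination: mean diagonal of the MAP model-recovery confusion
  matrix at the optimal two-block design versus baseline designs;
* parameter estimation (WSLTS): average marginal posterior standard
  deviation per parameter at the optimal three-block design versus baselines.

The optimal designs are the reward-probability settings found for the
3-armed, 30-trial task: blocks [0, 0, 0.6] and [1, 1, 0] for model
discrimination, and [0, 1, 0], [0, 1, 1], [1, 0, 1] for WSLTS parameter
estimation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from .critic import (
    CriticConfig,
    amortized_parameter_weights,
    encode_experiments,
    train_ensemble,
)
from .design import sample_baseline_design
from .evaluation import confusion_matrix
from .models import Design, Model, params_to_array
from .priors import PriorSpec, default_prior, sample_params
from .simulate import simulate_experiments_batch

__all__ = [
    "OPTIMAL_MD_DESIGN",
    "OPTIMAL_PE_WSLTS_DESIGN",
    "MDStudyResult",
    "PEStudyResult",
    "md_recovery_study",
    "pe_recovery_study",
]

OPTIMAL_MD_DESIGN = Design(np.array([[0.0, 0.0, 0.6],
                                     [1.0, 1.0, 0.0]]))
OPTIMAL_PE_WSLTS_DESIGN = Design(np.array([[0.0, 1.0, 0.0],
                                           [0.0, 1.0, 1.0],
                                           [1.0, 0.0, 1.0]]))

_STUDY_CONFIG = CriticConfig(epochs=30, batch_size=256)


@dataclass(frozen=True)
class MDStudyResult:
    """Model-recovery comparison: optimal versus baseline designs."""

    optimal_diagonal: float
    baseline_diagonals: np.ndarray

    @property
    def baseline_mean(self) -> float:
        return float(self.baseline_diagonals.mean())

    @property
    def optimal_wins(self) -> bool:
        return self.optimal_diagonal > self.baseline_mean


@dataclass(frozen=True)
class PEStudyResult:
    """Posterior-concentration comparison for WSLTS parameter estimation.

    Per-parameter posterior standard deviations are reported raw and, for
    the headline comparison, normalized by the prior standard deviation of
    each parameter (so that parameters on different scales — the reshaping
    exponent spans [0, 5], the stay/shift probabilities [0, 1] — contribute
    comparably and an unidentified parameter contributes 1 under any design).
    """

    optimal_sd: np.ndarray  # (3,) mean posterior sd per parameter
    baseline_sd: np.ndarray  # (n_baselines, 3)
    prior_sd: np.ndarray  # (3,) prior marginal sd per parameter

    @property
    def baseline_mean_sd(self) -> np.ndarray:
        return self.baseline_sd.mean(axis=0)

    @property
    def optimal_normalized(self) -> float:
        """Average over parameters of posterior SD / prior SD at the optimum."""
        return float((self.optimal_sd / self.prior_sd).mean())

    @property
    def baseline_normalized(self) -> float:
        return float((self.baseline_mean_sd / self.prior_sd).mean())

    @property
    def optimal_wins(self) -> bool:
        return self.optimal_normalized < self.baseline_normalized


def _md_diagonal(design: Design, prior: PriorSpec, seed: int, n_train: int,
                 n_members: int, n_per_model: int, n_trials: int,
                 config: CriticConfig) -> float:
    rng = np.random.default_rng(seed)
    ensemble = train_ensemble(design, "MD", prior, rng, config,
                              n_members=n_members, n_train=n_train,
                              n_trials=n_trials)
    cm = confusion_matrix(design, prior, ensemble, n_per_model, rng,
                          n_trials=n_trials)
    return cm.mean_diagonal


def md_recovery_study(seed: int, prior: Optional[PriorSpec] = None,
                      n_train: int = 4000, n_members: int = 2,
                      n_per_model: int = 300, n_baselines: int = 5,
                      n_trials: int = 30,
                      config: CriticConfig = _STUDY_CONFIG) -> MDStudyResult:
    """MAP model recovery at the optimal MD design versus baselines.

    For the optimal design and each Beta(2, 2) baseline design: train a
    small ensemble, simulate ``n_per_model`` experiments per generating
    model, and record the row-normalized confusion-matrix mean diagonal.
    """
    prior = prior or default_prior()
    seeds = np.random.SeedSequence(seed).generate_state(n_baselines + 2)
    opt = _md_diagonal(OPTIMAL_MD_DESIGN, prior, int(seeds[0] % 2 ** 31),
                       n_train, n_members, n_per_model, n_trials, config)
    brng = np.random.default_rng(int(seeds[1] % 2 ** 31))
    base = []
    for i in range(n_baselines):
        bd = sample_baseline_design(OPTIMAL_MD_DESIGN.n_blocks,
                                    OPTIMAL_MD_DESIGN.n_arms, brng)
        base.append(_md_diagonal(bd, prior, int(seeds[i + 2] % 2 ** 31),
                                 n_train, n_members, n_per_model, n_trials,
                                 config))
    return MDStudyResult(opt, np.asarray(base))


def _pe_mean_sd(design: Design, prior: PriorSpec, seed: int, n_train: int,
                n_members: int, n_subjects: int, n_prior_samples: int,
                n_trials: int, config: CriticConfig) -> np.ndarray:
    rng = np.random.default_rng(seed)
    ensemble = train_ensemble(design, "PE", prior, rng, config,
                              n_members=n_members, n_train=n_train,
                              model=Model.WSLTS, n_trials=n_trials)
    truths = sample_params(Model.WSLTS, prior, rng, n=n_subjects)
    acts, rews = simulate_experiments_batch(Model.WSLTS, truths, design,
                                            n_trials, rng, n_subjects)
    y = encode_experiments(acts, rews, design.n_arms)
    theta = params_to_array(sample_params(Model.WSLTS, prior, rng,
                                          n=n_prior_samples))
    W = amortized_parameter_weights(ensemble, y, theta, prior)
    means = W @ theta
    second = W @ theta ** 2
    sds = np.sqrt(np.maximum(second - means ** 2, 0.0))
    return sds.mean(axis=0)


def pe_recovery_study(seed: int, prior: Optional[PriorSpec] = None,
                      n_train: int = 4000, n_members: int = 2,
                      n_subjects: int = 200, n_prior_samples: int = 2000,
                      n_baselines: int = 5, n_trials: int = 30,
                      config: CriticConfig = _STUDY_CONFIG) -> PEStudyResult:
    """WSLTS posterior concentration at the optimal PE design vs baselines.

    For each design: train a small PE ensemble, simulate ``n_subjects``
    experiments at prior-drawn ground truths, and average the marginal
    posterior standard deviation of each of the three WSLTS parameters.
    """
    prior = prior or default_prior()
    seeds = np.random.SeedSequence(seed).generate_state(n_baselines + 2)
    opt = _pe_mean_sd(OPTIMAL_PE_WSLTS_DESIGN, prior,
                      int(seeds[0] % 2 ** 31), n_train, n_members,
                      n_subjects, n_prior_samples, n_trials, config)
    brng = np.random.default_rng(int(seeds[1] % 2 ** 31))
    base = []
    for i in range(n_baselines):
        bd = sample_baseline_design(OPTIMAL_PE_WSLTS_DESIGN.n_blocks,
                                    OPTIMAL_PE_WSLTS_DESIGN.n_arms, brng)
        base.append(_pe_mean_sd(bd, prior, int(seeds[i + 2] % 2 ** 31),
                                n_train, n_members, n_subjects,
                                n_prior_samples, n_trials, config))
    bounds = prior.bounds(Model.WSLTS)
    prior_sd = (bounds[:, 1] - bounds[:, 0]) / np.sqrt(12.0)
    return PEStudyResult(opt, np.asarray(base), prior_sd)
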