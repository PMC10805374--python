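"""Small exactly solvable bandit problems used for verification.

These fix point-mass parameter priors so the exact enumeration oracle applies,
giving ground-truth mutual information and posteriors against which the
learned critic is checked.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np

from .models import Design, Model
from .priors import PriorSpec, default_prior

__all__ = ["discrimination_toy", "certain_reward_toy", "TOY_EXACT_MI_NATS"]

# exact MI of the certain-reward toy: (3/4) ln(4/3), from hand enumeration
# over the 4 possible action sequences
TOY_EXACT_MI_NATS = 0.75 * float(np.log(4.0 / 3.0))


def _point_mass_prior(model_prior) -> PriorSpec:
    """Uniform-vs-stay pair: AEG(eps=1, rho=0) against WSLTS(gw=1, gl=1, tau=1).

    The AEG setting is the uniformly random policy; the WSLTS setting chooses
    uniformly on trial 1 (symmetric beliefs) and stays forever after a reward.
    """
    return (default_prior()
            .with_model_prior(model_prior)
            .with_ranges(Model.WSLTS, gamma_win=(1.0, 1.0),
                         gamma_lose=(1.0, 1.0), tau=(1.0, 1.0))
            .with_ranges(Model.AEG, epsilon=(1.0, 1.0), rho=(0.0, 0.0)))


def certain_reward_toy() -> Tuple[Design, PriorSpec, int]:
    """2 arms, 2 trials, certain rewards; uniform-random vs stay policy.

    Exact MI is (3/4) ln(4/3) ~ 0.2158 nats. Returns (design, prior, T).
    """
    return (Design(np.array([[1.0, 1.0]])),
            _point_mass_prior([0.5, 0.5, 0.0]), 2)


def discrimination_toy(arm_probs=(0.8, 0.2), n_trials: int = 3
                       ) -> Tuple[Design, PriorSpec, int]:
    """2 arms, 3 trials, stochastic rewards: (2K)^T = 64 outcome sequences."""
    return (Design(np.array([list(arm_probs)])),
            _point_mass_prior([0.5, 0.5, 0.0]), int(n_trials))
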