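"""Simulation of bandit behavior under the three models.

``simulate_block``/``simulate_experiment`` are the single-learner entry
points; ``simulate_blocks_batch`` runs many independent learners in parallel
(vectorized across simulations, looping only over trials), which is what the
training-set generation and the in-silico validation studies use. The
single-learner path delegates to the batch path, so both are one code path;
the exact-likelihood module provides the independent second implementation
of the same behavioral rules.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np

from .models import (
    AEGParams,
    BehaviorBlock,
    Design,
    ExperimentData,
    GLSParams,
    Model,
    WSLTSParams,
    aeg_policy_batch,
    gls_policy_batch,
    gls_transition,
    prob_best_arm_batch,
    wslts_policy_batch,
)

__all__ = ["simulate_block", "simulate_experiment", "simulate_blocks_batch"]


def _sample_rows(pi: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw one categorical sample per row of a probability matrix."""
    cum = np.cumsum(pi, axis=1)
    u = rng.random(pi.shape[0]) * cum[:, -1]
    return np.minimum((cum < u[:, None]).sum(axis=1), pi.shape[1] - 1)


def simulate_blocks_batch(model, params, arm_probs, n_trials: int,
                          rng: np.random.Generator,
                          n_sims: Optional[int] = None
                          ) -> Tuple[np.ndarray, np.ndarray]:
    """Simulate many independent single-block learners at once.

    ``params`` fields may be scalars (shared) or length-n arrays (one learner
    per row, e.g. prior draws). Returns (actions, rewards), each (n, T).
    Each learner starts from a fresh Beta(1, 1) belief per arm.
    """
    model = Model.parse(model)
    arm_probs = np.asarray(arm_probs, dtype=float)
    if np.any(arm_probs < 0) or np.any(arm_probs > 1):
        raise ValueError("arm probabilities must lie in [0, 1]")
    K = arm_probs.shape[0]
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if n_sims is None:
        sizes = [np.size(getattr(params, f)) for f in type(params).fields
                 if np.ndim(getattr(params, f)) > 0]
        n_sims = max(sizes) if sizes else 1
    n = int(n_sims)

    alpha = np.ones((n, K))
    beta = np.ones((n, K))
    actions = np.empty((n, n_trials), dtype=np.int64)
    rewards = np.empty((n, n_trials), dtype=np.int64)
    prev_a: Optional[np.ndarray] = None
    prev_r: Optional[np.ndarray] = None
    latent: Optional[np.ndarray] = None

    for t in range(n_trials):
        if model is Model.WSLTS:
            q = prob_best_arm_batch(alpha, beta)
            pi = wslts_policy_batch(params, q, prev_a, prev_r)
        elif model is Model.AEG:
            pi = aeg_policy_batch(params, alpha, beta, prev_a)
        else:
            p_explore = np.broadcast_to(
                np.asarray(gls_transition(params, latent, prev_r)), (n,))
            latent = (rng.random(n) < p_explore).astype(np.int64)
            pi = gls_policy_batch(alpha, beta, latent)
        a = _sample_rows(pi, rng)
        r = (rng.random(n) < arm_probs[a]).astype(np.int64)
        idx = np.arange(n)
        alpha[idx, a] += r
        beta[idx, a] += 1 - r
        actions[:, t] = a
        rewards[:, t] = r
        prev_a, prev_r = a, r
    return actions, rewards


def simulate_block(model, params, arm_probs, n_trials: int,
                   rng: np.random.Generator) -> BehaviorBlock:
    """Simulate one block of behavior for a single learner.

    The learner's Beta-Bernoulli belief is reset at the block start; for the
    GLS model the latent explore/exploit state is drawn each trial from its
    transition model before the action.
    """
    actions, rewards = simulate_blocks_batch(
        model, params, arm_probs, n_trials, rng, n_sims=1)
    return BehaviorBlock(actions[0], rewards[0])


def simulate_experiment(model, params, design: Design,
                        rng: np.random.Generator,
                        n_trials: int = 30) -> ExperimentData:
    """Simulate all blocks of a design independently (fresh learner each)."""
    blocks = [simulate_block(model, params, design.blocks[b], n_trials, rng)
              for b in range(design.n_blocks)]
    return ExperimentData(tuple(blocks))


def simulate_experiments_batch(model, params, design: Design, n_trials: int,
                               rng: np.random.Generator, n_sims: int
                               ) -> Tuple[np.ndarray, np.ndarray]:
    """(n, B, T) actions and rewards for many learners at one design."""
    acts = np.empty((n_sims, design.n_blocks, n_trials), dtype=np.int64)
    rews = np.empty_like(acts)
    for b in range(design.n_blocks):
        a, r = simulate_blocks_batch(
            model, params, design.blocks[b], n_trials, rng, n_sims=n_sims)
        acts[:, b, :] = a
        rews[:, b, :] = r
    return acts, rews
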