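"""Exact likelihoods, posteriors, and mutual information for small bandit problems.

Everything here works by explicit computation — per-trial likelihood products,
full enumeration of outcome sequences, and grid discretization of parameter
priors — and is therefore limited to desk-scale problems (a budget of 10^6
enumerated outcome sequences). It provides ground truth against which the
learned mutual-information critic and amortized posteriors are verified; it
is not a production inference path.

All information quantities are in nats.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy.special import expit

from .models import (
    BehaviorBlock,
    Design,
    ExperimentData,
    GLSParams,
    Model,
    PARAM_CLASSES,
    _greedy,
    aeg_policy_batch,
    params_from_array,
    prob_best_arm_batch,
    wslts_policy_batch,
)
from .priors import PriorSpec, sample_params

__all__ = [
    "block_log_likelihood",
    "block_log_likelihood_batch",
    "gls_path_enumeration_log_likelihood",
    "marginal_likelihood",
    "exact_model_posterior",
    "exact_mi",
    "ExactMIResult",
    "MarginalLikelihood",
    "ENUMERATION_BUDGET",
]

ENUMERATION_BUDGET = 10 ** 6


def _reward_log_prob(action: int, reward: int, arm_probs: np.ndarray) -> float:
    p = arm_probs[action] if reward else 1.0 - arm_probs[action]
    return math.log(p) if p > 0 else -math.inf


def block_log_likelihood_batch(model, params, block: BehaviorBlock,
                               arm_probs, n: Optional[int] = None
                               ) -> np.ndarray:
    """Log p(y_block | theta, d) for a batch of parameter vectors.

    The observed block fixes the learner-state trajectory, so the likelihood
    is a product over trials of policy probabilities (marginalized over the
    two latent states by a forward recursion for GLS) times the Bernoulli
    reward probabilities. Returns a length-n vector; -inf marks impossible
    sequences. This walks the behavioral rules trial by trial and is the
    second, independent implementation of the simulators' dynamics.
    """
    model = Model.parse(model)
    arm_probs = np.asarray(arm_probs, dtype=float)
    K = arm_probs.shape[0]
    if block.n_trials and int(block.actions.max()) >= K:
        raise ValueError("block contains actions outside the design's arms")
    if n is None:
        sizes = [np.size(getattr(params, f)) for f in type(params).fields
                 if np.ndim(getattr(params, f)) > 0]
        n = max(sizes) if sizes else 1
    T = block.n_trials

    reward_ll = 0.0
    for t in range(T):
        reward_ll += _reward_log_prob(
            int(block.actions[t]), int(block.rewards[t]), arm_probs)
    if not math.isfinite(reward_ll):
        return np.full(n, -np.inf)

    if model is Model.GLS:
        policy_ll = _gls_forward_recursion(params, block, K, n)
    else:
        alpha = np.ones(K)
        beta = np.ones(K)
        policy_ll = np.zeros(n)
        prev_a = prev_r = None
        for t in range(T):
            a_t = int(block.actions[t])
            if model is Model.WSLTS:
                q = np.broadcast_to(
                    prob_best_arm_batch(alpha[None, :], beta[None, :]),
                    (n, K))
                pi = wslts_policy_batch(params, q, prev_a, prev_r)
            else:
                pi = aeg_policy_batch(
                    params, np.broadcast_to(alpha, (n, K)),
                    np.broadcast_to(beta, (n, K)), prev_a)
            with np.errstate(divide="ignore"):
                policy_ll = policy_ll + np.log(pi[:, a_t])
            r_t = int(block.rewards[t])
            if r_t:
                alpha[a_t] += 1
            else:
                beta[a_t] += 1
            prev_a = np.full(n, a_t)
            prev_r = np.full(n, r_t)
    return policy_ll + reward_ll


def _gls_forward_recursion(params: GLSParams, block: BehaviorBlock, K: int,
                           n: int) -> np.ndarray:
    """Log policy likelihood marginalized over latent paths (2-state forward).

    w[:, z] tracks the joint probability of latent state z (0 = exploit,
    1 = explore) and the actions observed so far, rescaled every trial to
    avoid underflow; the accumulated scales give the log likelihood.
    """
    T = block.n_trials
    b0 = np.broadcast_to(np.asarray(params.beta0, dtype=float), (n,)).astype(float)
    bz = np.broadcast_to(np.asarray(params.beta_z, dtype=float), (n,)).astype(float)
    br = np.broadcast_to(np.asarray(params.beta_r, dtype=float), (n,)).astype(float)
    alpha = np.ones(K)
    beta = np.ones(K)
    loglik = np.zeros(n)
    w = np.zeros((n, 2))
    prev_r = 0
    for t in range(T):
        a_t = int(block.actions[t])
        greedy = _greedy(alpha[None, :], beta[None, :])[0]
        pi_exploit = greedy[a_t]
        pi_explore = 1.0 / K
        if t == 0:
            pe = expit(b0)
            w = np.stack([(1.0 - pe) * pi_exploit, pe * pi_explore], axis=1)
        else:
            pe_from_exploit = expit(b0 + br * prev_r)
            pe_from_explore = expit(b0 + bz + br * prev_r)
            stay_exploit = w[:, 0] * (1 - pe_from_exploit) \
                + w[:, 1] * (1 - pe_from_explore)
            go_explore = w[:, 0] * pe_from_exploit + w[:, 1] * pe_from_explore
            w = np.stack([stay_exploit * pi_exploit,
                          go_explore * pi_explore], axis=1)
        s = w.sum(axis=1)
        zero = s <= 0.0
        with np.errstate(divide="ignore"):
            loglik = np.where(zero, -np.inf, loglik + np.log(np.where(zero, 1.0, s)))
        w = np.where(zero[:, None], 0.0, w / np.where(s[:, None] == 0.0, 1.0,
                                                      s[:, None]))
        r_t = int(block.rewards[t])
        if r_t:
            alpha[a_t] += 1
        else:
            beta[a_t] += 1
        prev_r = r_t
    return loglik


def gls_path_enumeration_log_likelihood(params: GLSParams,
                                        block: BehaviorBlock,
                                        arm_probs) -> float:
    """Brute-force GLS log likelihood summing over all 2^T latent paths.

    Exponential-cost verification oracle for the forward recursion.
    """
    arm_probs = np.asarray(arm_probs, dtype=float)
    K = arm_probs.shape[0]
    T = block.n_trials
    b0 = float(np.asarray(params.beta0))
    bz = float(np.asarray(params.beta_z))
    br = float(np.asarray(params.beta_r))
    total = 0.0
    for path in itertools.product((0, 1), repeat=T):
        p = 1.0
        alpha = np.ones(K)
        beta = np.ones(K)
        prev_z = prev_r = None
        for t, z_t in enumerate(path):
            if t == 0:
                pe = expit(b0)
            else:
                pe = expit(b0 + bz * prev_z + br * prev_r)
            p *= pe if z_t else (1.0 - pe)
            a_t = int(block.actions[t])
            r_t = int(block.rewards[t])
            if z_t:
                p *= 1.0 / K
            else:
                p *= _greedy(alpha[None, :], beta[None, :])[0][a_t]
            p_r = arm_probs[a_t] if r_t else 1.0 - arm_probs[a_t]
            p *= p_r
            if r_t:
                alpha[a_t] += 1
            else:
                beta[a_t] += 1
            prev_z, prev_r = z_t, r_t
        total += p
    return math.log(total) if total > 0 else -math.inf


def block_log_likelihood(model, params, block: BehaviorBlock,
                         arm_probs) -> float:
    """Scalar log p(y_block | theta, d) for a single parameter setting."""
    return float(block_log_likelihood_batch(
        model, params, block, arm_probs, n=1)[0])


@dataclass(frozen=True)
class MarginalLikelihood:
    """Monte-Carlo marginal likelihood with its standard error."""

    value: float
    se: float
    n_draws: int


def marginal_likelihood(model, block: BehaviorBlock, arm_probs,
                        prior: PriorSpec, n_draws: int,
                        rng: np.random.Generator) -> MarginalLikelihood:
    """p(y_block | m, d) by Monte-Carlo averaging over prior draws."""
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    params = sample_params(model, prior, rng, n=n_draws)
    ll = block_log_likelihood_batch(model, params, block, arm_probs,
                                    n=n_draws)
    p = np.where(np.isfinite(ll), np.exp(ll), 0.0)
    se = float(p.std(ddof=1) / math.sqrt(n_draws)) if n_draws > 1 else 0.0
    return MarginalLikelihood(float(p.mean()), se, n_draws)


def exact_model_posterior(data: ExperimentData, design: Design,
                          prior: PriorSpec, n_draws: int,
                          rng: np.random.Generator) -> np.ndarray:
    """p(m | y, d) over the three models by Monte-Carlo marginalization.

    The parameter vector is shared across blocks (one learner per
    experiment), so the marginal likelihood of the full experiment averages
    the product of per-block likelihoods over prior draws of theta. With no
    data the prior is returned.
    """
    if data.n_blocks != design.n_blocks:
        raise ValueError("data and design must have the same number of blocks")
    if data.n_blocks == 0:
        return prior.model_prior.copy()
    evidence = np.zeros(3)
    for m in Model:
        if prior.model_prior[m] == 0.0:
            continue
        params = sample_params(m, prior, rng, n=n_draws)
        total = np.zeros(n_draws)
        for b, block in enumerate(data.blocks):
            total += block_log_likelihood_batch(
                m, params, block, design.blocks[b], n=n_draws)
        evidence[m] = np.where(np.isfinite(total), np.exp(total), 0.0).mean()
    post = prior.model_prior * evidence
    s = post.sum()
    if s == 0.0:
        return prior.model_prior.copy()
    return post / s


# ---------------------------------------------------------------------------
# Exact mutual information by full outcome enumeration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExactMIResult:
    """Exact mutual information with its full enumeration tables.

    mi: mutual information in nats (>= 0).
    weights: prior weight of each hypothesis v (model or grid point).
    likelihoods: (V, M) outcome probabilities p(y | v, d); rows sum to 1.
    marginal: (M,) outcome probabilities p(y | d).
    posteriors: (M, V) exact posteriors p(v | y, d) per outcome.
    contributions: per-outcome contribution to the MI sum.
    actions / rewards: (M, B, T) enumerated outcome sequences.
    hypotheses: list of (Model, params) pairs aligned with weights.
    """

    mi: float
    weights: np.ndarray
    likelihoods: np.ndarray
    marginal: np.ndarray
    posteriors: np.ndarray
    contributions: np.ndarray
    actions: np.ndarray
    rewards: np.ndarray
    hypotheses: tuple
    n_trials: int
    n_arms: int

    def model_posteriors(self) -> np.ndarray:
        """(M, 3) exact posterior over the model indicator per outcome."""
        out = np.zeros((self.posteriors.shape[0], 3))
        for i, (m, _) in enumerate(self.hypotheses):
            out[:, Model.parse(m)] += self.posteriors[:, i]
        return out

    def outcome_index(self, data: "ExperimentData") -> int:
        """Row of the enumeration tables matching an observed experiment."""
        a = np.stack([b.actions for b in data.blocks])
        r = np.stack([b.rewards for b in data.blocks])
        match = np.all((self.actions == a[None]) & (self.rewards == r[None]),
                       axis=(1, 2))
        idx = np.flatnonzero(match)
        if idx.size != 1:
            raise ValueError("experiment not found in the enumeration table")
        return int(idx[0])

    def optimal_critic_values(self) -> np.ndarray:
        """(V, M) values of the analytically optimal critic.

        At the optimum of the variational bound the critic equals
        1 + log(p(v | y, d) / p(v)); -inf marks zero-posterior cells.
        """
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = self.posteriors.T / self.weights[:, None]
            return np.where(ratio > 0, 1.0 + np.log(
                np.where(ratio > 0, ratio, 1.0)), -np.inf)


def _enumerate_block(K: int, T: int) -> Tuple[np.ndarray, np.ndarray]:
    """All (actions, rewards) sequences of length T over K arms: (2K)^T rows."""
    symbols = list(itertools.product(range(K), (0, 1)))
    rows = list(itertools.product(symbols, repeat=T))
    arr = np.array(rows, dtype=np.int64)  # (M, T, 2)
    return arr[:, :, 0], arr[:, :, 1]


def _grid_values(lo: float, hi: float, points: int) -> np.ndarray:
    if hi <= lo:
        return np.array([lo])
    return np.linspace(lo, hi, points)


def _build_hypotheses(goal: str, prior: PriorSpec, model, param_grid):
    """List of (Model, params) with prior weights; grids discretize priors."""
    points = 15 if param_grid is None else int(param_grid)
    hyps: List[tuple] = []
    weights: List[float] = []
    if str(goal).upper() == "PE":
        if model is None:
            raise ValueError("parameter estimation requires a model")
        models = [(Model.parse(model), 1.0)]
    else:
        models = [(m, float(prior.model_prior[m])) for m in Model
                  if prior.model_prior[m] > 0.0]
    for m, w_m in models:
        bounds = prior.bounds(m)
        axes = [_grid_values(lo, hi, points) for lo, hi in bounds]
        combos = list(itertools.product(*axes))
        for c in combos:
            hyps.append((m, params_from_array(m, np.array(c))))
            weights.append(w_m / len(combos))
    return hyps, np.array(weights)


def exact_mi(design: Design, goal: str, prior: PriorSpec, model=None,
             param_grid: Optional[int] = None,
             n_trials: int = 2) -> ExactMIResult:
    """Exact mutual information U(d) between v and y by full enumeration.

    For model discrimination v is the model indicator (parameters are fixed
    by degenerate prior ranges or marginalized on a uniform grid); for
    parameter estimation v is the parameter vector of ``model`` discretized
    on a uniform grid (``param_grid`` points per non-degenerate dimension,
    default 15) — the MI of the discretized prior is the reported oracle
    quantity. Feasible only when (2K)^(T*B) enumerated outcome sequences fit
    the budget.
    """
    hyps, weights = _build_hypotheses(goal, prior, model, param_grid)
    return exact_mi_from_hypotheses(design, hyps, weights, n_trials)


def exact_mi_from_hypotheses(design: Design, hypotheses, weights,
                             n_trials: int) -> ExactMIResult:
    """Exact MI for an explicit list of (model, params) hypotheses."""
    B, K = design.n_blocks, design.n_arms
    T = int(n_trials)
    n_outcomes = (2 * K) ** (T * B)
    if n_outcomes > ENUMERATION_BUDGET:
        raise ValueError(
            f"enumeration of (2K)^(T*B) = {n_outcomes} outcome sequences "
            f"exceeds the budget of {ENUMERATION_BUDGET}")
    weights = np.asarray(weights, dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9 or np.any(weights < 0):
        raise ValueError("hypothesis weights must form a simplex")
    V = len(hypotheses)

    block_actions, block_rewards = _enumerate_block(K, T)
    Mb = block_actions.shape[0]

    # (V, Mb) per-block log likelihoods for every block of the design,
    # vectorized over hypotheses of the same model
    per_block_ll = np.empty((B, V, Mb))
    by_model: dict = {}
    for i, (m, p) in enumerate(hypotheses):
        by_model.setdefault(Model.parse(m), []).append(i)
    for b in range(B):
        arm_probs = design.blocks[b]
        for m, idx in by_model.items():
            stacked = params_from_array(m, np.stack(
                [np.asarray([getattr(hypotheses[i][1], f)
                             for f in PARAM_CLASSES[m].fields])
                 for i in idx]))
            for j in range(Mb):
                blk = BehaviorBlock(block_actions[j], block_rewards[j])
                per_block_ll[b, idx, j] = block_log_likelihood_batch(
                    m, stacked, blk, arm_probs, n=len(idx))

    # joint outcomes across blocks: cartesian product of per-block indices
    combos = np.array(list(itertools.product(range(Mb), repeat=B)),
                      dtype=np.int64)  # (M, B)
    M = combos.shape[0]
    log_lik = np.zeros((V, M))
    for b in range(B):
        log_lik += per_block_ll[b][:, combos[:, b]]
    with np.errstate(over="ignore"):
        lik = np.where(np.isfinite(log_lik), np.exp(log_lik), 0.0)
    row_sums = lik.sum(axis=1)
    if np.any(np.abs(row_sums - 1.0) > 1e-6):
        raise AssertionError("enumerated outcome probabilities do not sum to 1")
    lik /= row_sums[:, None]

    marginal = weights @ lik
    with np.errstate(divide="ignore", invalid="ignore"):
        log_ratio = np.where(lik > 0, np.log(
            np.where(lik > 0, lik, 1.0) / np.where(marginal > 0, marginal, 1.0)),
            0.0)
    contrib = (weights[:, None] * lik * log_ratio).sum(axis=0)
    mi = float(contrib.sum())
    with np.errstate(invalid="ignore"):
        posteriors = np.where(marginal[None, :] > 0,
                              weights[:, None] * lik / marginal[None, :],
                              0.0).T

    actions = block_actions[combos]  # (M, B, T)
    rewards = block_rewards[combos]
    return ExactMIResult(
        mi=mi, weights=weights, likelihoods=lik, marginal=marginal,
        posteriors=posteriors, contributions=contrib,
        actions=actions, rewards=rewards, hypotheses=tuple(hypotheses),
        n_trials=T, n_arms=K)
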