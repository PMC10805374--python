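"""Behavioral simulator models for multi-armed bandit tasks.

Three models of human explore/exploit behavior in K-armed Bernoulli bandits:

* **WSLTS** (Win-Stay Lose-Thompson-Sample): stay after a reward with
  probability ``gamma_win``, otherwise shift by Thompson sampling on a
  (reshaped) posterior probability of each arm being best.
* **AEG** (Auto-regressive epsilon-Greedy): epsilon-greedy choice with a
  multiplicative stickiness (or anti-stickiness) bias toward the previous
  choice, controlled by ``rho``.
* **GLS** (Generalized Latent State): a two-state explore/exploit hidden
  process whose transition probabilities depend on the previous latent state
  and the previous reward.

All three models share the same internal Beta-Bernoulli belief over arm reward
probabilities (:class:`LearnerState`), initialized to Beta(1, 1) per arm and
reset at the start of every experimental block (blocks are exchangeable; no
knowledge transfer across blocks).

Actions are 0-based arm indices; rewards are strictly in {0, 1}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit
from scipy.stats import beta as _beta_dist

__all__ = [
    "Model",
    "Design",
    "BehaviorBlock",
    "ExperimentData",
    "WSLTSParams",
    "AEGParams",
    "GLSParams",
    "LearnerState",
    "prob_best_arm",
    "prob_best_arm_batch",
    "policy_probabilities",
    "gls_transition",
    "EXPLORE",
    "EXPLOIT",
]


class Model(IntEnum):
    """Model indicator m for the three behavioral models."""

    WSLTS = 0
    AEG = 1
    GLS = 2

    @classmethod
    def parse(cls, name: "Model | int | str") -> "Model":
        if isinstance(name, Model):
            return name
        if isinstance(name, (int, np.integer)):
            return cls(int(name))
        try:
            return cls[str(name).upper()]
        except KeyError:
            valid = ", ".join(m.name for m in cls)
            raise ValueError(
                f"unknown model {name!r}; valid models are: {valid}"
            ) from None


# latent-state encoding for the GLS model
EXPLOIT = 0
EXPLORE = 1


@dataclass(frozen=True)
class Design:
    """Per-block Bernoulli reward probabilities: the optimized quantity d.

    ``blocks`` is a (B, K) array; entry [b, k] is the reward probability of
    arm k in block b.
    """

    blocks: np.ndarray

    def __post_init__(self) -> None:
        arr = np.atleast_2d(np.asarray(self.blocks, dtype=float))
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 2:
            raise ValueError("design must be a (B >= 1, K >= 2) array")
        if np.any(arr < 0) or np.any(arr > 1) or not np.all(np.isfinite(arr)):
            raise ValueError("reward probabilities must lie in [0, 1]")
        object.__setattr__(self, "blocks", arr)

    @property
    def n_blocks(self) -> int:
        return self.blocks.shape[0]

    @property
    def n_arms(self) -> int:
        return self.blocks.shape[1]

    @classmethod
    def from_flat(cls, flat: Sequence[float], n_arms: int) -> "Design":
        flat = np.asarray(flat, dtype=float)
        return cls(flat.reshape(-1, n_arms))

    def flatten(self) -> np.ndarray:
        return self.blocks.ravel().copy()


@dataclass(frozen=True)
class BehaviorBlock:
    """One block of observed behavior: T actions and T rewards."""

    actions: np.ndarray
    rewards: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.actions, dtype=np.int64)
        r = np.asarray(self.rewards, dtype=np.int64)
        if a.ndim != 1 or a.shape != r.shape:
            raise ValueError("actions and rewards must be 1-d and equal length")
        if np.any(a < 0):
            raise ValueError("actions must be nonnegative arm indices")
        if np.any((r != 0) & (r != 1)):
            raise ValueError("rewards must be in {0, 1}")
        object.__setattr__(self, "actions", a)
        object.__setattr__(self, "rewards", r)

    @property
    def n_trials(self) -> int:
        return self.actions.shape[0]

    def encode(self, n_arms: int) -> np.ndarray:
        """Flat numeric encoding of length 2T: scaled actions then rewards."""
        scale = max(n_arms - 1, 1)
        return np.concatenate(
            [self.actions.astype(float) / scale, self.rewards.astype(float)]
        )


@dataclass(frozen=True)
class ExperimentData:
    """Behavior from B blocks, aligned with the design it was generated under."""

    blocks: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "blocks", tuple(self.blocks))
        for b in self.blocks:
            if not isinstance(b, BehaviorBlock):
                raise TypeError("blocks must be BehaviorBlock instances")

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def encode(self, n_arms: int) -> np.ndarray:
        """(B, 2T) numeric encoding."""
        return np.stack([b.encode(n_arms) for b in self.blocks])


def _check_unit(name: str, value) -> None:
    v = np.asarray(value, dtype=float)
    if np.any(v < 0) or np.any(v > 1) or not np.all(np.isfinite(v)):
        raise ValueError(f"{name} must lie in [0, 1]")


def _check_finite(name: str, value) -> None:
    if not np.all(np.isfinite(np.asarray(value, dtype=float))):
        raise ValueError(f"{name} must be finite")


@dataclass(frozen=True)
class WSLTSParams:
    """Win-Stay Lose-Thompson-Sample parameters.

    gamma_win: probability of staying after a reward.
    gamma_lose: probability of Thompson-shifting after a non-reward.
    tau: posterior reshaping exponent (>= 0); tau=1 is plain Thompson
        sampling on the probability-of-best vector, tau=0 is uniform, and
        tau -> inf approaches greedy choice of the most-probably-best arm.
    """

    gamma_win: float | np.ndarray
    gamma_lose: float | np.ndarray
    tau: float | np.ndarray

    def __post_init__(self) -> None:
        _check_unit("gamma_win", self.gamma_win)
        _check_unit("gamma_lose", self.gamma_lose)
        t = np.asarray(self.tau, dtype=float)
        if np.any(t < 0) or not np.all(np.isfinite(t)):
            raise ValueError("tau must be >= 0")

    fields = ("gamma_win", "gamma_lose", "tau")


@dataclass(frozen=True)
class AEGParams:
    """Auto-regressive epsilon-Greedy parameters.

    epsilon: exploration probability in [0, 1].
    rho: stickiness log-weight; positive = sticky, negative = anti-sticky.
    """

    epsilon: float | np.ndarray
    rho: float | np.ndarray

    def __post_init__(self) -> None:
        _check_unit("epsilon", self.epsilon)
        _check_finite("rho", self.rho)

    fields = ("epsilon", "rho")


@dataclass(frozen=True)
class GLSParams:
    """Generalized Latent State parameters (explore-transition log-odds).

    The probability of entering the explore state is
    sigmoid(beta0 + beta_z * [previous state was explore] + beta_r * previous
    reward); at trial 1 it is sigmoid(beta0).
    """

    beta0: float | np.ndarray
    beta_z: float | np.ndarray
    beta_r: float | np.ndarray

    def __post_init__(self) -> None:
        _check_finite("beta0", self.beta0)
        _check_finite("beta_z", self.beta_z)
        _check_finite("beta_r", self.beta_r)

    fields = ("beta0", "beta_z", "beta_r")


PARAM_CLASSES = {
    Model.WSLTS: WSLTSParams,
    Model.AEG: AEGParams,
    Model.GLS: GLSParams,
}


def params_to_array(params) -> np.ndarray:
    """Stack a params object's fields into a (..., P) array."""
    cols = [np.atleast_1d(np.asarray(getattr(params, f), dtype=float))
            for f in type(params).fields]
    return np.stack(np.broadcast_arrays(*cols), axis=-1)


def params_from_array(model: Model, arr: np.ndarray):
    cls = PARAM_CLASSES[Model.parse(model)]
    arr = np.asarray(arr, dtype=float)
    return cls(*(arr[..., i] if arr.ndim > 1 else float(arr[i])
                 for i in range(len(cls.fields))))


@dataclass
class LearnerState:
    """Per-arm Beta-Bernoulli pseudo-counts, Beta(1, 1) at block start."""

    alpha: np.ndarray
    beta: np.ndarray

    @classmethod
    def fresh(cls, n_arms: int) -> "LearnerState":
        return cls(np.ones(n_arms), np.ones(n_arms))

    def update(self, action: int, reward: int) -> None:
        if reward:
            self.alpha[action] += 1
        else:
            self.beta[action] += 1

    @property
    def posterior_means(self) -> np.ndarray:
        return self.alpha / (self.alpha + self.beta)


# ---------------------------------------------------------------------------
# Probability of being the best arm (Thompson weights)
# ---------------------------------------------------------------------------

_GRID_SIZE = 2001
_GRID = np.linspace(0.0, 1.0, _GRID_SIZE)

# lazily grown tables of Beta pdf/cdf rows on the fixed grid, keyed by (a, b)
_pair_index: dict = {}
_pdf_tab = np.empty((0, _GRID_SIZE))
_cdf_tab = np.empty((0, _GRID_SIZE))

# memo of probability-of-best vectors keyed by the raw state bytes
_state_cache: dict = {}


def _pair_rows(pairs: np.ndarray) -> np.ndarray:
    """Row indices into the pdf/cdf tables for an (M, 2) array of (a, b)."""
    global _pdf_tab, _cdf_tab
    idx = np.empty(len(pairs), dtype=np.int64)
    new = []
    for i, pair in enumerate(pairs):
        key = (float(pair[0]), float(pair[1]))
        j = _pair_index.get(key)
        if j is None:
            j = _pdf_tab.shape[0] + len(new)
            _pair_index[key] = j
            new.append(key)
        idx[i] = j
    if new:
        a = np.array([k[0] for k in new])[:, None]
        b = np.array([k[1] for k in new])[:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            pdf = _beta_dist.pdf(_GRID[None, :], a, b)
        pdf = np.nan_to_num(pdf, nan=0.0, posinf=0.0)
        cdf = _beta_dist.cdf(_GRID[None, :], a, b)
        _pdf_tab = np.vstack([_pdf_tab, pdf])
        _cdf_tab = np.vstack([_cdf_tab, cdf])
    return idx


def prob_best_arm_batch(alpha: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Probability that each arm's Beta draw is the largest, per state row.

    Vectorized over an (n, K) batch of pseudo-count states. Computed by
    fixed-grid trapezoid quadrature of f_k(x) * prod_{j != k} F_j(x) on a
    2001-point grid, then renormalized.
    """
    alpha = np.atleast_2d(np.asarray(alpha, dtype=float))
    beta = np.atleast_2d(np.asarray(beta, dtype=float))
    full_n, K = alpha.shape
    states = np.concatenate([alpha, beta], axis=1)
    uniq, inverse = np.unique(states, axis=0, return_inverse=True)
    keys = [u.tobytes() for u in uniq]
    todo = [i for i, k in enumerate(keys) if k not in _state_cache]
    if todo:
        sub = uniq[todo]
        a, b = sub[:, :K], sub[:, K:]
        n = sub.shape[0]
        pairs = np.stack([a.ravel(), b.ravel()], axis=1)
        rows = _pair_rows(pairs).reshape(n, K)
        q = np.empty((n, K))
        chunk = 512
        for lo in range(0, n, chunk):
            hi = min(lo + chunk, n)
            f = _pdf_tab[rows[lo:hi]]  # (c, K, G)
            F = _cdf_tab[rows[lo:hi]]
            for k in range(K):
                others = np.ones_like(F[:, 0, :])
                for j in range(K):
                    if j != k:
                        others *= F[:, j, :]
                q[lo:hi, k] = np.trapezoid(f[:, k, :] * others, _GRID)
        q = np.clip(q, 0.0, None)
        q /= q.sum(axis=1, keepdims=True)
        for i, row in zip(todo, q):
            _state_cache[keys[i]] = row
    out = np.stack([_state_cache[k] for k in keys])
    return out[inverse]


def prob_best_arm(state: LearnerState) -> np.ndarray:
    """P(arm k is best) under the learner's independent Beta beliefs."""
    return prob_best_arm_batch(state.alpha[None, :], state.beta[None, :])[0]


# ---------------------------------------------------------------------------
# Vectorized per-trial choice policies
# ---------------------------------------------------------------------------


def _one_hot(idx: np.ndarray, K: int) -> np.ndarray:
    out = np.zeros((idx.shape[0], K))
    out[np.arange(idx.shape[0]), idx] = 1.0
    return out


def _greedy(alpha: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Uniform distribution over the argmax arms of the posterior means."""
    means = alpha / (alpha + beta)
    ties = means >= means.max(axis=1, keepdims=True) - 1e-12
    return ties / ties.sum(axis=1, keepdims=True)


def _reshape_thompson(q: np.ndarray, tau: np.ndarray) -> np.ndarray:
    """pi proportional to q**tau; tau=0 gives uniform (0**0 treated as 1)."""
    with np.errstate(divide="ignore"):
        w = np.where((q == 0.0) & (tau[:, None] == 0.0), 1.0,
                     q ** tau[:, None])
    s = w.sum(axis=1, keepdims=True)
    # guard against total underflow at extreme tau: fall back to greedy-on-q
    bad = (s[:, 0] == 0.0) | ~np.isfinite(s[:, 0])
    if np.any(bad):
        top = q[bad] >= q[bad].max(axis=1, keepdims=True) - 1e-15
        w[bad] = top / top.sum(axis=1, keepdims=True)
        s = w.sum(axis=1, keepdims=True)
    return w / s


def wslts_policy_batch(params: WSLTSParams, q: np.ndarray,
                       prev_action: Optional[np.ndarray],
                       prev_reward: Optional[np.ndarray]) -> np.ndarray:
    n, K = q.shape
    gw = np.broadcast_to(np.asarray(params.gamma_win, dtype=float), (n,))
    gl = np.broadcast_to(np.asarray(params.gamma_lose, dtype=float), (n,))
    tau = np.broadcast_to(np.asarray(params.tau, dtype=float), (n,))
    thompson = _reshape_thompson(q, tau)
    if prev_action is None:
        return thompson
    stay = _one_hot(prev_action, K)
    # after a reward: stay w.p. gamma_win, else Thompson over all arms
    pi_win = gw[:, None] * stay + (1.0 - gw[:, None]) * thompson
    # after a non-reward: Thompson over the *other* arms w.p. gamma_lose,
    # else stay on the previous arm
    restricted = thompson * (1.0 - stay)
    s = restricted.sum(axis=1, keepdims=True)
    degenerate = s[:, 0] <= 0.0
    if np.any(degenerate):
        unif_others = (1.0 - stay[degenerate])
        restricted[degenerate] = unif_others / unif_others.sum(
            axis=1, keepdims=True)
        s = restricted.sum(axis=1, keepdims=True)
    restricted = restricted / s
    pi_lose = gl[:, None] * restricted + (1.0 - gl[:, None]) * stay
    rewarded = np.asarray(prev_reward).astype(bool)
    return np.where(rewarded[:, None], pi_win, pi_lose)


def aeg_policy_batch(params: AEGParams, alpha: np.ndarray, beta: np.ndarray,
                     prev_action: Optional[np.ndarray]) -> np.ndarray:
    n, K = alpha.shape
    eps = np.broadcast_to(np.asarray(params.epsilon, dtype=float), (n,))
    rho = np.broadcast_to(np.asarray(params.rho, dtype=float), (n,))
    pi = (1.0 - eps[:, None]) * _greedy(alpha, beta) + eps[:, None] / K
    if prev_action is not None:
        mult = np.ones((n, K))
        mult[np.arange(n), prev_action] = np.exp(rho)
        pi = pi * mult
        pi = pi / pi.sum(axis=1, keepdims=True)
    return pi


def gls_policy_batch(alpha: np.ndarray, beta: np.ndarray,
                     latent: np.ndarray) -> np.ndarray:
    n, K = alpha.shape
    greedy = _greedy(alpha, beta)
    uniform = np.full((n, K), 1.0 / K)
    explore = np.asarray(latent).astype(bool)
    return np.where(explore[:, None], uniform, greedy)


def gls_transition(params: GLSParams,
                   prev_latent: Optional[int | np.ndarray] = None,
                   prev_reward: Optional[int | np.ndarray] = None):
    """Probability of the explore state at the next trial.

    At trial 1 (no history) this is sigmoid(beta0); afterwards
    sigmoid(beta0 + beta_z * [prev_latent == explore] + beta_r * prev_reward).
    """
    if (prev_latent is None) != (prev_reward is None):
        raise ValueError(
            "prev_latent and prev_reward must both be given or both absent")
    b0 = np.asarray(params.beta0, dtype=float)
    if prev_latent is None:
        out = expit(b0)
    else:
        z = np.asarray(prev_latent, dtype=float)
        r = np.asarray(prev_reward, dtype=float)
        out = expit(b0 + np.asarray(params.beta_z, dtype=float) * z
                    + np.asarray(params.beta_r, dtype=float) * r)
    return float(out) if np.ndim(out) == 0 else out


def policy_probabilities(model: Model, params, state: LearnerState,
                         prev_action: Optional[int] = None,
                         prev_reward: Optional[int] = None,
                         latent_state: Optional[int] = None) -> np.ndarray:
    """Per-trial choice probabilities over the K arms for a single learner.

    ``prev_action``/``prev_reward`` must both be present or both absent
    (trial 1). For the GLS model the current latent state is required.
    Output is a valid simplex (sums to 1 within 1e-9).
    """
    model = Model.parse(model)
    if (prev_action is None) != (prev_reward is None):
        raise ValueError(
            "prev_action and prev_reward must both be given or both absent")
    alpha = state.alpha[None, :]
    beta = state.beta[None, :]
    pa = None if prev_action is None else np.array([prev_action])
    pr = None if prev_reward is None else np.array([prev_reward])
    if model is Model.WSLTS:
        q = prob_best_arm_batch(alpha, beta)
        pi = wslts_policy_batch(params, q, pa, pr)
    elif model is Model.AEG:
        pi = aeg_policy_batch(params, alpha, beta, pa)
    else:
        if latent_state is None:
            raise ValueError(
                "the GLS model requires the current latent_state "
                "(0 = exploit, 1 = explore)")
        pi = gls_policy_batch(alpha, beta, np.array([latent_state]))
    return pi[0]
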