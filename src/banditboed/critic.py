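"""Neural mutual-information critic with per-block summary sub-networks.

The critic T(v, y) scores how plausibly a variable of interest v (a model
indicator for model discrimination, a parameter vector for parameter
estimation) goes with simulated behavior y. It is trained by stochastic
gradient ascent on the variational lower bound on mutual information

    U(d) >= E_joint[T(v, y)] - E_marginal[exp(T(v, y) - 1)],

where the marginal expectation pairs each y with a v permuted across the
batch. A trained critic yields (a) a held-out lower-bound estimate of the
mutual information at the design the data were simulated from, (b) an
amortized posterior p(v | y, d) proportional to p(v) * exp(T(v, y) - 1), and
(c) learned per-block summary statistics (the sub-network outputs).

Architecture: one sub-network per experimental block maps the 2T-length
block encoding (actions rescaled to [0, 1], then rewards) to S summary
statistics; the concatenated summaries and the encoded v feed a joint
network with a single linear output.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, replace
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

from .models import (
    BehaviorBlock,
    Design,
    ExperimentData,
    Model,
    PARAM_CLASSES,
    params_from_array,
    params_to_array,
)
from .nn import MLP, Adam
from .priors import PriorSpec, sample_params
from .simulate import simulate_experiments_batch

__all__ = [
    "CriticConfig",
    "TrainingSet",
    "TrainedCritic",
    "CriticEnsemble",
    "MIEstimate",
    "Posterior",
    "generate_training_set",
    "nwj_objective",
    "train_critic",
    "estimate_mi",
    "train_ensemble",
    "amortized_posterior",
    "amortized_model_posteriors",
    "amortized_parameter_weights",
    "extract_summaries",
    "encode_experiments",
    "save_critic",
    "load_critic",
]

# clip on the exponent during training to keep early gradients finite
_EXP_CLIP = 30.0


@dataclass(frozen=True)
class CriticConfig:
    """Architecture and training hyperparameters for one critic."""

    block_widths: Tuple[int, ...] = (64, 32)
    summary_dim: int = 8
    joint_widths: Tuple[int, ...] = (128, 64)
    activation: str = "relu"
    learning_rate: float = 1e-3
    epochs: int = 200
    batch_size: int = 256
    heldout_fraction: float = 0.2
    one_hot_actions: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.summary_dim < 1:
            raise ValueError("summary_dim must be >= 1")
        if not 0.0 < self.heldout_fraction < 1.0:
            raise ValueError("heldout_fraction must be in (0, 1)")
        if self.activation != "relu":
            raise ValueError("only ReLU activations are implemented")


def encode_experiments(actions: np.ndarray, rewards: np.ndarray, n_arms: int,
                       one_hot_actions: bool = False) -> np.ndarray:
    """(n, B, T) actions/rewards -> (n, B, L) numeric block encodings.

    Default encoding keeps each block at length 2T (actions rescaled to
    [0, 1], then rewards); the one-hot option expands actions to T*K columns.
    """
    n, B, T = actions.shape
    if one_hot_actions:
        eye = np.eye(n_arms)
        a = eye[actions].reshape(n, B, T * n_arms)
    else:
        a = actions.astype(float) / max(n_arms - 1, 1)
    return np.concatenate([a, rewards.astype(float)], axis=2)


def _encode_md(models: np.ndarray) -> np.ndarray:
    return np.eye(3)[np.asarray(models, dtype=int)]


def _encode_pe(theta: np.ndarray, bounds: np.ndarray) -> np.ndarray:
    width = np.where(bounds[:, 1] > bounds[:, 0],
                     bounds[:, 1] - bounds[:, 0], 1.0)
    return (np.atleast_2d(theta) - bounds[:, 0]) / width


@dataclass(frozen=True)
class TrainingSet:
    """Paired (v_i, y_i) records simulated at one design.

    v_raw holds model indicators (MD) or parameter vectors (PE); v_enc is the
    network encoding (one-hot / min-max scaled); y is the (n, B, L) block
    encoding, with the raw (n, B, T) actions and rewards retained.
    """

    design: Design
    goal: str
    n_trials: int
    prior: PriorSpec
    model: Optional[Model]
    v_raw: np.ndarray
    v_enc: np.ndarray
    actions: np.ndarray
    rewards: np.ndarray
    y: np.ndarray
    seed: Optional[int] = None

    @property
    def n(self) -> int:
        return self.y.shape[0]

    def subset(self, idx: np.ndarray) -> "TrainingSet":
        return replace(self, v_raw=self.v_raw[idx], v_enc=self.v_enc[idx],
                       actions=self.actions[idx], rewards=self.rewards[idx],
                       y=self.y[idx])

    def split(self, heldout_fraction: float,
              rng: Optional[np.random.Generator] = None
              ) -> Tuple["TrainingSet", "TrainingSet"]:
        """Disjoint (train, heldout) split."""
        rng = rng or np.random.default_rng(0)
        perm = rng.permutation(self.n)
        n_held = max(1, int(round(self.n * heldout_fraction)))
        return self.subset(perm[n_held:]), self.subset(perm[:n_held])


def generate_training_set(design: Design, goal: str, prior: PriorSpec,
                          n: int, rng: np.random.Generator,
                          model=None, n_trials: int = 30,
                          one_hot_actions: bool = False) -> TrainingSet:
    """Simulate n paired (v, y) records from the prior at a fixed design.

    MD: v ~ model prior, theta ~ p(theta | m); PE: v = theta ~ p(theta | m)
    for the given model. Reproducible given the generator state.
    """
    goal = str(goal).upper()
    if n < 2:
        raise ValueError("need at least n=2 records")
    B, K, T = design.n_blocks, design.n_arms, int(n_trials)
    actions = np.empty((n, B, T), dtype=np.int64)
    rewards = np.empty_like(actions)
    if goal == "PE":
        if model is None:
            raise ValueError("parameter estimation requires a model")
        m = Model.parse(model)
        params = sample_params(m, prior, rng, n=n)
        actions, rewards = simulate_experiments_batch(
            m, params, design, T, rng, n)
        v_raw = params_to_array(params)
        v_enc = _encode_pe(v_raw, prior.bounds(m))
        models_arr = np.full(n, int(m))
    elif goal == "MD":
        models_arr = rng.choice(3, size=n, p=prior.model_prior)
        for m in Model:
            idx = np.flatnonzero(models_arr == m)
            if idx.size == 0:
                continue
            params = sample_params(m, prior, rng, n=idx.size)
            a, r = simulate_experiments_batch(m, params, design, T, rng,
                                              idx.size)
            actions[idx] = a
            rewards[idx] = r
        v_raw = models_arr.copy()
        v_enc = _encode_md(models_arr)
        model = None
    else:
        raise ValueError("goal must be 'MD' or 'PE'")
    y = encode_experiments(actions, rewards, K, one_hot_actions)
    return TrainingSet(design=design, goal=goal, n_trials=T, prior=prior,
                       model=None if model is None else Model.parse(model),
                       v_raw=v_raw, v_enc=v_enc, actions=actions,
                       rewards=rewards, y=y)


# ---------------------------------------------------------------------------
# The critic network
# ---------------------------------------------------------------------------


class Critic:
    """Per-block sub-networks plus a joint network: T(v, y) -> real."""

    def __init__(self, config: CriticConfig, n_blocks: int, block_len: int,
                 v_dim: int, rng: np.random.Generator):
        self.config = config
        self.n_blocks = n_blocks
        self.block_len = block_len
        self.v_dim = v_dim
        S = config.summary_dim
        self.subnets = [MLP((block_len, *config.block_widths, S), rng)
                        for _ in range(n_blocks)]
        self.joint = MLP((n_blocks * S + v_dim, *config.joint_widths, 1), rng)

    def _check_y(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        if y.ndim == 2:
            y = y[None]
        if y.shape[1] != self.n_blocks or y.shape[2] != self.block_len:
            raise ValueError(
                f"expected y of shape (n, {self.n_blocks}, {self.block_len}),"
                f" got {y.shape}")
        return y

    def summaries(self, y: np.ndarray, cache: bool = False) -> np.ndarray:
        """(n, B*S) learned per-block summary statistics."""
        y = self._check_y(y)
        return np.concatenate(
            [net.forward(y[:, b, :], cache=cache)
             for b, net in enumerate(self.subnets)], axis=1)

    def value_from_summaries(self, summaries: np.ndarray, v: np.ndarray,
                             cache: bool = False) -> np.ndarray:
        x = np.concatenate([summaries, np.atleast_2d(v)], axis=1)
        return self.joint.forward(x, cache=cache)[:, 0]

    def __call__(self, v: np.ndarray, y: np.ndarray,
                 cache: bool = False) -> np.ndarray:
        return self.value_from_summaries(self.summaries(y, cache=cache),
                                         np.atleast_2d(v), cache=cache)

    def backward(self, d_out: np.ndarray) -> None:
        d_in = self.joint.backward(d_out[:, None])
        S = self.config.summary_dim
        for b, net in enumerate(self.subnets):
            net.backward(d_in[:, b * S:(b + 1) * S])

    @property
    def params(self) -> List[np.ndarray]:
        out: List[np.ndarray] = []
        for net in self.subnets:
            out.extend(net.params)
        out.extend(self.joint.params)
        return out

    @property
    def grads(self) -> List[np.ndarray]:
        out: List[np.ndarray] = []
        for net in self.subnets:
            out.extend(net.grads)
        out.extend(self.joint.grads)
        return out


@dataclass
class TrainedCritic:
    """A trained critic with its architecture metadata and loss history."""

    network: Critic
    config: CriticConfig
    history: np.ndarray  # per-epoch mean training objective (nats)
    seed: int
    goal: str
    design: Design
    n_trials: int
    model: Optional[Model] = None

    def __call__(self, v: np.ndarray, y: np.ndarray) -> np.ndarray:
        return self.network(v, y)

    def summaries(self, y: np.ndarray) -> np.ndarray:
        return self.network.summaries(y)


def nwj_objective(critic: Callable[[np.ndarray, np.ndarray], np.ndarray],
                  joint_pairs: Tuple[np.ndarray, np.ndarray],
                  marginal_pairs: Tuple[np.ndarray, np.ndarray]) -> float:
    """Sample-average variational lower bound.

    mean T over joint (v, y) pairs minus mean exp(T - 1) over marginal pairs
    (v permuted across the batch to break the pairing). The bound is tight at
    T*(v, y) = 1 + log(p(v|y, d)/p(v)), where it equals the MI.
    """
    vj, yj = joint_pairs
    vm, ym = marginal_pairs
    if np.size(vj) == 0 or np.size(vm) == 0:
        raise ValueError("empty batch")
    t_joint = np.asarray(critic(vj, yj), dtype=float)
    t_marg = np.asarray(critic(vm, ym), dtype=float)
    return float(np.mean(t_joint) - np.mean(np.exp(t_marg - 1.0)))


def train_critic(config: CriticConfig, training_set: TrainingSet
                 ) -> TrainedCritic:
    """Stochastic gradient ascent on the variational MI bound.

    Marginal samples come from a within-batch cyclic shift of v after
    shuffling (a derangement: no record is paired with its own v).
    """
    ts = training_set
    if ts.n < 2:
        raise ValueError("training set must contain at least 2 records")
    rng = np.random.default_rng(config.seed)
    n, B, L = ts.y.shape
    critic = Critic(config, B, L, ts.v_enc.shape[1], rng)
    opt = Adam(critic.params, lr=config.learning_rate)
    batch = min(config.batch_size, n)
    history = []
    for _ in range(config.epochs):
        perm = rng.permutation(n)
        epoch_obj = []
        for lo in range(0, n - 1, batch):
            idx = perm[lo:lo + batch]
            nb = idx.size
            if nb < 2:
                continue
            v = ts.v_enc[idx]
            y = ts.y[idx]
            v_m = np.roll(v, 1, axis=0)
            t = critic(np.vstack([v, v_m]), np.concatenate([y, y], axis=0),
                       cache=True)
            t_joint, t_marg = t[:nb], t[nb:]
            e = np.exp(np.minimum(t_marg - 1.0, _EXP_CLIP))
            obj = float(t_joint.mean() - e.mean())
            # ascend: minimize -objective
            d_out = np.concatenate([np.full(nb, -1.0 / nb), e / nb])
            critic.backward(d_out)
            opt.step(critic.params, critic.grads)
            epoch_obj.append(obj)
        history.append(float(np.mean(epoch_obj)))
    return TrainedCritic(network=critic, config=config,
                         history=np.asarray(history), seed=config.seed,
                         goal=ts.goal, design=ts.design,
                         n_trials=ts.n_trials, model=ts.model)


@dataclass(frozen=True)
class MIEstimate:
    """Held-out lower-bound MI estimate in nats, with bootstrap SE."""

    value: float
    se: float
    n: int
    warnings: Tuple[str, ...] = ()


def estimate_mi(critic: TrainedCritic, heldout: TrainingSet,
                n_bootstrap: int = 200) -> MIEstimate:
    """Evaluate the variational bound on held-out data.

    Deterministic given the critic and the held-out set: the marginal pairing
    is a fixed cyclic shift and the bootstrap uses a fixed internal seed.
    The standard error is a batch bootstrap over records (200 resamples).
    """
    n = heldout.n
    warnings = ()
    if n < 100:
        warnings = (f"held-out set has only {n} records (< 100)",)
    net = critic.network if isinstance(critic, TrainedCritic) else critic
    s = net.summaries(heldout.y)
    t_joint = net.value_from_summaries(s, heldout.v_enc)
    t_marg = net.value_from_summaries(s, np.roll(heldout.v_enc, 1, axis=0))
    contrib_m = np.exp(t_marg - 1.0)
    value = float(t_joint.mean() - contrib_m.mean())
    brng = np.random.default_rng(0)
    stats = np.empty(n_bootstrap)
    for i in range(n_bootstrap):
        idx = brng.integers(0, n, n)
        stats[i] = t_joint[idx].mean() - contrib_m[idx].mean()
    return MIEstimate(value=value, se=float(stats.std(ddof=1)), n=n,
                      warnings=warnings)


# ---------------------------------------------------------------------------
# Ensembles and amortized posteriors
# ---------------------------------------------------------------------------


@dataclass
class CriticEnsemble:
    """Independently trained critics sharing design, goal, and priors."""

    members: List[TrainedCritic]
    prior: PriorSpec

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble must contain at least one critic")
        g = {m.goal for m in self.members}
        if len(g) > 1:
            raise ValueError("ensemble members disagree on the goal")

    @property
    def goal(self) -> str:
        return self.members[0].goal

    @property
    def design(self) -> Design:
        return self.members[0].design

    @property
    def model(self) -> Optional[Model]:
        return self.members[0].model


def train_ensemble(design: Design, goal: str, prior: PriorSpec,
                   rng: np.random.Generator, config: CriticConfig,
                   n_members: int = 50, n_train: int = 10000,
                   model=None, n_trials: int = 30) -> CriticEnsemble:
    """Train n_members critics on independently simulated training sets."""
    members = []
    for _ in range(n_members):
        seed = int(rng.integers(0, 2 ** 31 - 1))
        ts = generate_training_set(design, goal, prior, n_train,
                                   np.random.default_rng(seed), model=model,
                                   n_trials=n_trials,
                                   one_hot_actions=config.one_hot_actions)
        members.append(train_critic(replace(config, seed=seed), ts))
    return CriticEnsemble(members, prior)


@dataclass(frozen=True)
class Posterior:
    """Amortized posterior: discrete over models or weighted prior samples."""

    probs: Optional[np.ndarray] = None
    samples: Optional[np.ndarray] = None
    weights: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.probs is not None:
            p = np.asarray(self.probs, dtype=float)
            if abs(p.sum() - 1.0) > 1e-9 or np.any(p < 0):
                raise ValueError("posterior probabilities must form a simplex")
            object.__setattr__(self, "probs", p)
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if abs(w.sum() - 1.0) > 1e-9 or np.any(w < 0):
                raise ValueError("posterior weights must form a simplex")
            object.__setattr__(self, "weights", w)


def amortized_model_posteriors(ensemble: CriticEnsemble, y: np.ndarray,
                               prior: Optional[PriorSpec] = None
                               ) -> np.ndarray:
    """(n, 3) amortized model posteriors for a batch of encoded experiments.

    Per member the unnormalized mass is p(m) * exp(T(m, y) - 1), explicitly
    renormalized; the ensemble output is the arithmetic mean of member
    posteriors, renormalized.
    """
    prior = prior or ensemble.prior
    y = np.asarray(y, dtype=float)
    if y.ndim == 2:
        y = y[None]
    n = y.shape[0]
    eye = np.eye(3)
    acc = np.zeros((n, 3))
    for member in ensemble.members:
        net = member.network
        s = net.summaries(y)
        t = np.stack([net.value_from_summaries(s, np.tile(eye[j], (n, 1)))
                      for j in range(3)], axis=1)
        w = prior.model_prior[None, :] * np.exp(
            np.minimum(t - 1.0, _EXP_CLIP))
        w_sum = w.sum(axis=1, keepdims=True)
        w = np.where(w_sum > 0, w / np.where(w_sum > 0, w_sum, 1.0),
                     prior.model_prior[None, :])
        acc += w
    acc /= len(ensemble.members)
    return acc / acc.sum(axis=1, keepdims=True)


def amortized_parameter_weights(ensemble: CriticEnsemble, y: np.ndarray,
                                theta: np.ndarray,
                                prior: Optional[PriorSpec] = None
                                ) -> np.ndarray:
    """(n, n_samples) normalized posterior weights over shared prior samples.

    theta rows are raw parameter vectors of the ensemble's model; the prior
    being uniform, each member's weights are proportional to exp(T - 1),
    normalized, then averaged across members and renormalized.
    """
    prior = prior or ensemble.prior
    model = ensemble.model
    if model is None:
        raise ValueError("parameter weights require a PE ensemble")
    y = np.asarray(y, dtype=float)
    if y.ndim == 2:
        y = y[None]
    n = y.shape[0]
    v_enc = _encode_pe(np.asarray(theta, dtype=float), prior.bounds(model))
    ns = v_enc.shape[0]
    acc = np.zeros((n, ns))
    for member in ensemble.members:
        net = member.network
        s = net.summaries(y)  # (n, B*S)
        t = np.empty((n, ns))
        # evaluate the joint net on every (dataset, sample) pair in chunks
        chunk = max(1, int(2e6 // max(ns, 1)))
        for lo in range(0, n, chunk):
            hi = min(lo + chunk, n)
            rep_s = np.repeat(s[lo:hi], ns, axis=0)
            rep_v = np.tile(v_enc, (hi - lo, 1))
            t[lo:hi] = net.value_from_summaries(rep_s, rep_v).reshape(
                hi - lo, ns)
        w = np.exp(np.minimum(t - 1.0, _EXP_CLIP))
        w_sum = w.sum(axis=1, keepdims=True)
        w = np.where(w_sum > 0, w / np.where(w_sum > 0, w_sum, 1.0), 1.0 / ns)
        acc += w
    acc /= len(ensemble.members)
    return acc / acc.sum(axis=1, keepdims=True)


def amortized_posterior(ensemble: CriticEnsemble, data: ExperimentData,
                        prior: Optional[PriorSpec] = None,
                        prior_samples: Optional[np.ndarray] = None,
                        n_prior_samples: int = 10000,
                        rng: Optional[np.random.Generator] = None
                        ) -> Posterior:
    """Amortized posterior for one observed experiment.

    MD ensembles return a discrete posterior over the three models; PE
    ensembles return self-normalized importance weights over prior samples
    (fresh draws unless ``prior_samples`` is supplied).
    """
    prior = prior or ensemble.prior
    ref = ensemble.members[0]
    y = encode_experiments(
        np.stack([b.actions for b in data.blocks])[None],
        np.stack([b.rewards for b in data.blocks])[None],
        ref.design.n_arms, ref.config.one_hot_actions)
    if ensemble.goal == "MD":
        return Posterior(probs=amortized_model_posteriors(ensemble, y,
                                                          prior)[0])
    if prior_samples is None:
        rng = rng or np.random.default_rng(0)
        prior_samples = params_to_array(sample_params(
            ensemble.model, prior, rng, n=n_prior_samples))
    w = amortized_parameter_weights(ensemble, y, prior_samples, prior)[0]
    return Posterior(samples=np.asarray(prior_samples, dtype=float),
                     weights=w / w.sum())


def extract_summaries(critic: TrainedCritic, block: BehaviorBlock,
                      block_index: int = 0) -> np.ndarray:
    """Learned summary statistics of one block (the sub-network output)."""
    net = critic.network if isinstance(critic, TrainedCritic) else critic
    enc = block.encode(critic.design.n_arms)[None, :]
    return net.subnets[block_index].forward(enc)[0]


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def save_critic(critic: TrainedCritic, directory: str) -> None:
    """Write architecture JSON, weights (npz), and training-history CSV."""
    os.makedirs(directory, exist_ok=True)
    net = critic.network
    arch = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in vars(critic.config).items()},
        "n_blocks": net.n_blocks,
        "block_len": net.block_len,
        "v_dim": net.v_dim,
        "goal": critic.goal,
        "seed": critic.seed,
        "n_trials": critic.n_trials,
        "model": None if critic.model is None else critic.model.name,
        "design": critic.design.blocks.tolist(),
    }
    with open(os.path.join(directory, "architecture.json"), "w") as fh:
        json.dump(arch, fh, indent=2)
    arrays = {}
    for b, sub in enumerate(net.subnets):
        for i, (W, bias) in enumerate(zip(sub.W, sub.b)):
            arrays[f"sub{b}_W{i}"] = W
            arrays[f"sub{b}_b{i}"] = bias
    for i, (W, bias) in enumerate(zip(net.joint.W, net.joint.b)):
        arrays[f"joint_W{i}"] = W
        arrays[f"joint_b{i}"] = bias
    np.savez(os.path.join(directory, "weights.npz"), **arrays)
    with open(os.path.join(directory, "history.csv"), "w") as fh:
        fh.write("epoch,objective\n")
        for i, obj in enumerate(critic.history):
            fh.write(f"{i},{obj}\n")


def load_critic(directory: str) -> TrainedCritic:
    with open(os.path.join(directory, "architecture.json")) as fh:
        arch = json.load(fh)
    cfg_raw = arch["config"]
    cfg = CriticConfig(**{k: (tuple(v) if isinstance(v, list) else v)
                          for k, v in cfg_raw.items()})
    rng = np.random.default_rng(0)
    net = Critic(cfg, arch["n_blocks"], arch["block_len"], arch["v_dim"], rng)
    data = np.load(os.path.join(directory, "weights.npz"))
    for b, sub in enumerate(net.subnets):
        for i in range(len(sub.W)):
            sub.W[i] = data[f"sub{b}_W{i}"]
            sub.b[i] = data[f"sub{b}_b{i}"]
    for i in range(len(net.joint.W)):
        net.joint.W[i] = data[f"joint_W{i}"]
        net.joint.b[i] = data[f"joint_b{i}"]
    hist = []
    with open(os.path.join(directory, "history.csv")) as fh:
        next(fh)
        for line in fh:
            hist.append(float(line.strip().split(",")[1]))
    return TrainedCritic(
        network=net, config=cfg, history=np.asarray(hist),
        seed=arch["seed"], goal=arch["goal"],
        design=Design(np.asarray(arch["design"])),
        n_trials=arch["n_trials"],
        model=None if arch["model"] is None else Model.parse(arch["model"]))
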