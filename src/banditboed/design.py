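"""Bayesian-optimization search over reward-probability designs.

The search treats the held-out mutual-information estimate at a design as a
noisy black-box objective, models it with a Gaussian-process surrogate
(Matern-5/2 kernel plus a homoscedastic noise term) and picks each new design
by maximizing Expected Improvement over the unit box. Constraint-violating
candidates are rejected and resampled. The fitted surrogate doubles as the
exported utility surface.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm, qmc
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

from .critic import CriticConfig, MIEstimate, estimate_mi, generate_training_set, train_critic
from .models import Design
from .priors import PriorSpec

__all__ = [
    "DesignSpace",
    "BOConfig",
    "OptimizationResult",
    "UtilitySurface",
    "expected_improvement",
    "evaluate_objective",
    "optimize_design",
    "utility_surface",
    "sample_baseline_design",
]


@dataclass(frozen=True)
class DesignSpace:
    """Box-constrained space of flattened designs: D = B * K in [0, 1]^D."""

    n_blocks: int
    n_arms: int
    lower: Optional[np.ndarray] = None
    upper: Optional[np.ndarray] = None
    constraint: Optional[Callable[[np.ndarray], bool]] = None

    def __post_init__(self) -> None:
        D = self.dim
        lo = np.zeros(D) if self.lower is None else np.asarray(self.lower,
                                                               dtype=float)
        hi = np.ones(D) if self.upper is None else np.asarray(self.upper,
                                                              dtype=float)
        if lo.shape != (D,) or hi.shape != (D,):
            raise ValueError("bounds must have length B*K")
        if np.any(lo < 0) or np.any(hi > 1) or np.any(lo > hi):
            raise ValueError("bounds must satisfy 0 <= lower <= upper <= 1")
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)

    @property
    def dim(self) -> int:
        return self.n_blocks * self.n_arms

    def contains(self, flat: np.ndarray) -> bool:
        flat = np.asarray(flat, dtype=float)
        if np.any(flat < self.lower - 1e-12) or np.any(flat > self.upper + 1e-12):
            return False
        return self.constraint is None or bool(self.constraint(flat))

    def to_design(self, flat: np.ndarray) -> Design:
        return Design.from_flat(flat, self.n_arms)


@dataclass(frozen=True)
class BOConfig:
    """Bayesian-optimization settings (Matern-5/2 GP, Expected Improvement)."""

    n_init: int = 0  # 0 means max(8, 2 * D)
    budget: int = 30
    infer_noise: bool = True
    canonicalize_blocks: bool = False
    n_candidates: int = 512
    n_restarts: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.budget < 1:
            raise ValueError("budget must be >= 1")


@dataclass
class OptimizationResult:
    """Search outcome: incumbent design, estimate, trace and surrogate."""

    best_design: Design
    best_value: float
    best_se: float
    surrogate_best_design: Design
    surrogate_best_mean: float
    trace: pd.DataFrame  # columns: d0..d{D-1}, mi, se
    gp: GaussianProcessRegressor
    space: DesignSpace
    config: BOConfig

    def to_dict(self) -> dict:
        return {
            "best_design": self.best_design.blocks.tolist(),
            "best_value": self.best_value,
            "best_se": self.best_se,
            "surrogate_best_design":
                self.surrogate_best_design.blocks.tolist(),
            "surrogate_best_mean": self.surrogate_best_mean,
            "trace": self.trace.to_dict(orient="list"),
            "config": {"n_init": self.config.n_init,
                       "budget": self.config.budget,
                       "seed": self.config.seed},
        }


def expected_improvement(mean, sd, best_so_far) -> np.ndarray:
    """Closed-form Expected Improvement for maximization.

    EI = (mu - best) * Phi(z) + sd * phi(z), z = (mu - best) / sd; at sd = 0
    it degenerates to max(mu - best, 0).
    """
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    if np.any(sd < 0):
        raise ValueError("sd must be nonnegative")
    imp = mean - best_so_far
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, imp / np.where(sd > 0, sd, 1.0), 0.0)
    z = np.clip(z, -40.0, 40.0)  # far tails contribute 0 or the plug-in value
    ei = np.where(sd > 0, imp * norm.cdf(z) + sd * norm.pdf(z),
                  np.maximum(imp, 0.0))
    out = np.maximum(ei, 0.0)
    return float(out) if out.ndim == 0 else out


def evaluate_objective(design: Design, goal: str, prior: PriorSpec,
                       rng: np.random.Generator, model=None,
                       sim_n: int = 10000,
                       critic_config: Optional[CriticConfig] = None,
                       n_trials: int = 30) -> MIEstimate:
    """One noisy utility evaluation: simulate, train a critic, estimate MI."""
    from dataclasses import replace

    cfg = critic_config or CriticConfig()
    seed = int(rng.integers(0, 2 ** 31 - 1))
    ts = generate_training_set(design, goal, prior, sim_n,
                               np.random.default_rng(seed), model=model,
                               n_trials=n_trials,
                               one_hot_actions=cfg.one_hot_actions)
    train, held = ts.split(cfg.heldout_fraction, np.random.default_rng(seed))
    critic = train_critic(replace(cfg, seed=seed), train)
    return estimate_mi(critic, held)


def _canonicalize(flat: np.ndarray, n_arms: int) -> np.ndarray:
    """Sort blocks lexicographically (block order is exchangeable)."""
    blocks = flat.reshape(-1, n_arms)
    order = np.lexsort(blocks.T[::-1])
    return blocks[order].ravel()


def _fit_gp(X: np.ndarray, y: np.ndarray, noise_floor: float,
            infer_noise: bool, seed: int) -> GaussianProcessRegressor:
    D = X.shape[1]
    kernel = ConstantKernel(1.0, (1e-3, 1e3)) * Matern(
        length_scale=np.full(D, 0.3), length_scale_bounds=(1e-2, 1e2),
        nu=2.5)
    if infer_noise:
        kernel = kernel + WhiteKernel(
            noise_level=max(noise_floor ** 2, 1e-8),
            noise_level_bounds=(max(noise_floor ** 2, 1e-10), 1e1))
        alpha = 1e-10
    else:
        alpha = max(noise_floor ** 2, 1e-10)
    gp = GaussianProcessRegressor(kernel=kernel, alpha=alpha,
                                  normalize_y=True, n_restarts_optimizer=2,
                                  random_state=seed)
    with warnings.catch_warnings():
        # hyperparameters hitting a bound is routine at small sample sizes
        warnings.simplefilter("ignore", ConvergenceWarning)
        gp.fit(X, y)
    return gp


def _propose(gp, space: DesignSpace, best: float, cfg: BOConfig,
             rng: np.random.Generator) -> np.ndarray:
    """Maximize EI: random + quasi-random candidates, then local polish."""
    D = space.dim
    width = space.upper - space.lower
    cands: List[np.ndarray] = []
    attempts = 0
    while len(cands) < cfg.n_candidates:
        x = space.lower + rng.random((cfg.n_candidates, D)) * width
        for row in x:
            if space.contains(row):
                cands.append(row)
                if len(cands) >= cfg.n_candidates:
                    break
        attempts += cfg.n_candidates
        if attempts > 1000 * cfg.n_candidates:
            raise RuntimeError(
                "could not sample feasible candidates after 1,000 attempts "
                "per requested candidate; constraints may be infeasible")
    X = np.asarray(cands)
    mu, sd = gp.predict(X, return_std=True)
    ei = expected_improvement(mu, sd, best)

    def neg_ei(x):
        m, s = gp.predict(x[None, :], return_std=True)
        return -float(expected_improvement(m[0], s[0], best))

    starts = X[np.argsort(ei)[-cfg.n_restarts:]]
    best_x, best_ei = X[int(np.argmax(ei))], float(ei.max())
    for x0 in starts:
        res = minimize(neg_ei, x0, method="L-BFGS-B",
                       bounds=list(zip(space.lower, space.upper)))
        if -res.fun > best_ei and space.contains(res.x):
            best_x, best_ei = res.x, -res.fun
    return np.clip(best_x, space.lower, space.upper)


def optimize_design(objective: Callable[[Design], "MIEstimate | float"],
                    space: DesignSpace, config: BOConfig,
                    rng: np.random.Generator) -> OptimizationResult:
    """Gaussian-process Bayesian optimization of a noisy design utility.

    ``objective`` maps a Design to an MIEstimate (or plain float).
    Initialization uses scrambled Sobol points; each iteration fits the GP on
    all (standardized) observations and evaluates the EI-maximizing feasible
    candidate. The incumbent is the trace argmax of observed utility; the
    surrogate-mean argmax is reported alongside.
    """
    D = space.dim
    n_init = config.n_init if config.n_init > 0 else max(8, 2 * D)
    if config.budget < n_init:
        raise ValueError("budget must cover the initial points")

    sobol = qmc.Sobol(D, scramble=True,
                      seed=int(rng.integers(0, 2 ** 31 - 1)))
    init: List[np.ndarray] = []
    attempts = 0
    n_pow2 = 1 << (max(n_init - 1, 1)).bit_length()
    while len(init) < n_init:
        pts = space.lower + sobol.random(n_pow2) * (space.upper - space.lower)
        for row in pts:
            if space.contains(row):
                init.append(row)
                if len(init) >= n_init:
                    break
        attempts += n_init
        if attempts > 1000 * n_init:
            raise RuntimeError(
                "could not initialize with feasible designs after 1,000 "
                "attempts per point; constraints may be infeasible")

    X: List[np.ndarray] = []
    vals: List[float] = []
    ses: List[float] = []

    def record(flat: np.ndarray) -> None:
        est = objective(space.to_design(flat))
        if isinstance(est, MIEstimate):
            v, s = est.value, est.se
        else:
            v, s = float(est), 0.0
        stored = (_canonicalize(flat, space.n_arms)
                  if config.canonicalize_blocks else flat)
        X.append(stored)
        vals.append(v)
        ses.append(s)

    for flat in init:
        record(flat)

    gp = None
    for _ in range(config.budget - n_init):
        noise_floor = float(np.median(ses)) if np.any(ses) else 0.0
        gp = _fit_gp(np.asarray(X), np.asarray(vals), noise_floor,
                     config.infer_noise, config.seed)
        record(_propose(gp, space, max(vals), config, rng))

    noise_floor = float(np.median(ses)) if np.any(ses) else 0.0
    gp = _fit_gp(np.asarray(X), np.asarray(vals), noise_floor,
                 config.infer_noise, config.seed)

    best_i = int(np.argmax(vals))
    # surrogate argmax over a dense candidate set seeded at the incumbents
    grid = space.lower + qmc.Sobol(D, scramble=True, seed=config.seed).random(
        2048) * (space.upper - space.lower)
    grid = np.vstack([grid, np.asarray(X)])
    mu = gp.predict(grid)
    surr_i = int(np.argmax(mu))

    trace = pd.DataFrame(np.asarray(X),
                         columns=[f"d{i}" for i in range(D)])
    trace["mi"] = vals
    trace["se"] = ses
    return OptimizationResult(
        best_design=space.to_design(np.asarray(X)[best_i]),
        best_value=float(vals[best_i]), best_se=float(ses[best_i]),
        surrogate_best_design=space.to_design(grid[surr_i]),
        surrogate_best_mean=float(mu[surr_i]),
        trace=trace, gp=gp, space=space, config=config)


@dataclass
class UtilitySurface:
    """Queryable fitted utility surface (GP posterior mean and sd)."""

    gp: GaussianProcessRegressor
    space: DesignSpace
    trace: pd.DataFrame

    def predict(self, flats: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        mu, sd = self.gp.predict(np.atleast_2d(flats), return_std=True)
        return mu, sd

    def top_k(self, k: int = 1) -> pd.DataFrame:
        """The k best designs in the evaluation trace, by observed utility."""
        return self.trace.sort_values("mi", ascending=False).head(k)

    def grid(self, resolution: int = 11) -> pd.DataFrame:
        """Dense grid export: one column per dimension plus mean and sd.

        Full resolution^D grid for D <= 3; for larger D, a 2-d slice over the
        first two dimensions with the remaining coordinates fixed at the
        incumbent design.
        """
        D = self.space.dim
        best = self.trace.sort_values("mi", ascending=False).iloc[0]
        incumbent = best[[f"d{i}" for i in range(D)]].to_numpy(dtype=float)
        free = list(range(D)) if D <= 3 else [0, 1]
        axes = [np.linspace(self.space.lower[i], self.space.upper[i],
                            resolution) for i in free]
        mesh = np.meshgrid(*axes, indexing="ij")
        pts = np.tile(incumbent, (mesh[0].size, 1))
        for j, i in enumerate(free):
            pts[:, i] = mesh[j].ravel()
        mu, sd = self.predict(pts)
        out = pd.DataFrame(pts, columns=[f"d{i}" for i in range(D)])
        out["mean"] = mu
        out["sd"] = sd
        return out


def utility_surface(result: OptimizationResult) -> UtilitySurface:
    """Expose the optimization surrogate as a queryable utility surface."""
    if len(result.trace) < 2:
        raise ValueError("need at least 2 evaluations to fit a surface")
    return UtilitySurface(gp=result.gp, space=result.space,
                          trace=result.trace)


def sample_baseline_design(n_blocks: int, n_arms: int,
                           rng: np.random.Generator) -> Design:
    """Baseline design: every reward probability drawn from Beta(2, 2)."""
    return Design(rng.beta(2.0, 2.0, size=(n_blocks, n_arms)))
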