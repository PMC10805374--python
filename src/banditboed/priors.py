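"""Prior distributions over models and model parameters.

Uninformative priors: a uniform model prior and independent uniform
distributions per parameter, on ranges wide enough to contain the classic
nested models (Win-Stay Lose-Shift, plain epsilon-greedy, history-independent
latent switching). Degenerate ranges (lo == hi) are permitted, which gives
point-mass priors useful for constructing exactly solvable test problems.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .models import Model, PARAM_CLASSES, params_from_array

__all__ = ["PriorSpec", "default_prior", "sample_prior", "sample_params"]

GOAL_MD = "MD"
GOAL_PE = "PE"

_DEFAULT_RANGES = {
    Model.WSLTS: {"gamma_win": (0.0, 1.0), "gamma_lose": (0.0, 1.0),
                  "tau": (0.0, 5.0)},
    Model.AEG: {"epsilon": (0.0, 1.0), "rho": (-3.0, 3.0)},
    Model.GLS: {"beta0": (-3.0, 3.0), "beta_z": (-3.0, 3.0),
                "beta_r": (-3.0, 3.0)},
}


@dataclass(frozen=True)
class PriorSpec:
    """Model prior (simplex over the 3 models) and per-parameter uniform ranges.

    ``ranges[model]`` maps each parameter field name to an inclusive
    (low, high) interval with low <= high.
    """

    model_prior: np.ndarray = field(
        default_factory=lambda: np.full(3, 1.0 / 3.0))
    ranges: dict = field(default_factory=lambda: {
        m: dict(r) for m, r in _DEFAULT_RANGES.items()})

    def __post_init__(self) -> None:
        mp = np.asarray(self.model_prior, dtype=float)
        if mp.shape != (3,) or np.any(mp < 0) or abs(mp.sum() - 1.0) > 1e-9:
            raise ValueError("model_prior must be a length-3 simplex")
        object.__setattr__(self, "model_prior", mp)
        ranges = {Model.parse(m): dict(r) for m, r in self.ranges.items()}
        for m, r in ranges.items():
            expected = PARAM_CLASSES[m].fields
            if tuple(r) != tuple(expected):
                raise ValueError(
                    f"{m.name} ranges must cover fields {expected}")
            for name, (lo, hi) in r.items():
                if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
                    raise ValueError(f"invalid range for {m.name}.{name}")
        object.__setattr__(self, "ranges", ranges)

    def bounds(self, model: Model) -> np.ndarray:
        """(P, 2) array of parameter bounds for a model."""
        m = Model.parse(model)
        return np.array([self.ranges[m][f] for f in PARAM_CLASSES[m].fields])

    def with_model_prior(self, model_prior) -> "PriorSpec":
        return PriorSpec(np.asarray(model_prior, dtype=float), self.ranges)

    def with_ranges(self, model, **ranges) -> "PriorSpec":
        m = Model.parse(model)
        new = {k: dict(v) for k, v in self.ranges.items()}
        new[m].update({k: tuple(v) for k, v in ranges.items()})
        return PriorSpec(self.model_prior, new)

    def log_density(self, model, params_arr: np.ndarray) -> np.ndarray:
        """Log prior density of parameter vectors (rows) for one model."""
        b = self.bounds(model)
        arr = np.atleast_2d(np.asarray(params_arr, dtype=float))
        width = np.where(b[:, 1] > b[:, 0], b[:, 1] - b[:, 0], 1.0)
        inside = np.all((arr >= b[None, :, 0] - 1e-12)
                        & (arr <= b[None, :, 1] + 1e-12), axis=1)
        logd = -np.log(width).sum()
        return np.where(inside, logd, -np.inf)


def default_prior() -> PriorSpec:
    return PriorSpec()


def sample_params(model, prior: PriorSpec, rng: np.random.Generator,
                  n: Optional[int] = None):
    """Draw parameter vectors i.i.d. from the uniform prior of one model.

    Returns a params object with scalar fields if ``n`` is None, otherwise
    with length-n array fields.
    """
    m = Model.parse(model)
    b = prior.bounds(m)
    size = (b.shape[0],) if n is None else (n, b.shape[0])
    u = rng.random(size)
    arr = b[:, 0] + u * (b[:, 1] - b[:, 0])
    return params_from_array(m, arr)


def sample_prior(goal: str, prior: PriorSpec, rng: np.random.Generator,
                 model=None):
    """Draw from the prior: (model, params) for MD, params for PE.

    For parameter estimation (PE) the model must be given; for model
    discrimination (MD) the model indicator is drawn from the model prior
    and the parameters from that model's parameter prior.
    """
    goal = str(goal).upper()
    if goal == GOAL_PE:
        if model is None:
            raise ValueError("parameter estimation requires a model")
        return sample_params(model, prior, rng)
    if goal != GOAL_MD:
        raise ValueError(f"goal must be '{GOAL_MD}' or '{GOAL_PE}'")
    m = Model(int(rng.choice(3, p=prior.model_prior)))
    return m, sample_params(m, prior, rng)
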