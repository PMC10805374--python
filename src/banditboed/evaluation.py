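"""In-silico validation and statistical evaluation of designs.

Model-recovery confusion matrices, posterior entropy metrics (Shannon for
model posteriors, k-nearest-neighbor differential entropy for parameter
posteriors), parameter recovery, posterior parameter disentanglement
(Fisher-z-transformed Pearson correlations), and the group-comparison tests
(Welch's t, chi-square on allocation tables). All entropies are in nats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree
from scipy.special import digamma, gammaln

from .critic import (
    CriticEnsemble,
    amortized_model_posteriors,
    amortized_parameter_weights,
    encode_experiments,
)
from .models import Design, Model, params_from_array, params_to_array
from .priors import PriorSpec, sample_params
from .simulate import simulate_experiments_batch

__all__ = [
    "map_model",
    "confusion_matrix",
    "ConfusionMatrix",
    "shannon_entropy",
    "differential_entropy",
    "disentanglement",
    "DisentanglementReport",
    "welch_t",
    "chi_square_independence",
    "parameter_recovery",
    "RecoveryReport",
]


def map_model(posterior: np.ndarray,
              rng: Optional[np.random.Generator] = None) -> Model:
    """Maximum a posteriori model; ties broken uniformly at random.

    The tie-break generator defaults to a fixed seed so repeated calls on the
    same posterior are reproducible unless a generator is supplied.
    """
    p = np.asarray(posterior, dtype=float)
    if p.ndim != 1 or abs(p.sum() - 1.0) > 1e-6 or np.any(p < 0):
        raise ValueError("posterior must be a probability simplex")
    winners = np.flatnonzero(p >= p.max() - 1e-12)
    if winners.size == 1:
        return Model(int(winners[0]))
    rng = rng or np.random.default_rng(0)
    return Model(int(rng.choice(winners)))


@dataclass(frozen=True)
class ConfusionMatrix:
    """Rows = generating model, columns = MAP-inferred model."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (3, 3) or np.any(c < 0):
            raise ValueError("counts must be a nonnegative 3x3 table")
        object.__setattr__(self, "counts", c)

    @property
    def row_normalized(self) -> np.ndarray:
        rows = self.counts.sum(axis=1, keepdims=True)
        return self.counts / np.where(rows > 0, rows, 1)

    @property
    def mean_diagonal(self) -> float:
        return float(np.diag(self.row_normalized).mean())

    def to_frame(self) -> pd.DataFrame:
        names = [m.name for m in Model]
        return pd.DataFrame(self.counts, index=names, columns=names)


def confusion_matrix(design: Design, prior: PriorSpec,
                     ensemble: Optional[CriticEnsemble],
                     n_per_model: int, rng: np.random.Generator,
                     n_trials: int = 30,
                     posterior_fn: Optional[Callable] = None
                     ) -> ConfusionMatrix:
    """Simulate n_per_model experiments per model and tabulate MAP recovery.

    Posteriors come from the trained ensemble; ``posterior_fn`` (mapping a
    batch of encoded experiments to (n, 3) posteriors) can replace it, e.g.
    with the exact enumeration posterior on toy problems.
    """
    if posterior_fn is None:
        if ensemble is None:
            raise ValueError("either an ensemble or posterior_fn is required")
        posterior_fn = lambda y: amortized_model_posteriors(  # noqa: E731
            ensemble, y, prior)
    counts = np.zeros((3, 3), dtype=np.int64)
    tie_rng = np.random.default_rng(int(rng.integers(0, 2 ** 31 - 1)))
    for m in Model:
        params = sample_params(m, prior, rng, n=n_per_model)
        acts, rews = simulate_experiments_batch(
            m, params, design, n_trials, rng, n_per_model)
        y = encode_experiments(acts, rews, design.n_arms)
        posts = posterior_fn(y)
        for row in posts:
            counts[m, int(map_model(row, tie_rng))] += 1
    return ConfusionMatrix(counts)


def shannon_entropy(p: np.ndarray) -> float:
    """-sum p log p in nats, with 0 log 0 = 0."""
    p = np.asarray(p, dtype=float)
    if abs(p.sum() - 1.0) > 1e-6 or np.any(p < 0):
        raise ValueError("input must be a probability simplex")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def differential_entropy(samples: np.ndarray,
                         weights: Optional[np.ndarray] = None,
                         k: int = 3,
                         rng: Optional[np.random.Generator] = None) -> float:
    """Kozachenko-Leonenko k-nearest-neighbor differential entropy (nats).

    Weighted posterior samples are first resampled to equal weights. The
    estimate is digamma(n) - digamma(k) + log c_d + d * mean(log eps_i) with
    eps_i the distance to the k-th neighbor and c_d the unit-ball volume.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n, d = x.shape
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        ess = w.sum() ** 2 / (w ** 2).sum()
        if ess < 100:
            import warnings
            warnings.warn(f"effective sample size {ess:.1f} < 100; "
                          "entropy estimate may be unreliable")
        rng = rng or np.random.default_rng(0)
        idx = rng.choice(n, size=n, p=w / w.sum())
        x = x[idx]
    if n < k + 1:
        raise ValueError("need at least k+1 samples")
    # tiny jitter breaks exact duplicates produced by resampling
    jit = np.random.default_rng(0).normal(0.0, 1e-10, size=x.shape)
    tree = cKDTree(x + jit)
    dist, _ = tree.query(x + jit, k=k + 1)
    eps = np.maximum(dist[:, k], 1e-300)
    log_cd = (d / 2.0) * math.log(math.pi) - gammaln(d / 2.0 + 1.0)
    return float(digamma(n) - digamma(k) + log_cd + d * np.mean(np.log(eps)))


_Z_CAP = math.atanh(1.0 - 1e-12)


def _weighted_corr(x: np.ndarray, w: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Weighted Pearson correlation matrix; flags zero-variance parameters."""
    w = w / w.sum()
    mu = w @ x
    xc = x - mu
    cov = (xc * w[:, None]).T @ xc
    var = np.diag(cov).copy()
    ok = var > 0
    corr = np.eye(x.shape[1])
    sd = np.sqrt(np.where(ok, var, 1.0))
    denom = np.outer(sd, sd)
    with np.errstate(invalid="ignore"):
        full = cov / denom
    mask = np.outer(ok, ok)
    corr = np.where(mask, full, np.nan)
    np.fill_diagonal(corr, 1.0)
    return np.clip(corr, -1.0, 1.0), ok


@dataclass(frozen=True)
class DisentanglementReport:
    """Per-dataset posterior parameter correlations and Fisher z summary."""

    correlations: Tuple[np.ndarray, ...]
    fisher_z: Tuple[np.ndarray, ...]
    mean_abs_z: np.ndarray
    degenerate_flags: Tuple[np.ndarray, ...]


def disentanglement(posterior_samples: Sequence[np.ndarray],
                    weights: Optional[Sequence[np.ndarray]] = None
                    ) -> DisentanglementReport:
    """Posterior parameter disentanglement per dataset.

    For each dataset's (weighted) posterior samples: the Pearson correlation
    matrix, the Fisher z transform atanh(r) of every below-diagonal entry
    (capped at atanh(1 - 1e-12)), and the mean |z|. Pairs involving a
    zero-variance parameter are recorded as undefined and excluded from the
    mean.
    """
    corrs, zs, means, flags = [], [], [], []
    for i, x in enumerate(posterior_samples):
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] < 2:
            raise ValueError("need at least 2 parameters")
        w = (np.ones(x.shape[0]) if weights is None
             else np.asarray(weights[i], dtype=float))
        corr, ok = _weighted_corr(x, w)
        tri = np.tril_indices(x.shape[1], -1)
        r = corr[tri]
        with np.errstate(invalid="ignore"):
            z = np.arctanh(np.clip(r, -1 + 1e-12 / 2, 1 - 1e-12 / 2))
        z = np.clip(z, -_Z_CAP, _Z_CAP)
        valid = ~np.isnan(r)
        corrs.append(corr)
        zs.append(np.where(valid, z, np.nan))
        means.append(np.abs(z[valid]).mean() if valid.any() else np.nan)
        flags.append(~ok)
    return DisentanglementReport(tuple(corrs), tuple(zs),
                                 np.asarray(means), tuple(flags))


def welch_t(group_a: Sequence[float], group_b: Sequence[float]
            ) -> Tuple[float, float, float]:
    """Two-sided Welch's t-test: (t, Welch-Satterthwaite df, p)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if a.var(ddof=1) <= 0 or b.var(ddof=1) <= 0:
        raise ValueError("each group needs positive variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def chi_square_independence(table) -> Tuple[float, int, float]:
    """Pearson chi-square test of independence (no continuity correction)."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or np.any(t < 0) or t.sum() <= 0:
        raise ValueError("table must be a nonnegative 2-d contingency table")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("table has an all-zero row or column")
    res = stats.chi2_contingency(t, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


@dataclass(frozen=True)
class RecoveryReport:
    """Parameter-recovery aggregates across simulated ground truths."""

    true_values: np.ndarray  # (R, P)
    posterior_means: np.ndarray  # (R, P)
    posterior_sds: np.ndarray  # (R, P)
    interval_low: np.ndarray  # (R, P) central 90% interval
    interval_high: np.ndarray
    coverage: np.ndarray  # (P,) fraction of truths inside the interval
    bias: np.ndarray  # (P,) mean(posterior mean - truth)

    @property
    def mean_posterior_sd(self) -> np.ndarray:
        return self.posterior_sds.mean(axis=0)


def _weighted_quantile(x: np.ndarray, w: np.ndarray, q: float) -> float:
    order = np.argsort(x)
    cw = np.cumsum(w[order])
    cw /= cw[-1]
    return float(np.interp(q, cw, x[order]))


def parameter_recovery(model, design: Design, prior: PriorSpec,
                       ensemble: CriticEnsemble, true_params_list,
                       rng: np.random.Generator, n_trials: int = 30,
                       n_prior_samples: int = 2000,
                       interval: float = 0.9) -> RecoveryReport:
    """Simulate experiments at known parameters and summarize the posteriors.

    For each true parameter vector: simulate one experiment at the design,
    compute the amortized weighted-sample posterior, and record marginal
    means, standard deviations and central credible intervals; aggregates
    bias and coverage per parameter.
    """
    m = Model.parse(model)
    truths = np.atleast_2d(np.asarray(
        [params_to_array(p).ravel() if not isinstance(p, np.ndarray) else p
         for p in true_params_list], dtype=float))
    R, P = truths.shape
    params = params_from_array(m, truths)
    acts, rews = simulate_experiments_batch(m, params, design, n_trials,
                                            rng, R)
    y = encode_experiments(acts, rews, design.n_arms)
    theta = params_to_array(sample_params(m, prior, rng, n=n_prior_samples))
    W = amortized_parameter_weights(ensemble, y, theta, prior)  # (R, Ns)
    means = W @ theta
    second = W @ theta ** 2
    sds = np.sqrt(np.maximum(second - means ** 2, 0.0))
    lo_q, hi_q = (1 - interval) / 2, 1 - (1 - interval) / 2
    low = np.empty((R, P))
    high = np.empty((R, P))
    for i in range(R):
        for j in range(P):
            low[i, j] = _weighted_quantile(theta[:, j], W[i], lo_q)
            high[i, j] = _weighted_quantile(theta[:, j], W[i], hi_q)
    coverage = ((truths >= low) & (truths <= high)).mean(axis=0)
    bias = (means - truths).mean(axis=0)
    return RecoveryReport(true_values=truths, posterior_means=means,
                          posterior_sds=sds, interval_low=low,
                          interval_high=high, coverage=coverage, bias=bias)
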