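# Methods

This note documents the models, estimators, and numerical choices behind
`banditboed`, and what the package's synthetic validation does and does not
establish.

## Task and design space

A session has B blocks of T trials on a K-armed Bernoulli bandit
(defaults K = 3, T = 30; B = 2 for model discrimination, B = 3 for
parameter estimation). The design **d** is the (B × K) matrix of arm reward
probabilities, each in [0, 1] — a 6-dimensional space for MD and
9-dimensional for PE. Blocks are exchangeable: the learner's belief resets
at each block start and no knowledge transfers across blocks. A block's data
are its T actions (0-based arm indices) and T rewards ({0, 1}), encoded for
the networks as actions rescaled to [0, 1] followed by rewards — 2T = 60
numbers per block (a one-hot action encoding is available as a config
option). Baseline designs, for all comparisons, draw every reward
probability from Beta(2, 2).

## Behavioral models

All three models share a Beta(1, 1)-initialized Beta-Bernoulli belief
(α_k, β_k) per arm, updated by the observed reward of the chosen arm.
"Greedy" always means a uniform tie-break over the argmax arms of the
posterior means α_k/(α_k + β_k).

**WSLTS(γ_win, γ_lose, τ).** Let q be the vector of probabilities that each
arm's Beta draw is the largest, and let the reshaped Thompson distribution
be π ∝ q^τ (τ = 1: Thompson sampling; τ = 0: uniform; τ → ∞: greedy on q).
Trial 1 samples from π. After a reward, stay with probability γ_win,
otherwise sample from π over all arms. After a non-reward, with probability
γ_lose sample from π restricted to the other arms (renormalized — equivalent
to redrawing the Thompson winner until it differs from the previous arm),
otherwise stay. With τ = 0 and γ_win = γ_lose = γ this is exactly Win-Stay
Lose-Shift: after a loss each other arm receives γ/(K − 1).

**AEG(ε, ρ).** Base policy π_eg = (1 − ε)·greedy + ε/K. From trial 2 the
previous arm's probability is multiplied by e^ρ and the vector renormalized;
ρ = 0 recovers textbook ε-greedy, ρ > 0 is sticky, ρ < 0 anti-sticky.

**GLS(β₀, β_z, β_r).** A binary latent state drawn every trial: explore
with probability σ(β₀) at trial 1 and σ(β₀ + β_z·1[was exploring] +
β_r·previous reward) afterwards. Exploring chooses uniformly; exploiting
chooses greedily. β_z = β_r = 0 gives history-independent switching.

**Priors.** Model indicator uniform over the three models; γ_win, γ_lose,
ε ~ U(0, 1); τ ~ U(0, 5); ρ, β₀, β_z, β_r ~ U(−3, 3). Ranges are
uninformative and contain the nested classic models. Degenerate ranges
(lo = hi) are allowed and used to build exactly solvable test problems.

**q by quadrature.** q_k = ∫ f_k(x) Π_{j≠k} F_j(x) dx on a fixed
2001-point trapezoid grid over [0, 1], renormalized; accurate to ~1e−5 for
the pseudo-counts reachable within T ≤ 30. Grid rows per (α, β) pair and
per-state q vectors are memoized, and the simulator is vectorized across
learners (a Python loop only over trials), which is what makes the
validation studies run in minutes.

**Two code paths.** The batch simulator and the likelihood evaluator
implement the same behavioral rules independently; for GLS the likelihood
marginalizes the latent path with a rescaled two-state forward recursion,
verified against full latent-path enumeration to 1e−10. Simulated sequence
frequencies from 10^6 tiny blocks match exact likelihoods to < 0.002 per
sequence for all three models.

## Exact oracle

For small instances the package enumerates all (2K)^(T·B) outcome sequences
(budget 10^6) and computes mutual information, marginals and per-outcome
posteriors exactly. Continuous parameters are handled by discretizing each
non-degenerate prior dimension on a uniform grid (default 15 points); the MI
of the discretized prior is the documented oracle quantity. All information
quantities are in nats. The oracle is a verification tool, not a production
path: at the study scale (T = 30, B = 2) enumeration is astronomically
infeasible, which is precisely why the neural estimator exists.

## Neural mutual-information estimation

The critic T(v, y) is a feed-forward network: one sub-network per block
(default widths 2T → 64 → 32 → S = 8, ReLU) produces learned summary
statistics; their concatenation with the encoded v (one-hot model indicator
for MD, prior-range min-max-scaled parameters for PE) feeds a joint network
(default 128 → 64 → 1). Training maximizes the variational lower bound
mean[T(v, y)] − mean[e^{T(v', y) − 1}], where the marginal pairs v' come
from a cyclic within-batch shift after shuffling (a derangement — no record
keeps its own v). Optimization is Adam (lr 1e−3, batch 256, default 200
epochs; the toy problems and validation studies use 20-60 epochs and
smaller widths, recorded in the code). The exponent in the marginal term is
clipped at 30 during training to keep early gradients finite; evaluation is
unclipped and deterministic. The networks are plain numpy with manual
backpropagation — the package has no deep-learning dependency.

MI at a design is the bound evaluated on a held-out fraction (default 20%)
of the simulated records, with a 200-resample batch bootstrap standard
error. Because the estimator is a lower bound, held-out values sit at or
below the exact MI; on the enumerable toys the gap is ≤ 0.02-0.05 nats at
n = 50,000 training records.

**Amortized posteriors.** Each trained critic yields
p(v|y, d) ∝ p(v)·e^{T(v,y) − 1}, explicitly renormalized (the bound's
tightness makes the expression only approximately self-normalizing). MD
posteriors evaluate the three one-hot v's; PE posteriors are self-normalized
importance weights over shared prior samples (default 10,000; the studies
use 2,000). Ensembles of independently trained critics (fresh simulations
per member; default size 50, studies use 2-10) average member posteriors
and renormalize. On the 64-outcome toy an ensemble of 10 reaches mean
total-variation distance < 0.05 from the exact posteriors.

## Design optimization

The held-out MI estimate at a design is a noisy black-box objective.
Bayesian optimization uses scrambled Sobol initialization (max(8, 2D)
points), a Gaussian process with Matérn-5/2 kernel and a fitted white-noise
term (the median reported SE seeds the noise floor), and Expected
Improvement maximized by random/quasi-random candidates plus L-BFGS-B
polishing. Constraint-violating candidates are rejected and resampled, with
an error after 1,000 failed attempts per point. The incumbent is the trace
argmax of observed MI — robust at small budgets — with the surrogate-mean
argmax reported alongside; the fitted surrogate is exportable as a utility
surface (dense grid for D ≤ 3, a 2-d slice through the incumbent otherwise,
plus top-k extraction). Optional block canonicalization sorts blocks
lexicographically before GP fitting, exploiting block exchangeability.

## Evaluation metrics

* MAP model selection with uniformly random, seeded tie-breaks; 3×3
  confusion matrices (rows = generating model).
* Shannon entropy (nats) for model posteriors; differential entropy for
  parameter posteriors by the Kozachenko–Leonenko k-nearest-neighbor
  estimator (k = 3) after equal-weight resampling, with a 1e−10 jitter to
  break resampling duplicates. Verified within 0.05 nats on Gaussians in
  1-3 dimensions at n = 50,000.
* Disentanglement: weighted Pearson correlations of posterior samples
  (importance weights used directly, no resampling), Fisher z = atanh(r)
  capped at atanh(1 − 1e−12), mean |z| per dataset; zero-variance
  parameters are flagged and their pairs excluded.
* Group comparisons: two-sided Welch's t (Welch–Satterthwaite df) and
  Pearson chi-square without continuity correction.

## Validation studies and their scale

`banditboed.studies` compares the reported optimal designs against Beta(2,2)
baselines at reduced size: per design, an ensemble of M = 2 critics trained
on 4,000 simulated experiments (30 epochs), then 300 MAP recoveries per
model (MD) or 200 simulated subjects with 2,000-sample posteriors (PE).
At this scale the optimal MD design's mean confusion diagonal exceeds the
baseline average by roughly 10-20 points, reproducing the qualitative
recovery advantage; absolute diagonals are below what full-scale training
would give.

**Identifiability note (PE).** Under this package's WSLTS form, γ_win is
weakly identified at every design: a repeated choice is explained both by
the stay mechanism and by the Thompson term, whose probability-of-best mass
concentrates on a winning arm, so its posterior SD stays near the prior SD
(≈ 0.289) for optimal and baseline designs alike. The PE study therefore
reports per-parameter posterior SDs and takes as its headline comparison the
prior-normalized SD averaged over the three parameters, where the optimal
design's advantage (≈ 0.85 vs ≈ 0.94) is stable; γ_lose and τ individually
show clear dominance.

## What the synthetic validation does not show

The simulators are the data-generating truth in every study here, so passing
tests establish internal consistency — correct likelihoods, a valid and
reasonably tight MI bound, faithful amortized posteriors, a working search —
not that these models describe human behavior, nor that designs optimized
under them remain optimal under model misspecification, strategy switching,
or cross-block learning, all of which real participants may exhibit.
Reported human-study statistics can be recomputed only where the printed
summary tables suffice (the allocation chi-square); the empirical entropy
distributions require the original dataset and are out of scope.

## Degenerate inputs and tie-breaks

Greedy ties are uniform over argmax arms; reshaped-Thompson underflow at
extreme τ falls back to greedy-on-q; a fully suppressed shift distribution
(Thompson mass entirely on the previous arm) falls back to uniform over the
other arms; zero-evidence posteriors return the prior; −∞ log likelihoods
mark impossible sequences and propagate correctly through marginalization.
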