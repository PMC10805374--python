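"""Simulator models: priors, policies, learner beliefs, block simulation."""

import numpy as np
import pytest

from banditboed.models import (
    AEGParams,
    BehaviorBlock,
    Design,
    GLSParams,
    LearnerState,
    Model,
    WSLTSParams,
    gls_transition,
    policy_probabilities,
    prob_best_arm,
)
from banditboed.oracle import block_log_likelihood
from banditboed.priors import default_prior, sample_params, sample_prior
from banditboed.simulate import simulate_block, simulate_blocks_batch, simulate_experiment
from scipy.special import expit
from scipy.stats import ks_2samp


class TestPriors:
    def test_md_model_frequencies_uniform(self):
        rng = np.random.default_rng(0)
        prior = default_prior()
        draws = [sample_prior("MD", prior, rng)[0] for _ in range(30000)]
        freqs = np.bincount(draws, minlength=3) / 30000
        assert np.all(np.abs(freqs - 1 / 3) < 0.01)

    def test_pe_uniform_moments(self):
        rng = np.random.default_rng(1)
        prior = default_prior()
        wslts = sample_params(Model.WSLTS, prior, rng, n=30000)
        assert abs(np.mean(wslts.gamma_win) - 0.5) < 0.01
        gls = sample_params(Model.GLS, prior, rng, n=30000)
        # Var(U(-3, 3)) = 36/12 = 3
        assert abs(np.var(gls.beta0) / 3.0 - 1.0) < 0.05

    def test_unknown_model_rejected_with_valid_names(self):
        with pytest.raises(ValueError, match="WSLTS.*AEG.*GLS"):
            sample_prior("PE", default_prior(), np.random.default_rng(0),
                         model="QLEARNING")

    def test_pe_requires_model(self):
        with pytest.raises(ValueError, match="requires a model"):
            sample_prior("PE", default_prior(), np.random.default_rng(0))


class TestProbBestArm:
    def test_symmetric_beliefs_are_uniform(self):
        q = prob_best_arm(LearnerState.fresh(3))
        assert np.allclose(q, 1 / 3, atol=1e-6)

    def test_two_arm_asymmetric_matches_closed_form(self):
        # P(Beta(2,1) > Beta(1,2)) = 5/6 by direct double integration
        state = LearnerState(np.array([2.0, 1.0]), np.array([1.0, 2.0]))
        q = prob_best_arm(state)
        assert abs(q[0] - 5 / 6) < 1e-4

    def test_dominant_arm_limit(self):
        state = LearnerState(np.array([50.0, 1.0]), np.array([1.0, 50.0]))
        assert prob_best_arm(state)[0] > 0.999

    def test_output_is_simplex(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            counts = rng.integers(1, 20, size=(2, 4)).astype(float)
            q = prob_best_arm(LearnerState(counts[0], counts[1]))
            assert abs(q.sum() - 1.0) < 1e-9 and np.all(q >= 0)


class TestPolicies:
    def test_aeg_pure_random(self):
        pi = policy_probabilities(Model.AEG, AEGParams(1.0, 0.0),
                                  LearnerState.fresh(3))
        assert np.allclose(pi, 1 / 3)

    def test_wslts_deterministic_stay_after_win(self):
        pi = policy_probabilities(Model.WSLTS, WSLTSParams(1.0, 0.5, 1.0),
                                  LearnerState.fresh(3), prev_action=2,
                                  prev_reward=1)
        assert np.allclose(pi, [0, 0, 1])

    def test_aeg_sticky_reweighting(self):
        # tied posterior means, eps=0.5, rho=ln 2: [1/2*2, 1/2] -> [2/3, 1/3]
        pi = policy_probabilities(Model.AEG, AEGParams(0.5, np.log(2)),
                                  LearnerState.fresh(2), prev_action=0,
                                  prev_reward=1)
        assert np.allclose(pi, [2 / 3, 1 / 3])

    def test_aeg_sticky_matches_simulation(self):
        rng = np.random.default_rng(3)
        params = AEGParams(0.5, float(np.log(2)))
        # simulate one trial after a forced previous action on arm 0
        n = 10 ** 6
        from banditboed.models import aeg_policy_batch
        pi = aeg_policy_batch(params, np.ones((1, 2)), np.ones((1, 2)),
                              np.zeros(1, dtype=int))[0]
        draws = rng.choice(2, size=n, p=pi)
        assert abs(draws.mean() - 1 / 3) < 3 * np.sqrt(2 / 9 / n) + 2e-3

    def test_wslts_tau_zero_reduces_to_win_stay_lose_shift(self):
        # tau=0, gamma_win=gamma_lose=g: after a loss each non-previous arm
        # receives g/(K-1)
        g = 0.8
        K = 4
        pi = policy_probabilities(Model.WSLTS, WSLTSParams(g, g, 0.0),
                                  LearnerState.fresh(K), prev_action=1,
                                  prev_reward=0)
        expected = np.full(K, g / (K - 1))
        expected[1] = 1 - g
        assert np.allclose(pi, expected)

    def test_aeg_rho_zero_is_textbook_epsilon_greedy(self):
        eps = 0.3
        state = LearnerState(np.array([3.0, 1.0, 1.0]),
                             np.array([1.0, 2.0, 2.0]))
        pi = policy_probabilities(Model.AEG, AEGParams(eps, 0.0), state,
                                  prev_action=1, prev_reward=0)
        expected = np.array([1 - eps + eps / 3, eps / 3, eps / 3])
        assert np.allclose(pi, expected)

    def test_gls_requires_latent_state(self):
        with pytest.raises(ValueError, match="latent_state"):
            policy_probabilities(Model.GLS, GLSParams(0.0, 0.0, 0.0),
                                 LearnerState.fresh(3), prev_action=0,
                                 prev_reward=1)

    def test_history_args_must_be_paired(self):
        with pytest.raises(ValueError, match="both"):
            policy_probabilities(Model.AEG, AEGParams(0.5, 0.0),
                                 LearnerState.fresh(3), prev_action=0)

    def test_policy_outputs_are_simplices_under_random_inputs(self):
        rng = np.random.default_rng(4)
        prior = default_prior()
        n = 10000
        counts_a = rng.integers(1, 12, size=(n, 3)).astype(float)
        counts_b = rng.integers(1, 12, size=(n, 3)).astype(float)
        prev = rng.integers(0, 3, size=n)
        rew = rng.integers(0, 2, size=n)
        from banditboed.models import (aeg_policy_batch, gls_policy_batch,
                                       prob_best_arm_batch,
                                       wslts_policy_batch)
        w = sample_params(Model.WSLTS, prior, rng, n=n)
        q = prob_best_arm_batch(counts_a, counts_b)
        for pi in (
            wslts_policy_batch(w, q, prev, rew),
            aeg_policy_batch(sample_params(Model.AEG, prior, rng, n=n),
                             counts_a, counts_b, prev),
            gls_policy_batch(counts_a, counts_b, rng.integers(0, 2, size=n)),
        ):
            assert np.all(pi >= 0)
            assert np.allclose(pi.sum(axis=1), 1.0, atol=1e-9)


class TestGLSTransition:
    def test_trial_one_is_sigmoid_beta0(self):
        assert gls_transition(GLSParams(0.0, 1.0, 1.0)) == pytest.approx(0.5)

    def test_saturation(self):
        assert gls_transition(GLSParams(-10.0, 0.0, 0.0), 0, 0) < 5e-5

    def test_cancellation(self):
        p = gls_transition(GLSParams(0.0, 1.0, -1.0), prev_latent=1,
                           prev_reward=1)
        assert p == pytest.approx(0.5)

    def test_history_independent_when_coefficients_zero(self):
        params = GLSParams(0.7, 0.0, 0.0)
        vals = {gls_transition(params, z, r) for z in (0, 1) for r in (0, 1)}
        assert len({round(v, 12) for v in vals}) == 1
        assert vals.pop() == pytest.approx(expit(0.7))


class TestSimulation:
    def test_guaranteed_wins_with_stay_policy_repeat_forever(self):
        rng = np.random.default_rng(5)
        blk = simulate_block(Model.WSLTS, WSLTSParams(1.0, 0.5, 1.0),
                             np.array([1.0, 1.0, 1.0]), 10, rng)
        assert len(set(blk.actions.tolist())) == 1
        assert np.all(blk.rewards == 1)

    def test_uniform_policy_choice_frequencies(self):
        rng = np.random.default_rng(6)
        a, _ = simulate_blocks_batch(Model.AEG, AEGParams(1.0, 0.0),
                                     np.array([0.5, 0.5, 0.5]), 1, rng,
                                     n_sims=30000)
        freqs = np.bincount(a[:, 0], minlength=3) / 30000
        assert np.all(np.abs(freqs - 1 / 3) < 0.01)

    def test_invalid_trial_count_rejected(self):
        with pytest.raises(ValueError, match="n_trials"):
            simulate_block(Model.AEG, AEGParams(0.5, 0.0),
                           np.array([0.5, 0.5]), 0, np.random.default_rng(0))

    def test_fixed_seed_reproducibility(self):
        design = Design(np.array([[0.3, 0.6, 0.9], [0.9, 0.1, 0.5]]))
        runs = []
        for _ in range(2):
            rng = np.random.default_rng(123)
            runs.append(simulate_experiment(
                Model.GLS, GLSParams(0.2, -0.5, 1.0), design, rng, 30))
        for b1, b2 in zip(runs[0].blocks, runs[1].blocks):
            assert np.array_equal(b1.actions, b2.actions)
            assert np.array_equal(b1.rewards, b2.rewards)

    def test_flattened_dimensionality_is_60_per_block(self):
        design = Design(np.full((5, 3), 0.5))
        rng = np.random.default_rng(7)
        exp = simulate_experiment(Model.AEG, AEGParams(0.5, 0.0), design,
                                  rng, 30)
        enc = exp.encode(3)
        assert enc.shape == (5, 60)
        assert enc.size == 300

    def test_identical_blocks_have_identical_reward_distributions(self):
        rng = np.random.default_rng(8)
        params = sample_params(Model.WSLTS, default_prior(), rng, n=20000)
        arm_probs = np.array([0.7, 0.3, 0.5])
        _, r1 = simulate_blocks_batch(Model.WSLTS, params, arm_probs, 10,
                                      rng, 20000)
        _, r2 = simulate_blocks_batch(Model.WSLTS, params, arm_probs, 10,
                                      rng, 20000)
        p = ks_2samp(r1.sum(axis=1), r2.sum(axis=1)).pvalue
        assert p > 0.01


def _reference_wslts_block(gamma_win, gamma_lose, arm_probs, n_trials, rng):
    """Straight-line reimplementation of WSLTS at tau=1.

    Thompson steps draw Beta samples directly and take the argmax; the
    lose-shift draws are rejection-sampled to exclude the previous arm. This
    shares no code with the quadrature-based policy path.
    """
    K = len(arm_probs)
    alpha = np.ones(K)
    beta = np.ones(K)
    prev = prev_r = None
    actions = []
    for _ in range(n_trials):
        if prev is None:
            a = int(np.argmax(rng.beta(alpha, beta)))
        elif prev_r == 1:
            if rng.random() < gamma_win:
                a = prev
            else:
                a = int(np.argmax(rng.beta(alpha, beta)))
        else:
            if rng.random() < gamma_lose:
                while True:
                    a = int(np.argmax(rng.beta(alpha, beta)))
                    if a != prev:
                        break
            else:
                a = prev
        r = int(rng.random() < arm_probs[a])
        if r:
            alpha[a] += 1
        else:
            beta[a] += 1
        actions.append(a)
        prev, prev_r = a, r
    return actions


def test_wslts_simulator_matches_independent_reimplementation():
    """Mean arm-2 visits agree between the two WSLTS implementations."""
    arm_probs = np.array([1.0, 1.0, 0.0])
    params = WSLTSParams(0.9, 0.9, 1.0)
    rng = np.random.default_rng(9)
    a, _ = simulate_blocks_batch(Model.WSLTS, params, arm_probs, 30, rng,
                                 n_sims=10000)
    count_pkg = (a == 2).sum(axis=1)
    ref_rng = np.random.default_rng(10)
    count_ref = np.array([
        np.sum(np.array(_reference_wslts_block(0.9, 0.9, arm_probs, 30,
                                               ref_rng)) == 2)
        for _ in range(4000)])
    se = np.sqrt(count_pkg.var() / count_pkg.size
                 + count_ref.var() / count_ref.size)
    assert abs(count_pkg.mean() - count_ref.mean()) < 4 * se + 0.05


@pytest.mark.parametrize("model,params", [
    (Model.WSLTS, WSLTSParams(0.7, 0.4, 1.3)),
    (Model.AEG, AEGParams(0.3, 0.8)),
    (Model.GLS, GLSParams(0.5, -1.0, 1.0)),
])
def test_simulator_frequencies_match_exact_likelihoods(model, params):
    """10^6 tiny blocks: empirical sequence frequencies vs exact likelihoods.

    The simulator and the likelihood walk the behavioral rules through two
    different code paths; their agreement per sequence must be within
    Monte-Carlo resolution (max absolute error < 0.002).
    """
    arm_probs = np.array([0.6, 0.3])
    T, n = 3, 10 ** 6
    rng = np.random.default_rng(hash(model) % 2 ** 31)
    a, r = simulate_blocks_batch(model, params, arm_probs, T, rng, n_sims=n)
    codes = np.zeros(n, dtype=np.int64)
    for t in range(T):
        codes = codes * 4 + a[:, t] * 2 + r[:, t]
    freqs = np.bincount(codes, minlength=4 ** T) / n
    import itertools
    max_err = 0.0
    for i, seq in enumerate(itertools.product(range(4), repeat=T)):
        acts = np.array([s // 2 for s in seq])
        rews = np.array([s % 2 for s in seq])
        ll = block_log_likelihood(model, params, BehaviorBlock(acts, rews),
                                  arm_probs)
        max_err = max(max_err, abs(np.exp(ll) - freqs[i]))
    assert max_err < 0.002
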