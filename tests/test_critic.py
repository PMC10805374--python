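"""MI critic: training sets, variational bound, training, posteriors."""

import dataclasses

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression

from banditboed import oracle
from banditboed.critic import (
    CriticConfig,
    CriticEnsemble,
    Posterior,
    amortized_model_posteriors,
    amortized_posterior,
    estimate_mi,
    extract_summaries,
    generate_training_set,
    load_critic,
    nwj_objective,
    save_critic,
    train_critic,
)
from banditboed.models import BehaviorBlock, Design, ExperimentData, Model
from banditboed.priors import default_prior
from banditboed.toys import certain_reward_toy
from tests.conftest import TOY_CONFIG


class TestGenerateTrainingSet:
    def test_model_counts_near_uniform(self):
        design, _, n_trials = certain_reward_toy()
        ts = generate_training_set(design, "MD", default_prior(), 9999,
                                   np.random.default_rng(0),
                                   n_trials=n_trials)
        counts = np.bincount(ts.v_raw.astype(int), minlength=3)
        assert np.all(np.abs(counts - 3333) < 0.03 * 9999)

    def test_determinism_given_seed(self):
        design, prior, n_trials = certain_reward_toy()
        a = generate_training_set(design, "MD", prior, 500,
                                  np.random.default_rng(42),
                                  n_trials=n_trials)
        b = generate_training_set(design, "MD", prior, 500,
                                  np.random.default_rng(42),
                                  n_trials=n_trials)
        assert np.array_equal(a.y, b.y) and np.array_equal(a.v_enc, b.v_enc)

    def test_dimensionality_120_for_two_blocks_of_30(self):
        design = Design(np.full((2, 3), 0.5))
        ts = generate_training_set(design, "MD", default_prior(), 10,
                                   np.random.default_rng(1), n_trials=30)
        assert ts.y.shape == (10, 2, 60)
        assert ts.y[0].size == 120

    def test_pe_requires_model(self):
        with pytest.raises(ValueError, match="requires a model"):
            generate_training_set(Design(np.full((1, 2), 0.5)), "PE",
                                  default_prior(), 10,
                                  np.random.default_rng(0), n_trials=2)


class TestNWJObjective:
    def test_constant_one_critic_is_exactly_zero(self):
        v = np.zeros((50, 3))
        y = np.zeros((50, 1, 4))
        const = lambda vv, yy: np.ones(np.atleast_2d(vv).shape[0])  # noqa: E731
        assert nwj_objective(const, (v, y), (v, y)) == 0.0

    @pytest.mark.parametrize("c", [-1.0, 0.0, 0.5, 1.0, 2.0])
    def test_constant_critic_never_positive(self, c):
        v = np.zeros((50, 3))
        y = np.zeros((50, 1, 4))
        critic = lambda vv, yy: np.full(np.atleast_2d(vv).shape[0], c)  # noqa: E731
        obj = nwj_objective(critic, (v, y), (v, y))
        assert obj <= 1e-12
        if c == 1.0:
            assert obj == 0.0

    def test_empty_batch_rejected(self):
        const = lambda vv, yy: np.ones(0)  # noqa: E731
        with pytest.raises(ValueError, match="empty"):
            nwj_objective(const, (np.empty((0, 3)), np.empty((0, 1, 4))),
                          (np.empty((0, 3)), np.empty((0, 1, 4))))

    def test_oracle_critic_attains_exact_mi(self, certain_toy):
        """The bound is tight at T*(v,y) = 1 + log posterior ratio."""
        design, prior, n_trials, exact = certain_toy
        mp = exact.model_posteriors()
        ts = generate_training_set(design, "MD", prior, 100000,
                                   np.random.default_rng(8),
                                   n_trials=n_trials)

        def oracle_critic(v, y):
            v = np.atleast_2d(v)
            out = np.empty(v.shape[0])
            for i in range(v.shape[0]):
                a = np.rint(y[i, 0, :n_trials]).astype(int)
                r = np.rint(y[i, 0, n_trials:]).astype(int)
                j = exact.outcome_index(
                    ExperimentData((BehaviorBlock(a, r),)))
                m = int(np.argmax(v[i]))
                post = mp[j, m]
                out[i] = (1.0 + np.log(post / prior.model_prior[m])
                          if post > 0 else -50.0)
            return out

        sub = ts.subset(np.arange(20000))
        obj = nwj_objective(oracle_critic, (sub.v_enc, sub.y),
                            (np.roll(sub.v_enc, 1, axis=0), sub.y))
        # Monte-Carlo error of the sample average at n=20,000
        assert abs(obj - exact.mi) < 0.02


class TestTraining:
    def test_heldout_estimate_on_toy_within_band(self, toy_critic):
        critic, held, exact = toy_critic
        est = estimate_mi(critic, held)
        assert 0.15 <= est.value <= 0.23
        assert est.value <= exact.mi + 3 * est.se
        assert est.value >= exact.mi - 0.07

    def test_independent_v_y_estimate_near_zero(self, independent_critic):
        critic, held = independent_critic
        est = estimate_mi(critic, held)
        assert -0.02 <= est.value <= 0.05

    def test_training_objective_improves_with_more_epochs(self):
        design, prior, n_trials = certain_reward_toy()
        gaps = []
        for seed in range(3):
            ts = generate_training_set(design, "MD", prior, 8000,
                                       np.random.default_rng(100 + seed),
                                       n_trials=n_trials)
            short = train_critic(dataclasses.replace(
                TOY_CONFIG, epochs=10, seed=seed), ts).history[-1]
            long = train_critic(dataclasses.replace(
                TOY_CONFIG, epochs=20, seed=seed), ts).history[-1]
            gaps.append(long - short)
        assert np.mean(gaps) > -0.02

    def test_mismatched_block_length_rejected(self, toy_critic):
        critic, _, _ = toy_critic
        bad = np.zeros((5, 1, 10))
        with pytest.raises(ValueError, match="expected y of shape"):
            critic.network.summaries(bad)

    def test_history_recorded_per_epoch(self, toy_critic):
        critic, _, _ = toy_critic
        assert len(critic.history) == critic.config.epochs


class TestEstimateMI:
    def test_evaluation_is_deterministic(self, toy_critic):
        critic, held, _ = toy_critic
        a = estimate_mi(critic, held)
        b = estimate_mi(critic, held)
        assert a.value == b.value and a.se == b.se

    def test_small_heldout_records_warning(self, toy_critic):
        critic, held, _ = toy_critic
        tiny = held.subset(np.arange(50))
        est = estimate_mi(critic, tiny)
        assert any("50" in w for w in est.warnings)


class TestAmortizedPosterior:
    def _constant_one_critic(self, certain_toy):
        design, prior, n_trials, _ = certain_toy
        ts = generate_training_set(design, "MD", prior, 10,
                                   np.random.default_rng(0),
                                   n_trials=n_trials)
        trained = train_critic(dataclasses.replace(TOY_CONFIG, epochs=1), ts)
        # zero every weight, set the output bias to 1: T(v, y) = 1 everywhere
        net = trained.network
        for mlp in [*net.subnets, net.joint]:
            for i in range(len(mlp.W)):
                mlp.W[i][:] = 0.0
                mlp.b[i][:] = 0.0
        net.joint.b[-1][:] = 1.0
        return trained, prior

    def test_constant_critic_returns_prior(self, certain_toy):
        trained, prior = self._constant_one_critic(certain_toy)
        ens = CriticEnsemble([trained], prior)
        y = np.zeros((4, 1, trained.network.block_len))
        posts = amortized_model_posteriors(ens, y, prior)
        assert np.allclose(posts, prior.model_prior, atol=1e-12)

    def test_optimal_critic_reproduces_exact_posterior(self, stochastic_toy):
        """Plugging T* into the posterior formula is an algebraic identity."""
        *_, exact = stochastic_toy
        t_star = exact.optimal_critic_values()  # (V, M)
        w = exact.weights
        un = w[:, None] * np.where(np.isfinite(t_star),
                                   np.exp(t_star - 1.0), 0.0)
        recon = (un / un.sum(axis=0, keepdims=True)).T
        assert np.allclose(recon, exact.posteriors, atol=1e-9)

    def test_ensemble_posteriors_are_simplices(self, stochastic_toy_ensemble,
                                               stochastic_toy):
        design, prior, n_trials, exact = stochastic_toy
        from banditboed.critic import encode_experiments
        rng = np.random.default_rng(3)
        idx = rng.integers(0, exact.actions.shape[0], 1000)
        y = encode_experiments(exact.actions[idx], exact.rewards[idx], 2)
        posts = amortized_model_posteriors(stochastic_toy_ensemble, y, prior)
        assert np.allclose(posts.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(posts >= 0)

    def test_ensemble_matches_enumeration_posterior(self,
                                                    stochastic_toy_ensemble,
                                                    stochastic_toy):
        design, prior, n_trials, exact = stochastic_toy
        from banditboed.critic import encode_experiments
        y = encode_experiments(exact.actions, exact.rewards, 2)
        amort = amortized_model_posteriors(stochastic_toy_ensemble, y, prior)
        tv = 0.5 * np.abs(amort - exact.model_posteriors()).sum(axis=1)
        assert tv.mean() < 0.05

    def test_member_spread_shrinks_with_training_size(self, stochastic_toy):
        design, prior, n_trials, exact = stochastic_toy
        from banditboed.critic import encode_experiments, train_ensemble
        y = encode_experiments(exact.actions, exact.rewards, 2)
        spreads = {}
        for n in (2000, 20000):
            ens = train_ensemble(design, "MD", prior,
                                 np.random.default_rng(5),
                                 dataclasses.replace(TOY_CONFIG, epochs=20),
                                 n_members=4, n_train=n, n_trials=n_trials)
            member_posts = np.stack([
                amortized_model_posteriors(CriticEnsemble([m], prior), y,
                                           prior)
                for m in ens.members])
            spreads[n] = member_posts.std(axis=0).mean()
        assert spreads[20000] < spreads[2000]

    def test_posterior_object_for_single_experiment(self,
                                                    stochastic_toy_ensemble,
                                                    stochastic_toy):
        *_, exact = stochastic_toy
        data = ExperimentData((BehaviorBlock(exact.actions[7, 0],
                                             exact.rewards[7, 0]),))
        post = amortized_posterior(stochastic_toy_ensemble, data)
        assert isinstance(post, Posterior)
        assert post.probs.shape == (3,)


class TestSummaries:
    def test_identical_blocks_identical_summaries(self, toy_critic):
        critic, held, _ = toy_critic
        blk = BehaviorBlock(held.actions[0, 0], held.rewards[0, 0])
        s1 = extract_summaries(critic, blk)
        s2 = extract_summaries(critic, blk)
        assert np.array_equal(s1, s2)
        assert s1.shape == (critic.config.summary_dim,)

    def test_summaries_approximately_sufficient_for_discrimination(
            self, toy_critic, certain_toy):
        """A classifier on learned summaries nearly matches one on raw data."""
        critic, _, _ = toy_critic
        design, prior, n_trials, _ = certain_toy
        ts = generate_training_set(design, "MD", prior, 10000,
                                   np.random.default_rng(17),
                                   n_trials=n_trials)
        labels = ts.v_raw.astype(int)
        raw = ts.y.reshape(ts.n, -1)
        summ = critic.network.summaries(ts.y)
        accs = {}
        for name, X in (("raw", raw), ("summary", summ)):
            clf = LogisticRegression(max_iter=1000)
            clf.fit(X[:7000], labels[:7000])
            accs[name] = clf.score(X[7000:], labels[7000:])
        assert accs["summary"] > accs["raw"] - 0.05


class TestPermutationMarginals:
    def test_shuffled_v_preserves_marginals(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=(500, 3))
        rolled = np.roll(v[rng.permutation(500)], 1, axis=0)
        assert np.allclose(np.sort(rolled, axis=0), np.sort(v, axis=0))


class TestSerialization:
    def test_save_load_roundtrip(self, toy_critic, tmp_path):
        critic, held, _ = toy_critic
        d = str(tmp_path / "critic")
        save_critic(critic, d)
        loaded = load_critic(d)
        before = critic(held.v_enc[:20], held.y[:20])
        after = loaded(held.v_enc[:20], held.y[:20])
        assert np.allclose(before, after, atol=1e-12)
        assert (tmp_path / "critic" / "history.csv").exists()
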