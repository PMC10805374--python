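import dataclasses

import numpy as np
import pytest

from banditboed import oracle
from banditboed.critic import CriticConfig, generate_training_set, train_critic, train_ensemble
from banditboed.toys import certain_reward_toy, discrimination_toy

# small architecture for the 2-arm toys: the block inputs are only 4-6 wide
TOY_CONFIG = CriticConfig(block_widths=(32, 16), summary_dim=4,
                          joint_widths=(64, 32), epochs=30, batch_size=256,
                          seed=11)


@pytest.fixture(scope="session")
def certain_toy():
    """2-arm, 2-trial, certain-reward toy with its exact enumeration result."""
    design, prior, n_trials = certain_reward_toy()
    exact = oracle.exact_mi(design, "MD", prior, n_trials=n_trials)
    return design, prior, n_trials, exact


@pytest.fixture(scope="session")
def stochastic_toy():
    """2-arm, 3-trial toy with stochastic rewards: 64 outcome sequences."""
    design, prior, n_trials = discrimination_toy()
    exact = oracle.exact_mi(design, "MD", prior, n_trials=n_trials)
    return design, prior, n_trials, exact


@pytest.fixture(scope="session")
def toy_critic(certain_toy):
    """A critic trained on the certain-reward toy, with its held-out set."""
    design, prior, n_trials, exact = certain_toy
    ts = generate_training_set(design, "MD", prior, 50000,
                               np.random.default_rng(5), n_trials=n_trials)
    train, held = ts.split(0.2)
    critic = train_critic(TOY_CONFIG, train)
    return critic, held, exact


@pytest.fixture(scope="session")
def independent_critic(certain_toy):
    """A critic trained on records whose v was shuffled (v independent of y)."""
    design, prior, n_trials, _ = certain_toy
    ts = generate_training_set(design, "MD", prior, 50000,
                               np.random.default_rng(6), n_trials=n_trials)
    perm = np.random.default_rng(7).permutation(ts.n)
    ts = dataclasses.replace(ts, v_raw=ts.v_raw[perm], v_enc=ts.v_enc[perm])
    train, held = ts.split(0.2)
    critic = train_critic(dataclasses.replace(TOY_CONFIG, seed=13), train)
    return critic, held


@pytest.fixture(scope="session")
def stochastic_toy_ensemble(stochastic_toy):
    """Ensemble of 10 critics on the stochastic toy (for posterior fidelity)."""
    design, prior, n_trials, _ = stochastic_toy
    return train_ensemble(design, "MD", prior, np.random.default_rng(21),
                          dataclasses.replace(TOY_CONFIG, seed=0),
                          n_members=10, n_train=20000, n_trials=n_trials)
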