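"""Train a neural MI critic and estimate the utility of one design.

Simulates labeled (model, behavior) pairs at a fixed design, trains the
per-block summary critic by maximizing the variational lower bound on mutual
information, and evaluates the bound on held-out simulations. The held-out
value estimates the expected information gain (in nats) that an experiment
run at this design would provide about which model generated the behavior —
here on a toy problem small enough that the exact value is also computable,
so the printed numbers can be compared directly.
"""

import numpy as np

from banditboed import CriticConfig, estimate_mi, exact_mi, generate_training_set, train_critic
from banditboed.toys import certain_reward_toy

design, prior, n_trials = certain_reward_toy()
exact = exact_mi(design, "MD", prior, n_trials=n_trials)

config = CriticConfig(block_widths=(32, 16), summary_dim=4,
                      joint_widths=(64, 32), epochs=30, seed=0)
training_set = generate_training_set(design, "MD", prior, 50000,
                                     np.random.default_rng(1),
                                     n_trials=n_trials)
train, held = training_set.split(config.heldout_fraction)
critic = train_critic(config, train)
estimate = estimate_mi(critic, held)

print(f"exact MI (enumeration)   : {exact.mi:.4f} nats")
print(f"held-out NWJ lower bound : {estimate.value:.4f} "
      f"+- {estimate.se:.4f} nats (n = {estimate.n})")
print(f"final training objective : {critic.history[-1]:.4f} nats")
print("\nThe held-out estimate sits at or just below the exact value: the")
print("bound can only underestimate, and its gap measures critic quality.")
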