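"""Simulate bandit behavior from the three models and write it to CSV.

Builds a two-block, three-armed design, draws one parameter vector per model
from the uninformative priors, simulates 30-trial blocks, and prints the
choice sequences. The printed rows show which arm each simulated learner
chose per trial and whether it was rewarded; the CSV is the flat table the
rest of the workflow consumes.
"""

import numpy as np

from banditboed import Design, Model, default_prior, sample_params, simulate_experiment
from banditboed.io import experiments_to_table, write_behavior_csv

rng = np.random.default_rng(0)
design = Design(np.array([[0.0, 0.0, 0.6],
                          [1.0, 1.0, 0.0]]))
prior = default_prior()

experiments = []
for model in Model:
    params = sample_params(model, prior, rng)
    exp = simulate_experiment(model, params, design, rng, n_trials=30)
    experiments.append(exp)
    print(f"{model.name}: params = {params}")
    for b, blk in enumerate(exp.blocks):
        print(f"  block {b} actions: {''.join(map(str, blk.actions))}")
        print(f"  block {b} rewards: {''.join(map(str, blk.rewards))}")

table = experiments_to_table(experiments)
write_behavior_csv(table, "simulated_behavior.csv")
print(f"\nwrote {len(table)} rows to simulated_behavior.csv "
      "(participant, block, trial, action, reward)")
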