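"""Simulate one RLWM agent and summarize its learning curves.

Builds the default task (blocks of 2-5 stimuli, nine iterations each, three
response buttons), simulates an agent from the RL+WM mixture model, and
prints accuracy by set size and iteration.  Smaller set sizes should show
steeper early learning: working memory carries more of the load when there
is less to hold.
"""

import numpy as np

from rlwm import ModelParams, TaskConfig, generate_task, simulate_subject
from rlwm.analysis import summarize_learning_curves

rng = np.random.default_rng(0)
params = ModelParams(alpha_rl=0.03, gamma=0.5, phi=0.1, rho=0.9, wm_cap=3, nu=0.05)

design = generate_task(TaskConfig(), rng)
training, _ = simulate_subject(design, params, rng)
training["subject_id"] = 0

curves = summarize_learning_curves(training, by="iteration")
table = curves.pivot(index="previous_iterations", columns="set_size", values="accuracy")
print("Accuracy by iteration (rows) and set size (columns):")
print(table.round(2).to_string())
print(
    f"\nOverall accuracy {training.correct.mean():.3f} over "
    f"{len(training)} trials; iteration 1 is at chance (1/3), later "
    "iterations climb faster in smaller blocks."
)
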