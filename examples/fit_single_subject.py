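"""MAP-fit one simulated subject and compare estimates with the truth.

Simulates a session from known parameters, then runs the full estimator:
grid search over the integer WM capacity 2-5, multi-start L-BFGS-B over the
five continuous parameters, slightly informative Beta(1.05, 1.05) priors on
phi, gamma and nu.  Single-session estimates are noisy (especially phi); see
docs/methods.md for the measured recovery precision.
"""

import numpy as np

from rlwm import (
    FitConfig,
    ModelParams,
    TaskConfig,
    build_test_pairs,
    fit_subject,
    generate_task,
    simulate_subject,
)

rng = np.random.default_rng(1)
true = ModelParams(alpha_rl=0.02, gamma=0.4, phi=0.15, rho=0.9, wm_cap=3, nu=0.06)

design = generate_task(TaskConfig(), rng)
design.test_pairs = build_test_pairs(design, 4, rng)
training, test = simulate_subject(design, true, rng)

fit = fit_subject(training, test, FitConfig(), np.random.default_rng(2))

print(f"{'parameter':>9s} {'true':>7s} {'MAP':>7s}")
for name, t in true.as_dict().items():
    print(f"{name:>9s} {t:7.3f} {getattr(fit.params, name):7.3f}")
print(f"\nlog-posterior {fit.log_posterior:.2f}, converged={fit.converged}")
print("capacity profile (best log-posterior per WM capacity):")
for cap, lp in fit.capacity_profile.items():
    marker = " <- selected" if cap == fit.params.wm_cap else ""
    print(f"  wm_cap={cap}: {lp:.2f}{marker}")
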