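"""NDJ test cross: simulate a control and a knockdown arm, estimate %NDJ.

Simulates oocytes in the sensitized (backup-disabled) background, crosses
them to attached-X^Y Bar males, tallies viable progeny and applies the
doubled-E correction.  The knockdown arm has elevated arm-cohesion loss,
so its %NDJ should sit far above the control's, and the two-group test
should call the difference at any reasonable alpha.
"""

import numpy as np

from flyndj import compare_ndj, estimate_ndj, ndj_experiment_config, simulate_ndj_counts

rng = np.random.default_rng(42)

arms = {
    "control (no driver)": ndj_experiment_config(p_arm_loss=0.04),
    "mata KD": ndj_experiment_config(p_arm_loss=0.5),
}

counts = {}
for label, cfg in arms.items():
    counts[label] = simulate_ndj_counts(cfg, n_progeny=2000, rng=rng)
    est = estimate_ndj(counts[label])
    print(
        f"{label:20s} N={est.n_normal:5d}  E={est.E:4d}  "
        f"%NDJ={est.pct_ndj:6.2f}  [95% CI {est.ci_low:.2f}-{est.ci_high:.2f}]"
    )

res = compare_ndj(counts["mata KD"], counts["control (no driver)"], seed=1)
print(
    f"\nKD vs control: p_monte_carlo={res.p_monte_carlo:.2e} "
    f"(z-path p={res.p_normal_approx:.2e})"
)
print(
    "\nE is doubled because metafemale and nullo-X zygotes die: %NDJ\n"
    "estimates the gamete-level error rate, not the viable-progeny rate."
)
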