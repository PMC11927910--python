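"""Metric sensitivity to estimation error of controlled magnitude psi.

True probabilities are Uniform rescaled to (0.2, 0.8); estimates are
p +/- psi.  The IMV and R2 of the estimate (vs the base rate) collapse and
turn negative as psi grows, while AUC and F1 barely move.
"""

import numpy as np

from imv import break_even_psi, first_negative_crossing, run_psi_sweep

sweep = run_psi_sweep(n_samples=600, n=1000, seed=6)

bins = np.digitize(sweep.psi, np.linspace(0, 0.2, 5))
summary = sweep.groupby(bins)[["psi", "omega_p1", "r2_p1", "auc_p1", "f1_p1"]].mean()
print(summary.round(3).to_string(index=False))
print(f"omega zero crossing near psi = "
      f"{first_negative_crossing(sweep.psi, sweep.omega_p1, window=101):.3f}")
print(f"analytic squared-error break-even: psi = {break_even_psi():.3f}")
print(
    "Meaning: past the break-even the noisy estimate is worth less than the "
    "base rate — IMV and R2 say so; AUC/F1 hardly notice."
)
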