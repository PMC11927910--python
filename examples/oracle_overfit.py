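"""Oracle and Overfit IMV diagnostics across sample sizes.

Both compare the true generating probabilities with the fitted ones:
the Overfit IMV on the training outcomes (negative = the fit captured
noise), the Oracle IMV on fresh outcomes (positive = estimates still fall
short of the truth).  omega0 is the standalone value of the fitted model
over the prevalence.
"""

from imv import run_oracle_overfit_cells

cells = run_oracle_overfit_cells([0.5], [50, 500, 5000], n_reps=200, seed=4)
means = cells.groupby("n")[["omega0", "oracle", "overfit"]].mean()
print(means.round(4))
print(
    "Meaning: with more data the fit approaches the truth, so both "
    "diagnostics shrink toward zero while the model's own value (omega0) grows."
)
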