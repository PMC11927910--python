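"""IMV versus AIC/BIC under three model misspecifications.

Outcomes follow a logistic model in x with slope 0.5.  Alternatives: a
quadratic overfit, a fit on a noisy copy of x, and a complementary log-log
link.  The IMV prices the out-of-sample cost of each error; the
information criteria instead scale with sample size.
"""

import numpy as np

from imv import MisspecSimConfig, run_misspecification_study

tab = run_misspecification_study(MisspecSimConfig(seed=9), n_draws=120)
tab["n_band"] = np.where(tab.n < 1000, "N<1000", "N>=1000")
out = tab.groupby(["alternative", "n_band"])[
    ["omega", "delta_aic", "delta_bic", "rmse_alt"]
].mean()
print(out.round(4))
print(
    "Meaning: the quadratic overfit stops costing anything at large N (IMV "
    "-> 0, like the RMSE) while its BIC penalty keeps growing; the noisy "
    "covariate costs the same at any N; the wrong link is consistently cheap."
)
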