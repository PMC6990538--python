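"""Compare APC sub-models by DIC.

Fits the age-only (A), age-period (AP) and full age-period-cohort (APC)
models to the same synthetic stratum table — generated with real period
structure — and tabulates deviance, effective parameters and DIC.
Smaller DIC indicates better expected out-of-sample fit; with genuine
period signal the A-only model should lose clearly.
"""

import numpy as np

from apctrend import FitConfig, compare_models
from apctrend import validation as V

design = V.small_design()
table = V.simulate_cell_means(V.small_truth(), design, n_per_cell=200,
                              rng=np.random.default_rng(7))

cmp = compare_models(table, design, models=("A", "AP", "APC"),
                     config=FitConfig(chains=2, iterations=800, seed=5))
print(cmp.round(2).to_string(index=False))
best = cmp.loc[cmp["best"], "model"].iloc[0]
print(f"\nbest model by DIC: {best} — the age-only model loses decisively; "
      "the cohort signal in this truth is weak, so AP and APC are close and "
      "parsimony can tip the balance between them")
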