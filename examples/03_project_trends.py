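"""Project the fitted trend 10 years ahead under the RW2 predictive.

Each posterior draw's period and cohort effects are continued forward by
the second-order random walk theta[t] = 2 theta[t-1] - theta[t-2] +
Normal(0, tau^2) using that draw's own innovation SD, so the projection
bands widen with the horizon.  The yearly series averages the projected
cell means over ages.
"""

import numpy as np

from apctrend import FitConfig, extend_effects, fit_apc, trend_series
from apctrend import validation as V

design = V.small_design()
table = V.simulate_cell_means(V.small_truth(), design, n_per_cell=200,
                              rng=np.random.default_rng(0))
draws = fit_apc(table, design, FitConfig(chains=3, iterations=800, seed=0))

ext = extend_effects(draws, horizon=10, seed=1)
series = trend_series(ext, table, observed="fitted")
print(series.round(2).to_string(index=False))
proj = series[series.kind == "projected"]
print(f"\nCrI width grows from {proj.iloc[0].upper - proj.iloc[0].lower:.1f} "
      f"to {proj.iloc[-1].upper - proj.iloc[-1].lower:.1f} outcome units "
      f"across the 10-year horizon (forecast uncertainty accumulates).")
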