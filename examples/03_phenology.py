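"""From a noisy score series to heading date and rate of heading.

Fits the fixed-asymptote logistic y = 100 / (1 + exp(-(phi2 + phi3 day)))
to one plot's time series (after adding the 0%/100% anchor points) and reads
off the 50% intersect (heading date) and the slope (rate).  Then compares two
whole-trial measurement methods plot by plot.
"""

import numpy as np
import pandas as pd

from wheatpheno import phenology, simulate as sim

truth = {"plot": "17ASH_demo", "phi2": -0.55 * 126.4, "phi3": 0.55}
days = np.arange(112.0, 146.0, 3.0)
series = sim.sample_visual_scores(truth, days, seed=3)
series = phenology.augment_anchors(series)

fit = phenology.fit_logistic(series)
hd = phenology.heading_date(fit, (series.days.min(), series.days.max()), step=0.1)
print(f"phi2 = {fit.phi2:.2f}, phi3 = {fit.phi3:.3f}/day (converged: {fit.converged})")
print(f"heading date = {hd:.1f} (true 126.4); rate of heading = {phenology.heading_rate(fit):.3f}/day")

# Agreement between two measurement routes over 150 plots (e.g. visual scores
# vs classifier predictions): MAE/RMSE in days, fraction within 1 and 2 days,
# regression slope as a bias check.
rng = np.random.default_rng(7)
visual = pd.Series(rng.uniform(120, 132, 150), index=[f"P{i}" for i in range(150)])
cnn = visual + rng.normal(0.0, 1.25, 150)
stats = phenology.series_agreement(visual, cnn)
print(f"agreement over {stats.n} plots: MAE {stats.mae:.2f} d, RMSE {stats.rmse:.2f} d, "
      f"within 1 d {stats.frac_within_1:.0%}, within 2 d {stats.frac_within_2:.0%}, "
      f"slope {stats.slope:.2f}")
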