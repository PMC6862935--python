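"""Variance components, broad-sense heritability, and entry BLUPs.

Simulates a 2-rep trial, estimates the mixed model y = mu + entry + e by
REML (iid residual here; pass spatial="ar1" for the row-column autoregressive
residual) and evaluates H2 = s2_G / (s2_G + s2_e / r) on a line-mean basis.
"""

import numpy as np

from wheatpheno import quantgen, simulate as sim
from wheatpheno.core import VarianceComponents

gmap = sim.make_genetic_map(5, 40, 150)
G = sim.simulate_ril_population(gmap, 300, 5, seed=4)
heading = sim.genetic_values(G, sim.default_heading_architecture(gmap), seed=4)

vc_sim = VarianceComponents(var_g=float(np.var(heading, ddof=1)), var_e=0.3, n_reps=2)
truth = sim.simulate_trial(heading, np.full(300, 0.55), G.line_ids, 2, 1, 40, 16,
                           vc_sim, seed=5)
plots = truth.rename(columns={"heading_date": "value"})[
    ["entry", "year", "rep", "row", "col", "value"]
]

vc = quantgen.fit_variance_components(plots, spatial="iid")
h2 = quantgen.heritability(vc, "single_year")
print(f"REML: var_G = {vc.var_g:.2f}, var_e = {vc.var_e:.2f} (simulated {vc_sim.var_g:.2f}, 0.30)")
print(f"broad-sense H2 (single year, r = {vc.n_reps}) = {h2:.3f}")

blups = quantgen.entry_values(plots, mode="BLUP", vc=vc)
blues = quantgen.entry_values(plots, mode="BLUE", vc=vc)
spread = lambda s: s.max() - s.min()
print(f"entry BLUPs: {len(blups)} entries, range {spread(blups):.1f} d "
      f"(BLUE range {spread(blues):.1f} d -- BLUPs shrink toward the mean)")
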