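"""Simulate a biparental RIL field trial end to end.

Builds a genetic map, an F5 RIL population, a 3-locus epistatic heading-date
architecture with a polygenic rate trait, and a replicated trial with
spatially correlated plot noise, then samples noisy 10%-increment visual
scores the way a breeder would record them.
"""

import numpy as np

from wheatpheno import simulate as sim
from wheatpheno.core import VarianceComponents

gmap = sim.make_genetic_map(n_chrom=5, markers_per_chrom=40, chrom_length_cm=150)
G = sim.simulate_ril_population(gmap, n_lines=300, n_selfing_generations=5, seed=1)
print(f"population: {G.n_lines} lines x {G.n_markers} markers, "
      f"residual heterozygosity {np.mean(G.dose == 1):.3f} (expected {0.5**5:.3f})")

arch = sim.default_heading_architecture(gmap)
heading = sim.genetic_values(G, arch, seed=1)
rate = sim.genetic_values(G, sim.default_rate_architecture(gmap), seed=8)
print(f"heading date genetic values: mean {heading.mean():.1f} DOY, "
      f"sd {heading.std(ddof=1):.2f} days; rate mean {rate.mean():.2f}/day")

vc = VarianceComponents(var_g=float(np.var(heading, ddof=1)), var_e=0.3,
                        rho_row=0.4, rho_col=0.4, n_reps=2)
truth = sim.simulate_trial(heading, rate, G.line_ids, n_reps=2, n_years=1,
                           n_rows=40, n_cols=16, vc=vc, seed=1, rate_noise_sd=0.08)
print(f"trial: {len(truth)} plots on a 40 x 16 grid, 2 reps")

days = np.arange(112.0, 146.0, 3.0)  # scoring every 3 days through heading
series = sim.sample_visual_scores(truth.iloc[0], days, seed=42)
print(f"plot {series.plot}: true heading {truth.iloc[0]['heading_date']:.1f}, scores:")
print("  day    :", " ".join(f"{d:5.0f}" for d in series.days))
print("  percent:", " ".join(f"{p:5.0f}" for p in series.percents))
# The score track rises 0 -> 100 around the true heading date; occasional
# one- or two-class jumps are the simulated breeder mislabels.
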