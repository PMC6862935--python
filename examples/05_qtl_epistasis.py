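"""Genome scan, epistasis, and the segregation-ratio test.

Filters markers (MAF >= 0.1, missing <= 30%, het <= 6%), runs the
single-marker regression scan with Bonferroni control, tests all pairs of
significant markers for two-way epistasis, and checks the early/late split
against the 3:1 two-gene dominant-epistasis expectation.
"""

import numpy as np

from wheatpheno import genescan, simulate as sim

gmap = sim.make_genetic_map(5, 40, 150)
G = sim.simulate_ril_population(gmap, 300, 5, seed=6)
arch = sim.default_heading_architecture(gmap)
rng = np.random.default_rng(6)
y = sim.genetic_values(G, arch, seed=6) + rng.normal(0, 0.47, 300)  # line means, H2 ~ 0.98

Gf, report = genescan.filter_markers(G)
print(f"marker filter: {report}")

scan = genescan.marker_scan(y, Gf, alpha=0.05)
sig = scan[scan["significant"]]
print(f"scan: {len(sig)} markers above Bonferroni (p < {scan.attrs['threshold']:.2e}), "
      f"top hits per chromosome:")
print(sig.sort_values("p").groupby("chrom").head(1)[["marker", "effect", "neglog10p"]]
      .to_string(index=False))

epi = genescan.epistasis_scan(y, Gf, list(np.flatnonzero(scan["significant"])), alpha=0.05)
top = epi.sort_values("lod", ascending=False).iloc[0]
print(f"epistasis: {int(epi['significant'].sum())}/{epi.attrs['n_pairs']} pairs significant; "
      f"strongest {top['marker_j']} x {top['marker_k']}: LOD {top['lod']:.1f}, "
      f"interaction {top['epsilon']:.2f} d")

# Bimodal heading-date split: delimit early vs late and test 3:1
split = np.median(y) + 1.0
n_early, n_late = int((y < split).sum()), int((y >= split).sum())
chi2, p = genescan.segregation_test(n_early, n_late)
print(f"segregation {n_early} early : {n_late} late vs 3:1 -> chi2 = {chi2:.2f}, p = {p:.3f}")
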