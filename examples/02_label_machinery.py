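"""Label handling around the image classifier.

Shows label imputation between scoring dates, the partial-credit soft-label
target, its error function, and the two consensus stages (patch -> image,
image -> plot).
"""

import numpy as np

from wheatpheno import labels
from wheatpheno.core import ScorePoint

# A plot was scored 20% on day 120 and 40% on day 124; images taken on day
# 121 inherit a weighted label between the two.
pct = labels.impute_percent_label(ScorePoint(120, 20), ScorePoint(124, 40), day=121)
print(f"imputed label for day 121: {pct:.1f}% (weighted toward the nearer score)")

# Soft-label target for a 50% annotation: 0.7 on the annotated class, partial
# credit 0.1 / 0.05 one and two classes away.
target = labels.build_soft_label(5)
print("soft label for the 50% class:", np.round(target, 3))

point = np.zeros(11)
point[5] = 1.0
print(f"error of an overconfident exact prediction: {labels.soft_label_error(point, target):.4f}")
print(f"error of the target against itself:         {labels.soft_label_error(target, target):.4f}")

# Image-level consensus: 9 patch distributions summed, argmax wins.
grid = labels.grid_patches(672, 672, 3, 3, 224)
rng = np.random.default_rng(0)
patches = [np.roll(target, rng.integers(-1, 2)) for _ in range(grid.n_patches)]
print(f"{grid.n_patches} patches -> image consensus class {labels.consensus_image(patches)} "
      f"({labels.consensus_image(patches) * 10}%)")

# Plot-level consensus: majority vote across that plot's images.
image_calls = [5, 5, 4, 5, 6, 5, 5, 5, 4, 5, 5, 5]
print(f"{len(image_calls)} image calls -> plot consensus {labels.consensus_plot(image_calls) * 10}%")
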