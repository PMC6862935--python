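"""Label machinery around the percent-heading classifier.

Covers the bookkeeping that turns sparse breeder scores into trainable image
labels and classifier outputs back into plot phenotypes: imputation of
percent-heading labels between scoring dates, the patch-grid geometry used to
tile high-resolution plot images, the partial-credit soft-label target
distribution, its mean-absolute-difference error function, and consensus
voting at the image (summed probabilities) and plot (majority vote) levels.

No pixels are touched here: patches are geometry records and the classifier
is an injected function, so the machinery is testable with a stub.
"""

from __future__ import annotations

from collections import Counter
from typing import Callable, Hashable, Iterable, Sequence

import numpy as np
import pandas as pd

from .core import CLASS_PERCENTS, N_CLASSES, PatchGrid, ScorePoint

#: partial-credit masses: annotated class, one-class (10%) and two-class (20%) discrepancy
SOFT_LABEL_MASSES = (0.7, 0.1, 0.05)


def impute_percent_label(prev: ScorePoint, next: ScorePoint, day: float) -> float:
    """Percent-heading label for an imaging day between two visual scoring days.

    Weighted average of the flanking scores with weights proportional to the
    distance from the *other* score (i.e. linear interpolation in time), so
    each endpoint is recovered exactly.
    """
    prev, next = ScorePoint(*prev), ScorePoint(*next)
    if prev.day >= next.day:
        raise ValueError(f"scoring days must be increasing, got {prev.day} >= {next.day}")
    if not prev.day <= day <= next.day:
        raise ValueError(f"day {day} outside scoring interval [{prev.day}, {next.day}]")
    span = next.day - prev.day
    return prev.percent * (next.day - day) / span + next.percent * (day - prev.day) / span


def impute_labels_table(scores: pd.DataFrame, target_days: Sequence[float]) -> pd.DataFrame:
    """Imputed (plot, day, percent) labels for each target day bracketed by scores.

    ``scores`` needs columns plot, day, percent.  Days matching a scoring day
    take that score directly; days outside a plot's scored range are skipped.
    """
    out = []
    for plot, grp in scores.groupby("plot", sort=False):
        grp = grp.sort_values("day")
        days = grp["day"].to_numpy(dtype=float)
        pcts = grp["percent"].to_numpy(dtype=float)
        for day in target_days:
            if day < days[0] or day > days[-1]:
                continue
            j = int(np.searchsorted(days, day, side="right"))
            if day in days:
                pct = float(pcts[np.searchsorted(days, day)])
            else:
                pct = impute_percent_label(
                    ScorePoint(days[j - 1], pcts[j - 1]), ScorePoint(days[j], pcts[j]), day
                )
            out.append({"plot": plot, "day": float(day), "percent": pct})
    return pd.DataFrame(out, columns=["plot", "day", "percent"])


def grid_patches(image_w: int, image_h: int, grid_rows: int, grid_cols: int, patch: int) -> PatchGrid:
    """Top-left-anchored tiling of an image into grid_rows x grid_cols patches."""
    if min(image_w, image_h, grid_rows, grid_cols, patch) < 1:
        raise ValueError("all patch-grid dimensions must be >= 1")
    if grid_cols * patch > image_w or grid_rows * patch > image_h:
        raise ValueError(
            f"grid {grid_rows}x{grid_cols} of {patch}px patches exceeds image {image_w}x{image_h}"
        )
    offsets = tuple((r * patch, c * patch) for r in range(grid_rows) for c in range(grid_cols))
    return PatchGrid(image_w, image_h, grid_rows, grid_cols, patch, offsets)


def build_soft_label(class_index: int, n_classes: int = N_CLASSES) -> np.ndarray:
    """Partial-credit target distribution for an annotated percent-heading class.

    Mass 0.7 on the annotated class, 0.1 on each class one step away and 0.05
    two steps away; mass that would fall outside the class range is folded
    back onto the annotated class so the vector sums to exactly 1.
    """
    if not 0 <= class_index < n_classes:
        raise ValueError(f"class index {class_index} out of range for {n_classes} classes")
    p = np.zeros(n_classes)
    p[class_index] = SOFT_LABEL_MASSES[0]
    for step, mass in ((1, SOFT_LABEL_MASSES[1]), (2, SOFT_LABEL_MASSES[2])):
        for c in (class_index - step, class_index + step):
            if 0 <= c < n_classes:
                p[c] += mass
            else:
                p[class_index] += mass
    return p


def validate_soft_label(p: np.ndarray, atol: float = 1e-9) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("soft label must be a 1-D probability vector")
    if np.any(p < -atol) or abs(p.sum() - 1.0) > max(atol, 1e-6):
        raise ValueError("soft label entries must be non-negative and sum to 1")
    return p


def soft_label_error(pred: np.ndarray, target: np.ndarray) -> float:
    """Mean over classes of the absolute probability mismatch (the training
    error function): zero iff the distributions are identical."""
    pred, target = validate_soft_label(pred), validate_soft_label(target)
    if pred.shape != target.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {target.shape}")
    return float(np.mean(np.abs(pred - target)))


def consensus_image(patch_predictions: Iterable[np.ndarray]) -> int:
    """Whole-image class from its patch predictions: argmax of the element-wise
    sum of patch distributions, ties broken toward the lower class."""
    preds = [np.asarray(p, dtype=float) for p in patch_predictions]
    if not preds:
        raise ValueError("need at least one patch prediction")
    total = np.sum(preds, axis=0)
    return int(np.argmax(total))


def consensus_plot(image_labels: Sequence[Hashable]) -> Hashable:
    """Plot-level label: majority vote over image labels, ties to the lower
    (sort-first) label."""
    labels = list(image_labels)
    if not labels:
        raise ValueError("need at least one image label")
    counts = Counter(labels)
    best = max(counts.values())
    return min(lab for lab, n in counts.items() if n == best)


def classify_prediction_table(
    predictions: pd.DataFrame, mode: str = "vote"
) -> pd.DataFrame:
    """Plot-by-day consensus from an image-level prediction table.

    ``predictions`` holds one row per image with columns plot, day and p0..p100
    (11 class-probability columns).  Each image is first reduced to a class by
    argmax; per (plot, day) the consensus is either a majority vote over image
    classes (``mode="vote"``, default) or the class nearest the mean of the
    image class percentages (``mode="average"``).
    """
    pcols = [f"p{c}" for c in CLASS_PERCENTS]
    probs = predictions[pcols].to_numpy(dtype=float)
    img_class = probs.argmax(axis=1)
    df = predictions[["plot", "day"]].copy()
    df["image_class"] = img_class
    rows = []
    for (plot, day), grp in df.groupby(["plot", "day"], sort=False):
        if mode == "vote":
            cls = consensus_plot(list(grp["image_class"]))
        elif mode == "average":
            cls = int(np.clip(np.round(grp["image_class"].mean()), 0, N_CLASSES - 1))
        else:
            raise ValueError(f"unknown consensus mode {mode!r}")
        rows.append({"plot": plot, "day": float(day), "percent": float(CLASS_PERCENTS[cls])})
    return pd.DataFrame(rows, columns=["plot", "day", "percent"])


def classify_image(
    patch_classifier: Callable[[tuple[int, int]], np.ndarray], grid: PatchGrid
) -> int:
    """Consensus class of one image given an injected per-patch classifier
    mapping a patch offset to an 11-class probability vector."""
    return consensus_image(patch_classifier(off) for off in grid.offsets)
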