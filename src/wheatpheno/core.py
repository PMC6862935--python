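"""Shared domain types for the heading-date phenotyping and mapping pipeline.

Conventions used throughout the package:

* genotype dose coding: 0 = parent-A homozygote, 1 = heterozygote,
  2 = parent-B homozygote, ``nan`` = missing;
* map positions in centimorgan (cM), day-of-year is 1-based (Jan 1 = 1);
* percent heading lives on the 11-class grid {0, 10, ..., 100}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

N_CLASSES = 11
CLASS_PERCENTS = np.arange(0, 101, 10)


@dataclass(frozen=True)
class Chromosome:
    """One linkage group: name, genetic length (cM) and ordered marker positions."""

    name: str
    length_cm: float
    positions_cm: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions_cm", np.asarray(self.positions_cm, dtype=float))
        if self.length_cm < 0:
            raise ValueError(f"chromosome {self.name}: negative length {self.length_cm}")
        pos = self.positions_cm
        if pos.size and (np.any(np.diff(pos) < 0) or pos[0] < 0 or pos[-1] > self.length_cm):
            raise ValueError(f"chromosome {self.name}: positions must be ordered within [0, length]")

    @property
    def n_markers(self) -> int:
        return int(self.positions_cm.size)


@dataclass(frozen=True)
class GeneticMap:
    """Ordered collection of chromosomes; marker indexing is global and row-major."""

    chromosomes: tuple[Chromosome, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosomes", tuple(self.chromosomes))
        if not self.chromosomes:
            raise ValueError("map needs at least one chromosome")

    @property
    def n_markers(self) -> int:
        return sum(c.n_markers for c in self.chromosomes)

    def marker_table(self) -> pd.DataFrame:
        """Flat (marker, chrom, pos_cm) table in global marker order."""
        rows = []
        for chrom in self.chromosomes:
            for pos in chrom.positions_cm:
                rows.append((f"{chrom.name}_{pos:g}", chrom.name, float(pos)))
        return pd.DataFrame(rows, columns=["marker", "chrom", "pos_cm"])

    def chrom_slices(self) -> list[slice]:
        out, start = [], 0
        for chrom in self.chromosomes:
            out.append(slice(start, start + chrom.n_markers))
            start += chrom.n_markers
        return out


@dataclass
class GenotypeMatrix:
    """Lines x markers dose matrix with marker metadata.

    ``dose`` is float so missing genotypes can be ``nan``; observed values are
    restricted to {0, 1, 2}.
    """

    line_ids: list[str]
    markers: pd.DataFrame  # columns: marker, chrom, pos_cm
    dose: np.ndarray

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        if self.dose.shape != (len(self.line_ids), len(self.markers)):
            raise ValueError(
                f"dose shape {self.dose.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.markers)} markers"
            )
        observed = self.dose[~np.isnan(self.dose)]
        if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
            raise ValueError("genotype codes must be 0, 1, 2 or missing")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def marker_ids(self) -> list[str]:
        return list(self.markers["marker"])

    def sorted_by_position(self) -> "GenotypeMatrix":
        order = self.markers.sort_values(["chrom", "pos_cm"], kind="stable").index.to_numpy()
        return GenotypeMatrix(
            line_ids=list(self.line_ids),
            markers=self.markers.iloc[order].reset_index(drop=True),
            dose=self.dose[:, order],
        )


@dataclass(frozen=True)
class TraitArchitecture:
    """Genetic architecture of a trait on a given map.

    ``qtl`` holds (global marker index, additive effect) pairs where the effect
    is half the difference between the two homozygote classes (signed toward
    parent B); ``interactions`` holds (i, j, effect) on the product of the
    +/-1 codings of the two loci.  ``polygenic_var`` is the variance (trait
    units squared) of a genome-wide small-effect term.
    """

    qtl: tuple[tuple[int, float], ...] = ()
    interactions: tuple[tuple[int, int, float], ...] = ()
    polygenic_var: float = 0.0
    intercept: float = 0.0
    trait: str = "heading_date"

    def __post_init__(self) -> None:
        object.__setattr__(self, "qtl", tuple((int(i), float(a)) for i, a in self.qtl))
        object.__setattr__(
            self, "interactions", tuple((int(i), int(j), float(e)) for i, j, e in self.interactions)
        )
        if self.polygenic_var < 0:
            raise ValueError("polygenic_var must be >= 0")

    def validate_for(self, n_markers: int) -> None:
        idx = [i for i, _ in self.qtl] + [k for i, j, _ in self.interactions for k in (i, j)]
        if any(i < 0 or i >= n_markers for i in idx):
            raise ValueError("architecture refers to marker index outside the map")


class ScorePoint(NamedTuple):
    """A single visual score: day of year and percent heading on the 10% grid."""

    day: float
    percent: float


@dataclass
class ScoreSeries:
    """Time series of percent-heading observations for one plot."""

    plot: str
    days: np.ndarray
    percents: np.ndarray
    source: str = "visual"

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.percents = np.asarray(self.percents, dtype=float)
        if self.days.shape != self.percents.shape:
            raise ValueError("days and percents must have equal length")

    def __len__(self) -> int:
        return int(self.days.size)


@dataclass
class VarianceComponents:
    """Variance components of the plot-level mixed model.

    The residual may be iid or separable AR1 (rows) x AR1 (columns).  ``n_reps``
    and ``n_years`` are the replication counts entering the heritability
    denominators.
    """

    var_g: float
    var_e: float
    var_gy: float = 0.0
    var_year: float = 0.0
    var_rep: float = 0.0
    rho_row: float = 0.0
    rho_col: float = 0.0
    n_reps: int = 1
    n_years: int = 1
    loglik: float = float("nan")
    converged: bool = True

    def __post_init__(self) -> None:
        for name in ("var_g", "var_e", "var_gy", "var_year", "var_rep"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("rho_row", "rho_col"):
            if not -1 < getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in (-1, 1)")


@dataclass
class LogisticFit:
    """Per-plot logistic fit y = phi1 / (1 + exp(-(phi2 + phi3 * day))).

    phi1 is the upper asymptote and is fixed at 100 (percent); phi2 is the
    unitless intercept and phi3 the per-day slope.  The 50% intersect
    -phi2/phi3 is the heading date and phi3 the rate of heading.
    """

    phi2: float
    phi3: float
    sse: float
    converged: bool
    n_obs: int
    phi1: float = 100.0

    def predict(self, day: np.ndarray | float) -> np.ndarray | float:
        return self.phi1 / (1.0 + np.exp(-(self.phi2 + self.phi3 * np.asarray(day, dtype=float))))


@dataclass(frozen=True)
class AgreementStats:
    """Agreement between two per-plot heading-date measurements (days)."""

    mae: float
    rmse: float
    frac_within_1: float
    frac_within_2: float
    slope: float
    n: int


@dataclass(frozen=True)
class PatchGrid:
    """Geometry of the patch tiling applied to a plot image before classification."""

    image_w: int
    image_h: int
    grid_rows: int
    grid_cols: int
    patch: int
    offsets: tuple[tuple[int, int], ...]  # (y, x) of each patch's top-left corner

    @property
    def n_patches(self) -> int:
        return len(self.offsets)


def rng_for(seed: int, stream: int) -> np.random.Generator:
    """Dedicated substream per operation: one global seed, fixed stream offsets."""
    return np.random.default_rng(np.random.SeedSequence((int(seed), int(stream))))
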