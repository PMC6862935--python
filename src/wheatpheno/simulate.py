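"""Synthetic biparental RIL trials with the statistical structure the pipeline assumes.

The generator produces, in order: a genetic map; an F-generation RIL
population by single-seed descent with Haldane recombination (crossovers per
chromosome ~ Poisson(length/100), uniform positions, no interference);
per-line genetic values from a sparse epistatic QTL architecture plus a
polygenic tail; a replicated multi-year field trial with year, rep-within-year
and separable AR1 x AR1 spatially correlated plot noise; and finally noisy
visual scores of percent heading discretized to 10% increments with the
documented mislabel rates (10% of scores off by one class, 5% off by two).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    CLASS_PERCENTS,
    Chromosome,
    GeneticMap,
    GenotypeMatrix,
    ScoreSeries,
    TraitArchitecture,
    VarianceComponents,
    rng_for,
)

# fixed stream offsets expanding the single global seed (core.rng_for)
_STREAM_RIL = 1
_STREAM_GVALUES = 2
_STREAM_TRIAL = 3
_STREAM_SCORES = 4
_STREAM_IMAGES = 5


def make_genetic_map(n_chrom: int, markers_per_chrom: int, chrom_length_cm: float) -> GeneticMap:
    """Evenly spaced markers on ``n_chrom`` chromosomes of equal length."""
    if n_chrom < 1 or markers_per_chrom < 1 or chrom_length_cm < 1:
        raise ValueError("n_chrom, markers_per_chrom and chrom_length_cm must all be >= 1")
    chroms = []
    for c in range(n_chrom):
        if markers_per_chrom == 1:
            pos = np.array([0.0])
        else:
            pos = np.linspace(0.0, chrom_length_cm, markers_per_chrom)
        chroms.append(Chromosome(name=f"chr{c + 1}", length_cm=float(chrom_length_cm), positions_cm=pos))
    return GeneticMap(chromosomes=tuple(chroms))


def simulate_gametes(
    hap_a: np.ndarray,
    hap_b: np.ndarray,
    gmap: GeneticMap,
    n_gametes: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Meiotic gametes from one individual's two haplotypes (0/1 allele arrays).

    Crossover counts are Poisson(length_cm / 100) per chromosome with uniform
    positions (Haldane model); the starting chromatid is random and switches at
    each crossover.
    """
    m = gmap.n_markers
    out = np.empty((n_gametes, m), dtype=np.int8)
    slices = gmap.chrom_slices()
    for g in range(n_gametes):
        for chrom, sl in zip(gmap.chromosomes, slices):
            n_x = rng.poisson(chrom.length_cm / 100.0)
            start = rng.integers(0, 2)
            if n_x == 0:
                parity = np.full(chrom.n_markers, start)
            else:
                xo = np.sort(rng.uniform(0.0, chrom.length_cm, size=n_x))
                parity = (start + np.searchsorted(xo, chrom.positions_cm, side="left")) % 2
            src_a, src_b = hap_a[sl], hap_b[sl]
            out[g, sl] = np.where(parity == 0, src_a, src_b)
    return out


def simulate_ril_population(
    gmap: GeneticMap,
    n_lines: int,
    n_selfing_generations: int = 5,
    distortion: tuple[int, float] | None = None,
    seed: int = 0,
) -> GenotypeMatrix:
    """Biparental RIL population by single-seed descent from a uniform F1.

    Each line starts as the F1 heterozygote (haplotypes all-0 / all-1) and is
    selfed ``n_selfing_generations`` times, so residual heterozygosity per
    locus is 0.5**g in expectation.  ``distortion=(marker_index, ratio)``
    applies gametic viability selection at one marker: gametes carrying the
    parent-B allele survive ``ratio`` times as often as parent-A gametes at
    every meiosis, pulling the B-allele frequency above 0.5.
    """
    if n_lines < 2:
        raise ValueError("need at least 2 lines")
    if n_selfing_generations < 1:
        raise ValueError("need at least 1 selfing generation")
    m = gmap.n_markers
    d_marker = None
    if distortion is not None:
        d_marker, d_ratio = int(distortion[0]), float(distortion[1])
        if not 0 <= d_marker < m:
            raise ValueError(f"distortion marker {d_marker} outside map with {m} markers")
        if d_ratio <= 0:
            raise ValueError("distortion survival ratio must be > 0")
        # survival probability of a gamete given its allele at the marker
        p_keep = {0: min(1.0, 1.0 / d_ratio), 1: min(1.0, d_ratio)}
    rng = rng_for(seed, _STREAM_RIL)
    dose = np.empty((n_lines, m), dtype=float)
    for line in range(n_lines):
        hap_a = np.zeros(m, dtype=np.int8)
        hap_b = np.ones(m, dtype=np.int8)
        for _ in range(n_selfing_generations):
            gametes = []
            while len(gametes) < 2:
                g = simulate_gametes(hap_a, hap_b, gmap, 1, rng)[0]
                if d_marker is not None and rng.uniform() > p_keep[int(g[d_marker])]:
                    continue
                gametes.append(g)
            hap_a, hap_b = gametes
        dose[line] = hap_a + hap_b
    return GenotypeMatrix(
        line_ids=[f"RIL{line + 1:04d}" for line in range(n_lines)],
        markers=gmap.marker_table(),
        dose=dose,
    )


def genetic_values(G: GenotypeMatrix, arch: TraitArchitecture, seed: int = 0) -> np.ndarray:
    """Per-line genetic values: intercept + additive + epistatic + polygenic terms.

    Loci enter through the symmetric coding x = dose - 1 in {-1, 0, +1}, so a
    heterozygote sits at the midpoint of the two homozygote classes.  The
    polygenic term sums small normal effects over all markers and is rescaled
    so its sample variance across lines equals ``polygenic_var`` exactly.
    """
    arch.validate_for(G.n_markers)
    x = np.nan_to_num(G.dose - 1.0, nan=0.0)
    value = np.full(G.n_lines, float(arch.intercept))
    for idx, eff in arch.qtl:
        value += eff * x[:, idx]
    for i, j, eff in arch.interactions:
        value += eff * x[:, i] * x[:, j]
    if arch.polygenic_var > 0:
        rng = rng_for(seed, _STREAM_GVALUES)
        b = rng.normal(size=G.n_markers)
        u = (x - x.mean(axis=0)) @ b
        s = u.std(ddof=1)
        if s > 0:
            value += u * np.sqrt(arch.polygenic_var) / s
    return value


def _ar1_chol(n: int, rho: float) -> np.ndarray:
    idx = np.arange(n)
    corr = rho ** np.abs(idx[:, None] - idx[None, :])
    return np.linalg.cholesky(corr)


@dataclass(frozen=True)
class MislabelModel:
    """Visual mislabel rates: probability of a one-class (±10%) and a two-class
    (±20%) shift per recorded score."""

    p_shift_10: float = 0.10
    p_shift_20: float = 0.05


def simulate_trial(
    heading_values: np.ndarray,
    rate_values: np.ndarray,
    entry_ids: list[str],
    n_reps: int,
    n_years: int,
    n_rows: int,
    n_cols: int,
    vc: VarianceComponents,
    seed: int = 0,
    rate_noise_sd: float = 0.0,
) -> pd.DataFrame:
    """Replicated field trial laid out on a rows x cols grid, one grid per year.

    Each plot's latent heading date is its line's genetic value plus year,
    rep-within-year, genotype-by-year, and a spatial residual with separable
    AR1 correlation over (row, column).  Reps occupy contiguous row bands
    (augmented-design style blocking) with entries randomized within rep.
    The latent logistic curve per plot has slope phi3 (the line's rate value
    plus optional plot noise) and intercept phi2 = -phi3 * heading_date.
    """
    n_entries = len(entry_ids)
    if len(heading_values) != n_entries or len(rate_values) != n_entries:
        raise ValueError("heading/rate value vectors must match entry_ids")
    if n_rows * n_cols < n_entries * n_reps:
        raise ValueError(f"layout {n_rows}x{n_cols} too small for {n_entries} entries x {n_reps} reps")
    rng = rng_for(seed, _STREAM_TRIAL)
    L_row = _ar1_chol(n_rows, vc.rho_row)
    L_col = _ar1_chol(n_cols, vc.rho_col)
    rows_per_rep = n_rows // n_reps
    records = []
    for year in range(1, n_years + 1):
        year_eff = rng.normal(0.0, np.sqrt(vc.var_year)) if vc.var_year > 0 else 0.0
        gy = rng.normal(0.0, np.sqrt(vc.var_gy), size=n_entries) if vc.var_gy > 0 else np.zeros(n_entries)
        spatial = np.sqrt(vc.var_e) * (L_row @ rng.standard_normal((n_rows, n_cols)) @ L_col.T)
        for rep in range(1, n_reps + 1):
            rep_eff = rng.normal(0.0, np.sqrt(vc.var_rep)) if vc.var_rep > 0 else 0.0
            order = rng.permutation(n_entries)
            row0 = (rep - 1) * rows_per_rep
            for k, entry_idx in enumerate(order):
                row = row0 + k // n_cols
                col = k % n_cols
                hd = heading_values[entry_idx] + year_eff + rep_eff + gy[entry_idx] + spatial[row, col]
                phi3 = rate_values[entry_idx] + (rng.normal(0.0, rate_noise_sd) if rate_noise_sd > 0 else 0.0)
                if phi3 <= 0:
                    raise ValueError("simulated rate (phi3) must stay positive; lower rate_noise_sd")
                records.append(
                    {
                        "plot": f"Y{year}_R{rep}_{entry_ids[entry_idx]}",
                        "entry": entry_ids[entry_idx],
                        "year": year,
                        "rep": rep,
                        "row": row + 1,
                        "col": col + 1,
                        "phi2": -phi3 * hd,
                        "phi3": phi3,
                        "heading_date": hd,
                    }
                )
    return pd.DataFrame.from_records(records)


def sample_visual_scores(
    truth: pd.Series | dict,
    observation_days: np.ndarray,
    noise: MislabelModel | None = MislabelModel(),
    seed: int = 0,
    source: str = "visual",
) -> ScoreSeries:
    """Discretized noisy visual scores of one plot's latent logistic curve.

    The true curve value is rounded to the nearest 10%, then with probability
    ``p_shift_10`` shifted one class and with probability ``p_shift_20``
    shifted two classes (random direction, clipped to [0, 100]).  No
    monotonization is applied, matching raw field scoring.
    """
    days = np.asarray(observation_days, dtype=float)
    curve = 100.0 / (1.0 + np.exp(-(truth["phi2"] + truth["phi3"] * days)))
    score = np.round(curve / 10.0) * 10.0
    if noise is not None and (noise.p_shift_10 > 0 or noise.p_shift_20 > 0):
        rng = rng_for(seed, _STREAM_SCORES)
        u = rng.uniform(size=days.size)
        sign = rng.choice([-1.0, 1.0], size=days.size)
        shift = np.where(u < noise.p_shift_20, 2.0, np.where(u < noise.p_shift_20 + noise.p_shift_10, 1.0, 0.0))
        score = np.clip(score + sign * shift * 10.0, 0.0, 100.0)
    return ScoreSeries(plot=str(truth["plot"]), days=days, percents=score, source=source)


def simulate_image_predictions(
    truth: pd.Series | dict,
    day: float,
    n_images: int,
    neighbor_leak: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Image-level 11-class prediction table for one plot on one day.

    Each image perceives a class drawn from the true class with probability
    ``1 - 2*neighbor_leak`` and each adjacent class with ``neighbor_leak``
    (boundary mass folded back to the true class), then emits a probability
    vector peaked on the perceived class with the same leakage to its
    neighbors.  With leakage 0 every image predicts the true class exactly.
    """
    if n_images < 1:
        raise ValueError("need at least one image")
    if not 0 <= neighbor_leak < 0.5:
        raise ValueError("neighbor_leak must be in [0, 0.5)")
    curve = 100.0 / (1.0 + np.exp(-(truth["phi2"] + truth["phi3"] * day)))
    true_class = int(np.round(curve / 10.0))
    rng = rng_for(seed, _STREAM_IMAGES)

    def peaked(c: int) -> np.ndarray:
        p = np.zeros(11)
        p[c] = 1.0 - 2.0 * neighbor_leak
        for nb in (c - 1, c + 1):
            if 0 <= nb <= 10:
                p[nb] += neighbor_leak
            else:
                p[c] += neighbor_leak
        return p

    rows = []
    base = peaked(true_class)
    for i in range(n_images):
        perceived = int(rng.choice(11, p=base))
        vec = peaked(perceived)
        rows.append(
            {
                "image": f"{truth['plot']}_d{day:g}_img{i + 1}",
                "plot": truth["plot"],
                "day": float(day),
                **{f"p{c}": vec[ci] for ci, c in enumerate(CLASS_PERCENTS)},
            }
        )
    return pd.DataFrame(rows)


def default_heading_architecture(gmap: GeneticMap) -> TraitArchitecture:
    """Three-locus epistatic heading-date architecture (days).

    Mimics the photoperiod-gene architecture of winter wheat: a major locus
    (Ppd-D1-like, -2.5 d for the early allele), a second photoperiod locus
    (-1.6 d) and a third locus (-1.2 d) whose effects interact with the major
    locus (-1.2 d each), so the third locus reverses sign conditional on the
    major early allele.  A small polygenic tail (0.25 d^2) sits on top of an
    intercept near day 128.
    """
    slices = gmap.chrom_slices()
    if len(slices) < 3:
        raise ValueError("default architecture needs at least 3 chromosomes")
    mid = [s.start + (s.stop - s.start) // 2 for s in slices[:3]]
    return TraitArchitecture(
        qtl=((mid[0], -2.5), (mid[1], -1.6), (mid[2], -1.2)),
        interactions=((mid[0], mid[1], -1.2), (mid[0], mid[2], -1.2)),
        polygenic_var=0.25,
        intercept=128.0,
        trait="heading_date",
    )


def default_rate_architecture(gmap: GeneticMap) -> TraitArchitecture:
    """Purely polygenic rate-of-heading trait (per-day units): no large-effect
    loci, variance 0.01 around a mean slope of 0.55/day."""
    return TraitArchitecture(qtl=(), interactions=(), polygenic_var=0.01, intercept=0.55, trait="rate")
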