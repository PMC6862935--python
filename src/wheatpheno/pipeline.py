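"""End-to-end synthetic-or-real pipeline with a plain-text config.

Stages (each toggleable): simulate -> impute -> consensus -> phenology ->
heritability -> scan -> epistasis -> predict.  Every run writes its tables
plus a manifest recording package/library versions, the global seed and a
hash of the full parameter set, so a rerun with the same config is
reproducible byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, genescan, io, labels, phenology, quantgen, simulate
from .core import VarianceComponents

log = logging.getLogger("wheatpheno")


@dataclass
class PipelineConfig:
    """All pipeline parameters; defaults mirror the documented analysis
    (phi1 = 100, 0.1-day grid, 10/20/30-day anchors, 0.7/0.1/0.05 soft labels,
    alpha = 0.05, MAF >= 0.1, missing <= 30%, het <= 6%, 10% masking x 100 CV
    replicates)."""

    seed: int = 1
    out_dir: str = "wheatpheno_run"
    # stage toggles
    stages: list[str] = field(
        default_factory=lambda: ["simulate", "phenology", "heritability", "scan", "epistasis"]
    )
    # input paths (unused when simulating)
    scores_path: str | None = None
    layout_path: str | None = None
    genotypes_path: str | None = None
    # simulation
    n_lines: int = 300
    n_chrom: int = 5
    markers_per_chrom: int = 40
    chrom_length_cm: float = 150.0
    n_selfing_generations: int = 5
    n_reps: int = 2
    n_years: int = 1
    n_rows: int = 40
    n_cols: int = 16
    var_e: float = 0.3
    rho_row: float = 0.4
    rho_col: float = 0.4
    rate_noise_sd: float = 0.08
    p_shift_10: float = 0.10
    p_shift_20: float = 0.05
    obs_interval_days: float = 3.0
    season: tuple[float, float] = (112.0, 145.0)
    # phenology
    grid_step: float = 0.1
    # filters and tests
    alpha: float = 0.05
    maf_min: float = 0.1
    miss_max: float = 0.30
    het_max: float = 0.06
    het_policy: str = "missing"
    # prediction
    mask_fraction: float = 0.10
    cv_reps: int = 100
    spatial: str = "iid"

    def validate(self) -> None:
        checks = [
            (0 <= self.maf_min <= 0.5, "maf_min must be in [0, 0.5]"),
            (0 <= self.miss_max <= 1, "miss_max must be in [0, 1]"),
            (0 <= self.het_max <= 1, "het_max must be in [0, 1]"),
            (0 < self.alpha < 1, "alpha must be in (0, 1)"),
            (0 < self.mask_fraction < 1, "mask_fraction must be in (0, 1)"),
            (self.grid_step > 0, "grid_step must be positive"),
            (0 <= self.p_shift_10 + self.p_shift_20 <= 1, "mislabel probabilities must sum within [0, 1]"),
            (self.spatial in ("iid", "ar1"), "spatial must be 'iid' or 'ar1'"),
            (self.het_policy in ("missing", "midpoint"), "het_policy must be 'missing' or 'midpoint'"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid config: {msg}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "season" in raw:
            raw["season"] = tuple(raw["season"])
        return cls(**raw)

    def param_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _simulate_inputs(cfg: PipelineConfig):
    gmap = simulate.make_genetic_map(cfg.n_chrom, cfg.markers_per_chrom, cfg.chrom_length_cm)
    G = simulate.simulate_ril_population(
        gmap, cfg.n_lines, cfg.n_selfing_generations, seed=cfg.seed
    )
    arch_hd = simulate.default_heading_architecture(gmap)
    arch_rate = simulate.default_rate_architecture(gmap)
    hd = simulate.genetic_values(G, arch_hd, seed=cfg.seed)
    rate = simulate.genetic_values(G, arch_rate, seed=cfg.seed + 7)
    vc = VarianceComponents(
        var_g=float(np.var(hd, ddof=1)), var_e=cfg.var_e,
        rho_row=cfg.rho_row, rho_col=cfg.rho_col,
        n_reps=cfg.n_reps, n_years=cfg.n_years,
    )
    truth = simulate.simulate_trial(
        hd, rate, G.line_ids, cfg.n_reps, cfg.n_years, cfg.n_rows, cfg.n_cols,
        vc, seed=cfg.seed, rate_noise_sd=cfg.rate_noise_sd,
    )
    days = np.arange(cfg.season[0], cfg.season[1] + 1e-9, cfg.obs_interval_days)
    noise = simulate.MislabelModel(cfg.p_shift_10, cfg.p_shift_20)
    score_rows = []
    for i, (_, row) in enumerate(truth.iterrows()):
        s = simulate.sample_visual_scores(row, days, noise=noise, seed=cfg.seed * 100003 + i)
        score_rows.append(pd.DataFrame(
            {"plot": s.plot, "day": s.days, "percent": s.percents, "source": s.source}
        ))
    scores = pd.concat(score_rows, ignore_index=True)
    layout = truth[["plot", "entry", "year", "rep", "row", "col"]].copy()
    return G, truth, scores, layout


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the toggled stages, writing CSV artifacts and a manifest into
    ``cfg.out_dir``; returns the in-memory results keyed by stage."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    stages = list(cfg.stages)

    if "simulate" in stages:
        G, truth, scores, layout = _simulate_inputs(cfg)
        io.write_genotypes_csv(G, out / "genotypes.csv", out / "genotypes_map.csv")
        truth.to_csv(out / "plot_truth.csv", index=False)
        scores.to_csv(out / "scores.csv", index=False)
        layout.to_csv(out / "layout.csv", index=False)
        log.info("simulate: %d lines, %d markers, %d plots", G.n_lines, G.n_markers, len(truth))
    else:
        G = io.read_genotypes(cfg.genotypes_path) if cfg.genotypes_path else None
        scores = io.read_scores(cfg.scores_path) if cfg.scores_path else None
        layout = io.read_layout(cfg.layout_path) if cfg.layout_path else None
    results["genotypes"], results["scores"], results["layout"] = G, scores, layout

    if "impute" in stages:
        if scores is None:
            raise RuntimeError("impute stage needs a score table (scores_path or simulate stage)")
        days = sorted(scores["day"].unique())
        results["imputed"] = labels.impute_labels_table(scores, days)
        results["imputed"].to_csv(out / "imputed_labels.csv", index=False)

    if "phenology" in stages:
        if scores is None:
            raise RuntimeError("phenology stage needs a score table (scores_path or simulate stage)")
        fits = phenology.fit_plots(scores, step=cfg.grid_step)
        fits.to_csv(out / "phenology.csv", index=False)
        results["phenology"] = fits
        log.info("phenology: fit %d plots, %d converged", len(fits), int(fits["converged"].sum()))

    if "heritability" in stages:
        if layout is None or "phenology" not in results:
            raise RuntimeError("heritability stage needs layout and phenology outputs")
        plots = layout.merge(results["phenology"][["plot", "heading_date", "rate"]], on="plot")
        h2_rows = []
        vcs = {}
        for trait in ("heading_date", "rate"):
            tbl = plots.rename(columns={trait: "value"})[
                ["entry", "year", "rep", "row", "col", "value"]
            ].dropna(subset=["value"])
            vc = quantgen.fit_variance_components(tbl, spatial=cfg.spatial, seed=cfg.seed)
            mode = "multi_year" if vc.n_years > 1 else "single_year"
            h2_rows.append({
                "trait": trait, "H2": quantgen.heritability(vc, mode), "mode": mode,
                "var_g": vc.var_g, "var_gy": vc.var_gy, "var_e": vc.var_e,
                "rho_row": vc.rho_row, "rho_col": vc.rho_col,
            })
            vcs[trait] = vc
            blups = quantgen.entry_values(tbl, mode="BLUP", vc=vc, spatial=cfg.spatial)
            blups.rename("value").rename_axis("entry").to_csv(out / f"blup_{trait}.csv")
            results[f"blup_{trait}"] = blups
        results["heritability"] = pd.DataFrame(h2_rows)
        results["variance_components"] = vcs
        results["heritability"].to_csv(out / "heritability.csv", index=False)

    if "scan" in stages or "epistasis" in stages or "predict" in stages:
        if G is None:
            raise RuntimeError("genetic stages need genotypes (genotypes_path or simulate stage)")
        Gf, report = genescan.filter_markers(G, cfg.maf_min, cfg.miss_max, cfg.het_max)
        log.info("marker filter: %s", report)
        results["filter_report"] = report
        pheno = results.get(f"blup_heading_date")
        if pheno is None:
            raise RuntimeError("genetic stages need entry values from the heritability stage")
        y = pheno.reindex(Gf.line_ids).to_numpy()

    if "scan" in stages:
        scan = genescan.marker_scan(y, Gf, alpha=cfg.alpha, het=cfg.het_policy)
        scan.to_csv(out / "scan.csv", index=False)
        results["scan"] = scan
        log.info("scan: %d/%d markers significant", int(scan["significant"].sum()), len(scan))

    if "epistasis" in stages:
        sig = list(np.flatnonzero(results["scan"]["significant"].to_numpy()))
        if len(sig) >= 2:
            epi = genescan.epistasis_scan(y, Gf, sig, alpha=cfg.alpha, het=cfg.het_policy)
            epi.to_csv(out / "epistasis.csv", index=False)
            results["epistasis"] = epi
        else:
            log.info("epistasis: fewer than 2 significant markers, skipped")

    if "predict" in stages:
        rate = results.get("blup_rate")
        if rate is None:
            raise RuntimeError("predict stage needs rate BLUPs from the heritability stage")
        cv = genescan.genomic_prediction_cv(
            rate.reindex(Gf.line_ids).to_numpy(), Gf,
            mask_fraction=cfg.mask_fraction, reps=cfg.cv_reps, seed=cfg.seed,
        )
        results["prediction_cv"] = cv
        pd.DataFrame({"rep": np.arange(cv.reps), "r": cv.per_rep_r}).to_csv(
            out / "prediction_cv.csv", index=False
        )

    manifest = {
        "wheatpheno": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": cfg.seed,
        "param_hash": cfg.param_hash(),
        "stages": stages,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    results["manifest"] = manifest
    return results
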