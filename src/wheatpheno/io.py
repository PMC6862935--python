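"""Table and genotype readers/writers.

All tables are plain CSV.  Genotypes travel either as a lines x markers CSV
(header = marker ids) paired with a map CSV (marker, chrom, pos_cm), or as a
minimal biallelic VCF (GT field only, one sample per line).  VCF base-pair
positions encode map positions at 1 cM = 1 Mb (pos_bp = round(pos_cm * 1e6) + 1),
documented here because the genetic map is the native coordinate system.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import GenotypeMatrix

log = logging.getLogger("wheatpheno")

_CM_PER_BP = 1e-6
_GT_CODES = {(0, 0): 0.0, (0, 1): 1.0, (1, 0): 1.0, (1, 1): 2.0}


def write_genotypes_csv(G: GenotypeMatrix, geno_path: str | Path, map_path: str | Path) -> None:
    df = pd.DataFrame(G.dose, index=pd.Index(G.line_ids, name="line"), columns=G.marker_ids)
    df.to_csv(geno_path)
    G.markers.to_csv(map_path, index=False)


def read_genotypes_csv(geno_path: str | Path, map_path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(geno_path, index_col=0)
    markers = pd.read_csv(map_path)
    if list(df.columns) != list(markers["marker"]):
        markers = markers.set_index("marker").loc[list(df.columns)].reset_index()
    G = GenotypeMatrix(
        line_ids=[str(x) for x in df.index],
        markers=markers[["marker", "chrom", "pos_cm"]].reset_index(drop=True),
        dose=df.to_numpy(dtype=float),
    )
    return G.sorted_by_position()


def write_genotypes_vcf(G: GenotypeMatrix, path: str | Path) -> None:
    """Minimal biallelic VCF, one sample per line, GT only; REF/ALT stand for
    the parent-A and parent-B alleles."""
    gt_str = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in G.markers["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(G.line_ids) + "\n")
        for k in range(G.n_markers):
            row = G.markers.iloc[k]
            pos_bp = int(round(row["pos_cm"] / _CM_PER_BP)) + 1
            calls = "\t".join(gt_str.get(d, "./.") for d in G.dose[:, k])
            fh.write(f"{row['chrom']}\t{pos_bp}\t{row['marker']}\tA\tB\t.\t.\t.\tGT\t{calls}\n")


def read_genotypes_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a biallelic VCF into dose coding {0, 1, 2, missing}; multiallelic
    records are skipped with a logged count."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    line_ids = list(vcf.samples)
    rows, doses, skipped = [], [], 0
    for var in vcf:
        if len(var.ALT) != 1:
            skipped += 1
            continue
        d = np.full(len(line_ids), np.nan)
        for i, gt in enumerate(var.genotypes):
            a, b = gt[0], gt[1]
            if a >= 0 and b >= 0:
                d[i] = _GT_CODES[(min(a, 1), min(b, 1))]
        rows.append((var.ID or f"{var.CHROM}_{var.POS}", var.CHROM, (var.POS - 1) * _CM_PER_BP))
        doses.append(d)
    vcf.close()
    if skipped:
        log.warning("skipped %d multiallelic VCF records", skipped)
    markers = pd.DataFrame(rows, columns=["marker", "chrom", "pos_cm"])
    G = GenotypeMatrix(line_ids=line_ids, markers=markers, dose=np.array(doses).T)
    return G.sorted_by_position()


def read_genotypes(path: str | Path, format: str | None = None) -> GenotypeMatrix:
    """Dispatch on format ('vcf' or 'csv'; csv expects a sibling map file named
    ``<stem>_map.csv``)."""
    path = Path(path)
    fmt = format or ("vcf" if path.suffix.lower() == ".vcf" else "csv")
    if fmt == "vcf":
        return read_genotypes_vcf(path)
    if fmt == "csv":
        return read_genotypes_csv(path, path.with_name(path.stem + "_map.csv"))
    raise ValueError(f"unknown genotype format {fmt!r}")


def read_scores(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    needed = {"plot", "day", "percent"}
    if missing := needed - set(df.columns):
        raise ValueError(f"score table {path} missing columns {sorted(missing)}")
    return df


def read_layout(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    needed = {"plot", "entry", "year", "rep", "row", "col"}
    if missing := needed - set(df.columns):
        raise ValueError(f"layout table {path} missing columns {sorted(missing)}")
    return df
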