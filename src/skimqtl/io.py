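"""Readers and writers for the pipeline's on-disk formats.

Genotypes travel as parent-coded TSV (sites as rows: chrom, pos, one
{A, B, -} column per line) or as minimal biallelic VCF with GT-only
samples.  Gene models are GFF3 (1-based inclusive, read through
gffutils); bins and LD blocks are additionally exported as BED, which is
the only place coordinates become 0-based half-open.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import GeneAnnotation, GenotypeMatrix

# ---------------------------------------------------------------------------
# parent-coded TSV

def write_genotypes_tsv(matrix: GenotypeMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index=False)


def read_genotypes_tsv(path: str | Path) -> GenotypeMatrix:
    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str}, keep_default_na=False)
    frame["pos"] = frame["pos"].astype(np.int64)
    return GenotypeMatrix.from_frame(frame)


# ---------------------------------------------------------------------------
# VCF

_VCF_HEADER = """##fileformat=VCFv4.2
##source=skimqtl
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_vcf(
    matrix: GenotypeMatrix,
    path: str | Path,
    parent1: str = "P1",
    parent2: str = "P2",
) -> None:
    """Minimal biallelic VCF: parents as fixed 0/0 and 1/1 samples, lines
    as homozygous-coded GT with missing './.'."""
    from .core import A, B

    samples = [parent1, parent2, *matrix.lines]
    gt_map = {A: "0/0", B: "1/1"}
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for chrom in matrix.chromosomes():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for j, site in enumerate(matrix.sites.itertuples(index=False)):
            calls = ["0/0", "1/1"] + [
                gt_map.get(int(c), "./.") for c in matrix.calls[:, j]
            ]
            fh.write(
                f"{site.chrom}\t{site.pos}\t.\tG\tT\t.\tPASS\t.\tGT\t"
                + "\t".join(calls)
                + "\n"
            )


def read_genotypes_vcf(
    path: str | Path, parent1: str, parent2: str
) -> tuple[GenotypeMatrix, dict]:
    """Read a biallelic VCF and encode lines against the two parents.

    Parent samples must be homozygous and distinct at a site for it to
    be informative; heterozygous or third-allele line calls are missing.
    Multi-allelic records are skipped and counted.
    """
    from cyvcf2 import VCF

    from .core import MISSING, A, B

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    for parent in (parent1, parent2):
        if parent not in samples:
            raise ValueError(f"parent sample {parent!r} not in VCF")
    i1, i2 = samples.index(parent1), samples.index(parent2)
    line_idx = [k for k, s in enumerate(samples) if s not in (parent1, parent2)]
    lines = [samples[k] for k in line_idx]
    sites = []
    columns = []
    n_multiallelic = 0
    n_uninformative = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multiallelic += 1
            continue
        gts = rec.genotypes  # [allele1, allele2, phased]
        g1, g2 = gts[i1], gts[i2]

        def _hom(g):
            return g[0] if g[0] == g[1] and g[0] >= 0 else None

        a1, a2 = _hom(g1), _hom(g2)
        if a1 is None or a2 is None or a1 == a2:
            n_uninformative += 1
            continue
        col = np.full(len(line_idx), MISSING, dtype=np.int8)
        for out_i, k in enumerate(line_idx):
            allele = _hom(gts[k])
            if allele == a1:
                col[out_i] = A
            elif allele == a2:
                col[out_i] = B
        sites.append({"chrom": rec.CHROM, "pos": rec.POS})
        columns.append(col)
    if not sites:
        raise ValueError("no informative biallelic sites in VCF")
    matrix = GenotypeMatrix(
        sites=pd.DataFrame(sites),
        lines=lines,
        calls=np.column_stack(columns),
    )
    report = {
        "n_multiallelic_skipped": n_multiallelic,
        "n_uninformative_skipped": n_uninformative,
    }
    return matrix, report


def read_genotypes(
    path: str | Path,
    fmt: str = "tsv",
    parent1: str = "P1",
    parent2: str = "P2",
) -> GenotypeMatrix:
    if fmt == "tsv":
        return read_genotypes_tsv(path)
    if fmt == "vcf":
        matrix, _ = read_genotypes_vcf(path, parent1, parent2)
        return matrix
    raise ValueError(f"unknown genotype format {fmt!r}")


# ---------------------------------------------------------------------------
# GFF3

def write_gff3(annotation: GeneAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in annotation.genes.itertuples(index=False):
            fh.write(
                f"{g.chrom}\tskimqtl\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )


def read_annotation(path: str | Path) -> GeneAnnotation:
    """Gene-typed GFF3 features as a GeneAnnotation (1-based inclusive)."""
    import warnings

    import gffutils

    # quick structural check: gffutils tolerates inverted coordinates
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 5 and int(parts[3]) > int(parts[4]):
                raise ValueError(f"{path}:{ln}: feature start > end")
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    rows = []
    for feat in db.features_of_type("gene"):
        rows.append(
            {
                "gene_id": feat.id,
                "chrom": feat.seqid,
                "start": feat.start,
                "end": feat.end,
                "strand": feat.strand or "+",
            }
        )
    if not rows:
        warnings.warn("no gene-typed features in GFF3", stacklevel=2)
        return GeneAnnotation()
    return GeneAnnotation(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# BED (the single 0-based half-open surface)

def write_bed(intervals: pd.DataFrame, path: str | Path, name_col: str = "bin_id") -> None:
    """Write 1-based inclusive intervals (chrom, start, end, <name>) as BED."""
    out = intervals[["chrom", "start", "end", name_col]].copy()
    out["start"] = out["start"].astype(int) - 1
    out["end"] = out["end"].astype(int)
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# tables

def write_phenotypes(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index_label="line")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="line")


def write_qtl_table(
    qtls: pd.DataFrame, regions: list, gmap, path: str | Path
) -> None:
    """QTL results CSV with the reporting column set: trait, linkage
    group, flanking markers, region, physical size (Kb), genetic size
    (cM), LOD, PVE."""
    from .qtl import region_size_kb

    region_of = {}
    for reg in regions:
        region_of[(reg.left_bin, reg.right_bin)] = reg.name
    rows = []
    for q in qtls.to_dict("records"):
        size_kb = region_size_kb(q["left_bin"], q["right_bin"])
        cm_l = gmap.table.loc[gmap.table["bin_id"] == q["left_bin"], "cm"]
        cm_r = gmap.table.loc[gmap.table["bin_id"] == q["right_bin"], "cm"]
        genetic = (
            abs(float(cm_r.iloc[0]) - float(cm_l.iloc[0]))
            if len(cm_l) and len(cm_r)
            else np.nan
        )
        rows.append(
            {
                "trait": q["trait"],
                "environment": q["environment"],
                "linkage_group": q["chrom"],
                "flanking_markers": f"{q['left_bin']} - {q['right_bin']}",
                "region": region_of.get((q["left_bin"], q["right_bin"]), ""),
                "physical_size_kb": size_kb,
                "genetic_size_cm": round(genetic, 2) if np.isfinite(genetic) else "",
                "lod": round(float(q["lod"]), 2),
                "pve_pct": round(float(q["pve"]), 2),
                "additive": round(float(q["additive"]), 4),
                "class": q["class"],
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")
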