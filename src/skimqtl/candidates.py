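"""Candidate-gene resolution and prioritization.

Hotspot sub-regions delimited by flanking bins are resolved to gene
lists by interval overlap against the annotation, and the prioritized
candidates are the genes named by both lines of evidence: presence in a
QTL hotspot region and significance in the co-localization enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .core import GeneAnnotation
from .qtl import HotspotRegion


def genes_in_region(
    region: HotspotRegion, annotation: GeneAnnotation
) -> pd.DataFrame:
    """Genes overlapping a hotspot region (1-based inclusive, any overlap)."""
    chroms = set(annotation.genes["chrom"]) if len(annotation) else set()
    genes = annotation.genes
    match = genes["chrom"].map(_chrom_key) == _chrom_key(region.chrom)
    if len(annotation) and not match.any() and region.chrom not in chroms:
        raise ValueError(f"region chromosome {region.chrom!r} not in annotation")
    on_chrom = genes[match]
    overlap = (on_chrom["start"] <= region.end) & (on_chrom["end"] >= region.start)
    return on_chrom[overlap].reset_index(drop=True)


def _chrom_key(chrom: str) -> str:
    from .binning import chromosome_number

    return chromosome_number(str(chrom))


@dataclass
class CandidateSet:
    region_genes: list[str]
    enriched_genes: list[str]
    prioritized: list[str]
    provenance: pd.DataFrame = field(default_factory=pd.DataFrame)


def prioritize(
    region_genes: pd.DataFrame | list[str],
    enriched_genes: list[str],
    annotation: GeneAnnotation | None = None,
) -> CandidateSet:
    """Intersect region genes with enrichment-positive genes.

    The prioritized list is the set intersection, stable-sorted by
    genomic position when an annotation is available (by id otherwise);
    the provenance table records which source(s) named each gene.
    """
    if isinstance(region_genes, pd.DataFrame):
        region_ids = list(region_genes["gene_id"])
    else:
        region_ids = list(region_genes)
    region_set = set(region_ids)
    enriched_set = set(enriched_genes)
    common = region_set & enriched_set

    def sort_key(gid: str):
        if annotation is not None and len(annotation):
            row = annotation.genes[annotation.genes["gene_id"] == gid]
            if len(row):
                return (str(row["chrom"].iloc[0]), int(row["start"].iloc[0]), gid)
        return ("", 0, gid)

    prioritized = sorted(common, key=sort_key)
    all_ids = sorted(region_set | enriched_set, key=sort_key)
    provenance = pd.DataFrame(
        {
            "gene_id": all_ids,
            "in_region": [g in region_set for g in all_ids],
            "enriched": [g in enriched_set for g in all_ids],
        }
    )
    return CandidateSet(
        region_genes=sorted(region_set, key=sort_key),
        enriched_genes=sorted(enriched_set, key=sort_key),
        prioritized=prioritized,
        provenance=provenance,
    )
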