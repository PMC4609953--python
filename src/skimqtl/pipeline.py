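"""Stage-oriented pipeline driver with a reproducible run manifest.

Stages run in a fixed order — simulate (synthetic mode only), qc,
binmap, map, qtl, gwas, enrich, prioritize — and every stage reads the
canonical artifacts of its predecessors from the output directory, so
any stage can be re-run on its own.  The manifest records the package
version, the seed, every parameter block and a sha256 checksum per
artifact: two runs with the same configuration and seed produce
identical manifests.

Defaults emulate the study conditions (222 lines at ~0.72X, eight
chromosomes, 15-SNP windows at >= 9 homozygous calls, 100 kb grid,
MAF >= 0.20, ICIM with 1000 permutations at alpha 0.05, RMIP >= 5 of
100 resamples, 10,000 enrichment permutations, PVE > 10% for a major
QTL).  One deliberate exception: skim coverage leaves about half of all
calls missing by design, so in synthetic mode the per-line missingness
filter ships at 0.95 — the literal 5% rule would discard every
skim-genotyped line and belongs to dense genotyping matrices.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, binning, candidates, io, linkage, qc, qtl, simulate
from .core import GeneAnnotation


@dataclass
class GenomeConfig:
    n_chromosomes: int = 2
    chrom_length: int = 50_000_000
    snps_per_chromosome: int = 2_000
    recomb_rate: float = simulate.DEFAULT_RECOMB_RATE


@dataclass
class PopulationConfig:
    n_lines: int = simulate.DEFAULT_N_LINES
    generation: int = simulate.DEFAULT_GENERATION
    mean_depth: float = simulate.DEFAULT_MEAN_DEPTH
    error_rate: float = simulate.DEFAULT_ERROR_RATE


@dataclass
class TraitConfig:
    name: str = "trait1"
    chrom: str = "Ca1"
    pos: int = 25_000_000
    effect: float = 1.0
    h2: float = 0.6


@dataclass
class QcConfig:
    maf_min: float = 0.20
    line_missing_max: float = 0.95  # skim data: ~half of calls missing by design


@dataclass
class RunConfig:
    mode: str = "synthetic"  # or "real"
    seed: int = 0
    outdir: str = "skimqtl_run"
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    population: PopulationConfig = field(default_factory=PopulationConfig)
    traits: list[TraitConfig] = field(default_factory=lambda: [TraitConfig()])
    n_environments: int = 1
    n_genes: int = 200
    mean_gene_length: int = 3_000
    qc: QcConfig = field(default_factory=QcConfig)
    binning: binning.BinningParams = field(default_factory=binning.BinningParams)
    map: linkage.MapParams = field(default_factory=linkage.MapParams)
    icim: qtl.IcimParams = field(default_factory=qtl.IcimParams)
    assoc: association.AssocParams = field(default_factory=association.AssocParams)
    genome_size_kb: float | None = None
    # real-data inputs
    genotypes_path: str | None = None
    genotypes_format: str = "tsv"
    parent1: str = "P1"
    parent2: str = "P2"
    phenotypes_path: str | None = None
    annotation_path: str | None = None

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        nested = {
            "genome": GenomeConfig,
            "population": PopulationConfig,
            "qc": QcConfig,
            "binning": binning.BinningParams,
            "map": linkage.MapParams,
            "icim": qtl.IcimParams,
            "assoc": association.AssocParams,
        }
        for key, klass in nested.items():
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = klass(**kwargs[key])
        if "traits" in kwargs:
            kwargs["traits"] = [
                TraitConfig(**t) if isinstance(t, dict) else t
                for t in kwargs["traits"]
            ]
        return cls(**kwargs)


class StageError(RuntimeError):
    """A stage's upstream artifact is missing."""


def _require(path: Path, stage: str, needed_by: str) -> Path:
    if not path.exists():
        raise StageError(
            f"stage {needed_by!r} needs {path.name} from stage {stage!r}; "
            f"run that stage first"
        )
    return path


def _seeded(config: RunConfig, offset: int) -> int:
    return (config.seed * 1000 + offset) % (2**31 - 1)


# ---------------------------------------------------------------------------
# stages

def stage_simulate(config: RunConfig, out: Path) -> dict:
    genome = simulate.make_genome(
        n_chromosomes=config.genome.n_chromosomes,
        chrom_length=config.genome.chrom_length,
        snps_per_chromosome=config.genome.snps_per_chromosome,
        recomb_rate=config.genome.recomb_rate,
        seed=_seeded(config, 1),
    )
    truth = simulate.simulate_ril(
        genome,
        n_lines=config.population.n_lines,
        n_selfing_generations=config.population.generation,
        seed=_seeded(config, 2),
    )
    skim = simulate.simulate_skim(
        truth,
        simulate.SkimModel(
            mean_depth=config.population.mean_depth,
            error_rate=config.population.error_rate,
            seed=_seeded(config, 3),
        ),
    )
    spec = simulate.QtlSpec(
        traits=[
            simulate.TraitModel(
                name=t.name, qtls=[(t.chrom, t.pos, t.effect)], h2=t.h2
            )
            for t in config.traits
        ],
        n_environments=config.n_environments,
    )
    phenos = simulate.simulate_phenotypes(truth, spec, seed=_seeded(config, 4))
    genes = simulate.simulate_genes(
        genome,
        n_genes=config.n_genes,
        mean_length=config.mean_gene_length,
        seed=_seeded(config, 5),
    )
    io.write_genotypes_tsv(skim, out / "genotypes.tsv")
    io.write_vcf(skim, out / "genotypes.vcf")
    truth.breakpoint_table().to_csv(out / "truth_breakpoints.csv", index=False)
    io.write_phenotypes(phenos.table, out / "phenotypes.csv")
    phenos.qtl_sites.to_csv(out / "truth_qtls.csv", index=False)
    io.write_gff3(genes, out / "genes.gff3")
    lengths = {c.name: c.length for c in genome.chromosomes}
    io.write_json({"chrom_lengths": lengths}, out / "genome.json")
    return {
        "artifacts": [
            "genotypes.tsv",
            "genotypes.vcf",
            "truth_breakpoints.csv",
            "phenotypes.csv",
            "truth_qtls.csv",
            "genes.gff3",
            "genome.json",
        ]
    }


def stage_qc(config: RunConfig, out: Path) -> dict:
    if config.mode == "real":
        if not config.genotypes_path:
            raise StageError("stage 'qc' needs genotypes_path in real-data mode")
        matrix = io.read_genotypes(
            config.genotypes_path,
            config.genotypes_format,
            config.parent1,
            config.parent2,
        )
    else:
        matrix = io.read_genotypes_tsv(_require(out / "genotypes.tsv", "simulate", "qc"))
    filtered, report = qc.apply_filters(
        matrix,
        maf_min=config.qc.maf_min,
        line_missing_max=config.qc.line_missing_max,
    )
    io.write_genotypes_tsv(filtered, out / "genotypes_filtered.tsv")
    io.write_json(
        {
            "n_removed_sites": report.n_removed_sites,
            "n_removed_lines": report.n_removed_lines,
            "removed_lines": report.removed_lines,
            "maf_min": report.maf_min,
            "line_missing_max": report.line_missing_max,
        },
        out / "qc_report.json",
    )
    return {"artifacts": ["genotypes_filtered.tsv", "qc_report.json"]}


def _chrom_lengths(out: Path) -> dict[str, int] | None:
    import json

    path = out / "genome.json"
    if path.exists():
        with open(path) as fh:
            return {k: int(v) for k, v in json.load(fh)["chrom_lengths"].items()}
    return None


def stage_binmap(config: RunConfig, out: Path) -> dict:
    matrix = io.read_genotypes_tsv(
        _require(out / "genotypes_filtered.tsv", "qc", "binmap")
    )
    lengths = _chrom_lengths(out)
    segments = binning.call_segments(matrix, config.binning, lengths)
    bins = binning.consensus_bins(segments, matrix, config.binning, lengths)
    bin_matrix = binning.genotype_bins(bins, segments)
    bins.to_csv(out / "bins.csv", index=False)
    io.write_bed(bins, out / "bins.bed")
    bin_matrix.to_frame().to_csv(out / "bin_genotypes.tsv", sep="\t", index=False)
    annotation = (
        io.read_annotation(out / "genes.gff3")
        if (out / "genes.gff3").exists()
        else None
    )
    io.write_json(binning.bin_statistics(bins, annotation), out / "bin_stats.json")
    return {"artifacts": ["bins.csv", "bins.bed", "bin_genotypes.tsv", "bin_stats.json"]}


def _read_bin_matrix(out: Path, stage: str) -> binning.BinGenotypeMatrix:
    from .core import characters_to_calls

    frame = pd.read_csv(
        _require(out / "bin_genotypes.tsv", "binmap", stage),
        sep="\t",
        dtype={"chrom": str},
        keep_default_na=False,
    )
    meta = ["bin_id", "chrom", "start", "end"]
    lines = [c for c in frame.columns if c not in meta]
    bins = frame[meta].copy()
    bins["start"] = bins["start"].astype(int)
    bins["end"] = bins["end"].astype(int)
    calls = characters_to_calls(frame[lines].to_numpy(dtype="<U1").T)
    return binning.BinGenotypeMatrix(bins=bins, lines=lines, calls=calls)


def stage_map(config: RunConfig, out: Path) -> dict:
    bin_matrix = _read_bin_matrix(out, "map")
    gmap = linkage.build_map(bin_matrix, config.map)
    gmap.table.to_csv(out / "genetic_map.csv", index=False)
    genome_kb = config.genome_size_kb
    if genome_kb is None and config.mode == "synthetic":
        genome_kb = config.genome.n_chromosomes * config.genome.chrom_length / 1000.0
    summary = linkage.map_summary(gmap, genome_kb)
    n_total = bin_matrix.n_bins
    summary["n_bins_total"] = n_total
    summary["placement_pct"] = linkage.placement_percentage(
        len(gmap.table), n_total
    )
    io.write_json(summary, out / "map_summary.json")
    return {"artifacts": ["genetic_map.csv", "map_summary.json"]}


def stage_qtl(config: RunConfig, out: Path) -> dict:
    bin_matrix = _read_bin_matrix(out, "qtl")
    map_table = pd.read_csv(
        _require(out / "genetic_map.csv", "map", "qtl"), dtype={"chrom": str}
    )
    gmap = linkage.GeneticMap(
        table=map_table, mapping_function=config.map.mapping_function
    )
    pheno_path = (
        Path(config.phenotypes_path)
        if config.mode == "real" and config.phenotypes_path
        else _require(out / "phenotypes.csv", "simulate", "qtl")
    )
    phenos = io.read_phenotypes(pheno_path).loc[bin_matrix.lines]
    all_qtls = []
    thresholds = {}
    for col in phenos.columns:
        y = phenos[col].to_numpy(dtype=float)
        params = dataclasses.replace(config.icim, seed=_seeded(config, 10))
        profile = qtl.scan_trait(gmap, bin_matrix, y, params)
        thr = qtl.permutation_threshold(gmap, bin_matrix, y, params)
        thresholds[col] = thr
        trait, _, env = col.partition("__")
        all_qtls.append(
            qtl.call_qtls(profile, thr, params, trait=trait, environment=env or "env1")
        )
    qtls = pd.concat(all_qtls, ignore_index=True)
    regions: list[qtl.HotspotRegion] = []
    if len(qtls):
        _, regions = qtl.topmost_and_hotspots(qtls)
    io.write_qtl_table(qtls, regions, gmap, out / "qtl_results.csv")
    qtls.to_csv(out / "qtl_raw.csv", index=False)
    pd.DataFrame(
        [
            {
                "name": r.name,
                "chrom": r.chrom,
                "left_bin": r.left_bin,
                "right_bin": r.right_bin,
                "start": r.start,
                "end": r.end,
                "size_kb": r.size_kb,
                "traits": ";".join(r.traits),
            }
            for r in regions
        ],
        columns=[
            "name",
            "chrom",
            "left_bin",
            "right_bin",
            "start",
            "end",
            "size_kb",
            "traits",
        ],
    ).to_csv(out / "hotspots.csv", index=False)
    io.write_json({"lod_thresholds": thresholds}, out / "qtl_thresholds.json")
    return {
        "artifacts": [
            "qtl_results.csv",
            "qtl_raw.csv",
            "hotspots.csv",
            "qtl_thresholds.json",
        ]
    }


def _gwas_chromosome(out: Path, matrix) -> str:
    hotspots = pd.read_csv(out / "hotspots.csv", dtype={"chrom": str})
    if len(hotspots):
        return str(hotspots["chrom"].iloc[0])
    return matrix.chromosomes()[0]


def stage_gwas(config: RunConfig, out: Path) -> dict:
    matrix = io.read_genotypes_tsv(
        _require(out / "genotypes_filtered.tsv", "qc", "gwas")
    )
    pheno_path = (
        Path(config.phenotypes_path)
        if config.mode == "real" and config.phenotypes_path
        else _require(out / "phenotypes.csv", "simulate", "gwas")
    )
    phenos = io.read_phenotypes(pheno_path).loc[matrix.lines]
    _require(out / "hotspots.csv", "qtl", "gwas")
    chrom = _gwas_chromosome(out, matrix)
    sub = matrix.subset(site_idx=np.flatnonzero(matrix.site_mask(chrom)))
    params = dataclasses.replace(config.assoc, seed=_seeded(config, 20))
    mta_rows = []
    rmip_tables = []
    for col in phenos.columns:
        y = phenos[col].to_numpy(dtype=float)
        assoc = association.single_marker_association(sub, y)
        mta = association.bonferroni_mtas(assoc["p"].to_numpy(), params.alpha)
        counts = association.rmip(sub, y, params)
        table = assoc[["chrom", "pos", "p"]].copy()
        table["trait"] = col
        table["mta"] = mta
        table["rmip"] = counts
        rmip_tables.append(table)
        mta_rows.append(table[table["mta"]])
    pd.concat(rmip_tables, ignore_index=True).to_csv(out / "rmip.csv", index=False)
    pd.concat(mta_rows, ignore_index=True).to_csv(out / "mta.csv", index=False)
    return {"artifacts": ["rmip.csv", "mta.csv"]}


def stage_enrich(config: RunConfig, out: Path) -> dict:
    matrix = io.read_genotypes_tsv(
        _require(out / "genotypes_filtered.tsv", "qc", "enrich")
    )
    rmip_table = pd.read_csv(
        _require(out / "rmip.csv", "gwas", "enrich"), dtype={"chrom": str}
    )
    hotspots = pd.read_csv(
        _require(out / "hotspots.csv", "qtl", "enrich"), dtype={"chrom": str}
    )
    annotation_path = (
        Path(config.annotation_path)
        if config.mode == "real" and config.annotation_path
        else _require(out / "genes.gff3", "simulate", "enrich")
    )
    annotation = io.read_annotation(annotation_path)
    params = dataclasses.replace(config.assoc, seed=_seeded(config, 30))
    chrom = _gwas_chromosome(out, matrix)
    idx = np.flatnonzero(matrix.site_mask(chrom))
    pos = matrix.sites["pos"].to_numpy()[idx]
    ld_pairs = association.consecutive_ld(matrix, chrom, params.alpha)
    try:
        pad = association.median_complete_ld_distance(
            matrix, chrom, params.alpha, max_pairs=20_000, seed=params.seed
        )
    except ValueError:
        pad = float(np.median(np.diff(pos))) if len(pos) > 1 else 0.0
    candidate_genes = _candidate_genes(hotspots, annotation)
    blocks = []
    for g in candidate_genes.itertuples(index=False):
        start, end, _ = association.ld_block_for_gene(
            g.start, g.end, pos, ld_pairs, fallback_pad=pad
        )
        blocks.append(
            {"gene_id": g.gene_id, "chrom": chrom, "block_start": start, "block_end": end}
        )
    blocks_df = pd.DataFrame(
        blocks, columns=["gene_id", "chrom", "block_start", "block_end"]
    )
    results = []
    for trait, grp in rmip_table.groupby("trait", sort=False):
        on_chrom = grp[grp["chrom"] == chrom]
        counts = on_chrom.set_index("pos").loc[pos, "rmip"].to_numpy()
        if (counts >= params.rmip_min).sum() == 0:
            continue
        enr = association.enrichment_test(blocks_df, pos, counts, params)
        enr["trait"] = trait
        results.append(enr)
    if results:
        enrichment = pd.concat(results, ignore_index=True)
    else:
        enrichment = pd.DataFrame(
            columns=[
                "gene_id",
                "block_start",
                "block_end",
                "n_block_snps",
                "n_block_significant",
                "colocalization_weight",
                "permutation_p",
                "hypergeometric_p",
                "enriched",
                "trait",
            ]
        )
    enrichment.to_csv(out / "enrichment.csv", index=False)
    if len(blocks_df):
        bed = blocks_df.rename(columns={"block_start": "start", "block_end": "end"})
        io.write_bed(bed, out / "blocks.bed", name_col="gene_id")
    else:
        (out / "blocks.bed").write_text("")
    return {"artifacts": ["enrichment.csv", "blocks.bed"]}


def _candidate_genes(hotspots: pd.DataFrame, annotation: GeneAnnotation) -> pd.DataFrame:
    frames = []
    for reg in hotspots.itertuples(index=False):
        region = qtl.HotspotRegion(
            name=reg.name,
            chrom=str(reg.chrom),
            left_bin=reg.left_bin,
            right_bin=reg.right_bin,
            start=int(reg.start),
            end=int(reg.end),
            traits=str(reg.traits).split(";"),
        )
        frames.append(candidates.genes_in_region(region, annotation))
    if not frames:
        return annotation.genes.iloc[0:0]
    return (
        pd.concat(frames, ignore_index=True)
        .drop_duplicates("gene_id")
        .reset_index(drop=True)
    )


def stage_prioritize(config: RunConfig, out: Path) -> dict:
    hotspots = pd.read_csv(
        _require(out / "hotspots.csv", "qtl", "prioritize"), dtype={"chrom": str}
    )
    enrichment = pd.read_csv(_require(out / "enrichment.csv", "enrich", "prioritize"))
    annotation_path = (
        Path(config.annotation_path)
        if config.mode == "real" and config.annotation_path
        else _require(out / "genes.gff3", "simulate", "prioritize")
    )
    annotation = io.read_annotation(annotation_path)
    region_genes = _candidate_genes(hotspots, annotation)
    enriched = (
        sorted(set(enrichment.loc[enrichment["enriched"].astype(bool), "gene_id"]))
        if len(enrichment)
        else []
    )
    result = candidates.prioritize(region_genes, enriched, annotation)
    result.provenance.to_csv(out / "candidates.csv", index=False)
    io.write_json(
        {
            "n_region_genes": len(result.region_genes),
            "n_enriched_genes": len(result.enriched_genes),
            "prioritized": result.prioritized,
        },
        out / "candidates_summary.json",
    )
    return {"artifacts": ["candidates.csv", "candidates_summary.json"]}


STAGES = {
    "simulate": stage_simulate,
    "qc": stage_qc,
    "binmap": stage_binmap,
    "map": stage_map,
    "qtl": stage_qtl,
    "gwas": stage_gwas,
    "enrich": stage_enrich,
    "prioritize": stage_prioritize,
}


def run_pipeline(
    config: RunConfig, stages: list[str] | None = None
) -> dict:
    """Run the requested stages in canonical order; returns the manifest."""
    from importlib.metadata import PackageNotFoundError, version

    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    if stages is None:
        stages = list(STAGES)
        if config.mode == "real":
            stages.remove("simulate")
    try:
        pkg_version = version("skimqtl")
    except PackageNotFoundError:
        pkg_version = "unknown"
    manifest: dict = {
        "package_version": pkg_version,
        "seed": config.seed,
        "parameters": dataclasses.asdict(config),
        "stages": {},
    }
    for name in stages:
        result = STAGES[name](config, out)
        manifest["stages"][name] = {
            "artifacts": {
                art: io.sha256_of(out / art) for art in result["artifacts"]
            }
        }
    io.write_json(manifest, out / "manifest.json")
    return manifest
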