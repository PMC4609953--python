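"""Synthetic RIL populations with known recombination and QTL truth.

The generator emulates the data a skim-sequencing genotyping study of a
biparental recombinant inbred line (RIL) population produces:

* a genome of several chromosomes carrying thousands of biallelic SNPs
  that are fixed for opposite alleles in the two parents;
* RILs built by explicit meioses — an F1 selfed by single-seed descent,
  with per-meiosis crossover counts Poisson-distributed (no interference,
  i.e. the Haldane model) and crossover positions uniform along the
  chromosome;
* skim-coverage observations of the true genotypes: per line and site a
  Poisson read count (zero reads = missing call) and a small per-call
  allele-flip error;
* additive multi-environment quantitative traits driven by planted QTLs
  with a prescribed narrow-sense heritability;
* a non-overlapping gene annotation.

Every operation is deterministic given its seed, and each returns the
ground truth (crossover positions, planted QTL sites, genetic values)
needed to score the downstream pipeline.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import A, B, MISSING, GeneAnnotation, GenotypeMatrix

# Defaults mirror the study conditions the generator emulates: 222 lines
# genotyped at ~0.72X mean depth, advanced to the F8 generation, with
# chromosomes carrying on average four crossovers per RIL (twice the
# per-meiosis rate of 2 after inbreeding map expansion).
DEFAULT_N_LINES = 222
DEFAULT_GENERATION = 8
DEFAULT_MEAN_DEPTH = 0.72
DEFAULT_ERROR_RATE = 0.005
DEFAULT_RECOMB_RATE = 2.0


@dataclass
class Chromosome:
    name: str
    length: int
    snp_positions: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.snp_positions, dtype=np.int64)
        if len(pos) and (np.diff(pos) <= 0).any():
            raise ValueError(f"{self.name}: SNP positions must be strictly increasing")
        if len(pos) and (pos[0] < 1 or pos[-1] > self.length):
            raise ValueError(f"{self.name}: SNP positions outside [1, length]")
        self.snp_positions = pos


@dataclass
class GenomeSpec:
    """Chromosome layout, SNP catalog and per-meiosis crossover rate."""

    chromosomes: list[Chromosome]
    recomb_rate: float = DEFAULT_RECOMB_RATE

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("genome must declare at least one chromosome")
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        if not self.recomb_rate >= 0:
            raise ValueError("recomb_rate must be >= 0")

    @property
    def n_sites(self) -> int:
        return sum(len(c.snp_positions) for c in self.chromosomes)

    def site_table(self) -> pd.DataFrame:
        rows = [
            {"chrom": c.name, "pos": int(p)}
            for c in self.chromosomes
            for p in c.snp_positions
        ]
        return pd.DataFrame(rows, columns=["chrom", "pos"])


def make_genome(
    n_chromosomes: int = 8,
    chrom_length: int = 50_000_000,
    snps_per_chromosome: int = 2_000,
    recomb_rate: float = DEFAULT_RECOMB_RATE,
    seed: int = 0,
) -> GenomeSpec:
    """Random genome with uniformly scattered SNPs (desk-scale stand-in
    for an eight-pseudomolecule genome)."""
    rng = np.random.default_rng(seed)
    chroms = []
    for k in range(n_chromosomes):
        pos = rng.choice(
            np.arange(1, chrom_length + 1), size=snps_per_chromosome, replace=False
        )
        chroms.append(Chromosome(f"Ca{k + 1}", chrom_length, np.sort(pos)))
    return GenomeSpec(chroms, recomb_rate=recomb_rate)


# ---------------------------------------------------------------------------
# parents

def simulate_parents(spec: GenomeSpec, seed: int = 0) -> pd.DataFrame:
    """Site catalog with fixed parental alleles (parent 1 = A, parent 2 = B).

    Parents of a biparental RIL cross are by construction fixed for
    opposite alleles at every informative site, so the catalog is
    deterministic; the seed is accepted for interface uniformity.
    """
    table = spec.site_table()
    if table.empty:
        raise ValueError("genome has no SNP sites")
    table["parent1"] = "A"
    table["parent2"] = "B"
    return table


# ---------------------------------------------------------------------------
# meiosis machinery
#
# A haplotype on one chromosome is a piecewise-constant parental-origin
# function stored as (bounds, origins): `bounds` are the internal
# breakpoints (bp, ascending floats) and `origins[i]` is the origin (0 or
# 1) on the i-th segment, with len(origins) == len(bounds) + 1.

Haplotype = tuple[list[float], list[int]]


def _slice_origins(hap: Haplotype, lo: float, hi: float) -> Haplotype:
    """Origin function of `hap` restricted to [lo, hi): internal bounds
    strictly inside the window plus the covering origins."""
    bounds, origins = hap
    b = [x for x in bounds if lo < x < hi]
    i0 = np.searchsorted(bounds, lo, side="right")
    o = origins[i0 : i0 + len(b) + 1]
    return list(b), list(o)


def _simplify(hap: Haplotype) -> Haplotype:
    bounds, origins = hap
    nb: list[float] = []
    no: list[int] = [origins[0]]
    for x, o in zip(bounds, origins[1:]):
        if o != no[-1]:
            nb.append(x)
            no.append(o)
    return nb, no


def meiosis(
    h1: Haplotype, h2: Haplotype, rate: float, length: int, rng: np.random.Generator
) -> tuple[Haplotype, int]:
    """One gamete from a diploid (h1, h2): Poisson(rate) crossovers placed
    uniformly, no interference.  Returns the gamete and crossover count."""
    n_x = int(rng.poisson(rate))
    start = int(rng.integers(2))
    if n_x == 0:
        return (h1 if start == 0 else h2), 0
    xovers = np.sort(rng.uniform(0.0, float(length), size=n_x))
    haps = (h1, h2)
    cur = start
    bounds: list[float] = []
    origins: list[int] = []
    edges = [0.0, *xovers.tolist(), float(length)]
    for lo, hi in itertools.pairwise(edges):
        b, o = _slice_origins(haps[cur], lo, hi)
        if bounds or origins:
            bounds.append(lo)
        bounds.extend(b)
        origins.extend(o)
        cur = 1 - cur
    return _simplify((bounds, origins)), n_x


def _resolve_mosaic(
    h1: Haplotype, h2: Haplotype, rng: np.random.Generator
) -> Haplotype:
    """Collapse a near-inbred diploid to one exported parental mosaic.

    Homozygous segments keep their origin; each maximal residual
    heterozygous tract is assigned a single fair coin flip, so the
    exported genotype is piecewise constant and exactly consistent with
    its breakpoint list.
    """
    union = sorted(set(h1[0]) | set(h2[0]))
    state: list[int] = []  # 0 = hom A, 1 = hom B, 2 = het
    for lo in [0.0, *union]:
        o1 = h1[1][int(np.searchsorted(h1[0], lo, side="right"))]
        o2 = h2[1][int(np.searchsorted(h2[0], lo, side="right"))]
        state.append(o1 if o1 == o2 else 2)
    resolved = list(state)
    i = 0
    while i < len(resolved):
        if resolved[i] == 2:
            j = i
            while j < len(resolved) and resolved[j] == 2:
                j += 1
            flip = int(rng.integers(2))
            for k in range(i, j):
                resolved[k] = flip
            i = j
        else:
            i += 1
    return _simplify((union, resolved))


@dataclass
class TrueGenotypes:
    """Fully phased truth: parental mosaic per line plus exported calls."""

    matrix: GenotypeMatrix
    breakpoints: dict[str, dict[str, np.ndarray]]  # line -> chrom -> bp positions

    def breakpoint_table(self) -> pd.DataFrame:
        rows = [
            {"line": line, "chrom": chrom, "pos": float(p)}
            for line, per_chrom in self.breakpoints.items()
            for chrom, pos in per_chrom.items()
            for p in pos
        ]
        return pd.DataFrame(rows, columns=["line", "chrom", "pos"])


def simulate_ril(
    spec: GenomeSpec,
    n_lines: int = DEFAULT_N_LINES,
    n_selfing_generations: int = DEFAULT_GENERATION,
    seed: int = 0,
) -> TrueGenotypes:
    """Single-seed-descent RIL population with explicit meioses.

    ``n_selfing_generations`` is the filial generation number (F1 = 1, so
    the default 8 performs seven rounds of selfing and leaves an expected
    residual heterozygosity of (1/2)**7 per locus before resolution).
    """
    if n_lines < 1 or n_selfing_generations < 1:
        raise ValueError("n_lines and n_selfing_generations must be >= 1")
    rng = np.random.default_rng(seed)
    n_rounds = n_selfing_generations - 1
    lines = [f"RIL{i + 1:03d}" for i in range(n_lines)]
    calls = np.empty((n_lines, spec.n_sites), dtype=np.int8)
    breakpoints: dict[str, dict[str, np.ndarray]] = {ln: {} for ln in lines}
    col0 = 0
    for chrom in spec.chromosomes:
        f1: tuple[Haplotype, Haplotype] = (([], [A]), ([], [B]))
        pos = chrom.snp_positions.astype(float)
        for li, line in enumerate(lines):
            individual = f1
            for _ in range(n_rounds):
                if individual[0] == individual[1]:
                    break  # fixed: further selfing cannot change the mosaic
                g1, _ = meiosis(*individual, spec.recomb_rate, chrom.length, rng)
                g2, _ = meiosis(*individual, spec.recomb_rate, chrom.length, rng)
                individual = (g1, g2)
            mosaic = _resolve_mosaic(*individual, rng)
            bounds, origins = mosaic
            seg = np.searchsorted(bounds, pos, side="right")
            calls[li, col0 : col0 + len(pos)] = np.asarray(origins, dtype=np.int8)[seg]
            breakpoints[line][chrom.name] = np.asarray(bounds, dtype=float)
        col0 += len(pos)
    matrix = GenotypeMatrix(sites=spec.site_table(), lines=lines, calls=calls)
    return TrueGenotypes(matrix=matrix, breakpoints=breakpoints)


# ---------------------------------------------------------------------------
# skim-coverage observation model

@dataclass
class SkimModel:
    """Poisson read-depth observation model for skim genotyping."""

    mean_depth: float = DEFAULT_MEAN_DEPTH
    error_rate: float = DEFAULT_ERROR_RATE
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.error_rate < 0.5):
            raise ValueError("error_rate must be in [0, 0.5)")
        if not (np.isfinite(self.mean_depth) and self.mean_depth >= 0):
            raise ValueError("mean_depth must be finite and >= 0")


def simulate_skim(truth: TrueGenotypes, model: SkimModel) -> GenotypeMatrix:
    """Observe true genotypes through Poisson coverage with allele flips.

    A site with zero reads is missing; otherwise the observed call is the
    true allele flipped with probability ``error_rate`` (a consensus-level
    error, applied once per observed site).
    """
    rng = np.random.default_rng(model.seed)
    true_calls = truth.matrix.calls
    depth = rng.poisson(model.mean_depth, size=true_calls.shape)
    flips = rng.random(true_calls.shape) < model.error_rate
    observed = np.where(flips, 1 - true_calls, true_calls).astype(np.int8)
    observed[depth == 0] = MISSING
    return GenotypeMatrix(
        sites=truth.matrix.sites.copy(), lines=list(truth.matrix.lines), calls=observed
    )


# ---------------------------------------------------------------------------
# phenotypes

@dataclass
class TraitModel:
    """One trait: planted additive QTLs and a narrow-sense heritability."""

    name: str
    qtls: list[tuple[str, int, float]]  # (chrom, pos bp, additive effect a)
    h2: float = 0.6

    def __post_init__(self) -> None:
        if not (0 < self.h2 <= 1):
            raise ValueError("h2 must be in (0, 1]")


@dataclass
class QtlSpec:
    traits: list[TraitModel] = field(default_factory=list)
    n_environments: int = 1
    env_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n_environments < 1:
            raise ValueError("n_environments must be >= 1")


@dataclass
class SimulatedPhenotypes:
    """Phenotype table plus the truth needed to score QTL recovery."""

    table: pd.DataFrame  # index = line, columns = trait__envK
    qtl_sites: pd.DataFrame  # trait, chrom, pos, site_pos, effect
    genetic_values: pd.DataFrame  # index = line, one column per trait


def trait_column(trait: str, environment: int) -> str:
    return f"{trait}__env{environment}"


def simulate_phenotypes(
    truth: TrueGenotypes, qtl: QtlSpec, seed: int = 0
) -> SimulatedPhenotypes:
    """Additive QTL phenotypes with heritability-scaled Gaussian noise.

    The genetic value of a line is g = sum(a_i * x_i) with x = +1 for the
    A allele and -1 for B at the catalog site nearest each planted QTL.
    Residual noise is scaled so that Var(g) / Var(y) equals h2 against the
    realized genetic variance; each environment receives an independent
    noise draw plus an environment main effect of s.d. ``env_noise_sd``.
    A trait whose QTL effects are all zero is pure unit-variance noise.
    """
    rng = np.random.default_rng(seed)
    matrix = truth.matrix
    sites = matrix.sites
    columns: dict[str, np.ndarray] = {}
    qtl_rows = []
    gvals: dict[str, np.ndarray] = {}
    for trait in qtl.traits:
        g = np.zeros(matrix.n_lines)
        for chrom, pos, a in trait.qtls:
            on_chrom = np.flatnonzero((sites["chrom"] == chrom).to_numpy())
            if len(on_chrom) == 0:
                raise ValueError(f"QTL chromosome {chrom!r} has no catalog sites")
            site_pos = sites["pos"].to_numpy()[on_chrom]
            nearest = on_chrom[np.argmin(np.abs(site_pos - pos))]
            x = np.where(matrix.calls[:, nearest] == A, 1.0, -1.0)
            g += a * x
            qtl_rows.append(
                {
                    "trait": trait.name,
                    "chrom": chrom,
                    "pos": int(pos),
                    "site_pos": int(sites["pos"].iloc[nearest]),
                    "effect": float(a),
                }
            )
        var_g = float(np.var(g))
        if var_g > 0:
            noise_sd = float(np.sqrt(var_g * (1 - trait.h2) / trait.h2))
        else:
            noise_sd = 1.0
        gvals[trait.name] = g
        for env in range(1, qtl.n_environments + 1):
            env_shift = rng.normal(0.0, qtl.env_noise_sd) if qtl.env_noise_sd else 0.0
            noise = rng.normal(0.0, noise_sd, size=len(g)) if noise_sd else 0.0
            columns[trait_column(trait.name, env)] = g + env_shift + noise
    table = pd.DataFrame(columns, index=pd.Index(matrix.lines, name="line"))
    return SimulatedPhenotypes(
        table=table,
        qtl_sites=pd.DataFrame(
            qtl_rows, columns=["trait", "chrom", "pos", "site_pos", "effect"]
        ),
        genetic_values=pd.DataFrame(gvals, index=table.index),
    )


# ---------------------------------------------------------------------------
# gene annotation

def simulate_genes(
    spec: GenomeSpec,
    n_genes: int,
    mean_length: int = 3_000,
    seed: int = 0,
    max_retries: int = 1_000,
) -> GeneAnnotation:
    """Non-overlapping gene models with geometric lengths, placed uniformly.

    Genes are apportioned to chromosomes proportionally to length; if a
    non-overlapping placement cannot be found within ``max_retries``
    resampling rounds per chromosome, an error is raised.
    """
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    rng = np.random.default_rng(seed)
    if n_genes == 0:
        return GeneAnnotation()
    total_len = sum(c.length for c in spec.chromosomes)
    counts = [round(n_genes * c.length / total_len) for c in spec.chromosomes]
    counts[0] += n_genes - sum(counts)
    rows = []
    gene_no = 0
    for chrom, count in zip(spec.chromosomes, counts):
        if count <= 0:
            continue
        for _ in range(max_retries):
            lengths = rng.geometric(1.0 / mean_length, size=count)
            starts = np.sort(rng.integers(1, chrom.length + 1, size=count))
            ends = starts + lengths - 1
            if ends[-1] <= chrom.length and (starts[1:] > ends[:-1]).all():
                break
        else:
            raise RuntimeError(
                f"could not place {count} non-overlapping genes on {chrom.name}"
            )
        for s, e in zip(starts, ends):
            gene_no += 1
            rows.append(
                {
                    "gene_id": f"gene_{gene_no:05d}",
                    "chrom": chrom.name,
                    "start": int(s),
                    "end": int(e),
                    "strand": "+" if rng.integers(2) else "-",
                }
            )
    return GeneAnnotation(pd.DataFrame(rows))
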