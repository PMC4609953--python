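"""Single-marker association, RMIP stability, LD blocks and enrichment.

Marker-trait associations (MTAs) come from a per-SNP two-sided test of
the phenotype difference between the two parental genotype classes
(simple linear regression on +/-1 coding, equivalent to an equal-variance
two-sample t-test) with a Bonferroni cutoff over the SNPs tested for the
trait.  Association stability is summarized by the resample model
inclusion probability (RMIP): the analysis is repeated on seeded random
subsets of the lines and a SNP's RMIP is the number of subsets in which
it is re-declared an MTA; SNPs with RMIP >= 5 of 100 form the
significant-association set.

Local linkage blocks around candidate genes use Lewontin's scaled D':
D = pAB - pA*pB normalized by its frequency-constrained maximum, with
pair significance from a 2x2 chi-square.  A gene's block is the maximal
run of consecutive SNPs in significant LD that contains the gene; genes
in SNP-poor regions fall back to the gene span padded by the median
distance between fully dependent (D' = 1) SNP pairs on the chromosome.

Gene enrichment scores the GWAS signal co-localizing with each gene's
block: a weight summing RMIP/n_resamples over significant SNPs in the
block, an upper-tail hypergeometric test on the significant-SNP count,
and a permutation null of 10,000 random association sets of the true
size drawn without replacement from the chromosome's SNPs.  A gene is
enriched when both tests pass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import A, B, MISSING, GenotypeMatrix


@dataclass
class AssocParams:
    alpha: float = 0.05
    n_resamples: int = 100
    resample_fraction: float = 0.8
    rmip_min: int = 5
    n_enrich_permutations: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.resample_fraction < 1):
            raise ValueError("resample_fraction must be in (0, 1)")
        if self.rmip_min > self.n_resamples:
            raise ValueError("rmip_min cannot exceed n_resamples")


# ---------------------------------------------------------------------------
# association

def single_marker_association(
    matrix: GenotypeMatrix, phenotype: np.ndarray
) -> pd.DataFrame:
    """Per-SNP two-sided p-values for the A-vs-B phenotype contrast.

    Missing genotypes are dropped per SNP; a SNP monomorphic after drops
    gets p = 1 and is flagged.  Vectorized equal-variance t-test.
    """
    y = np.asarray(phenotype, dtype=float)
    calls = matrix.calls
    is_a = calls == A
    is_b = calls == B
    n_a = is_a.sum(axis=0).astype(float)
    n_b = is_b.sum(axis=0).astype(float)
    sum_a = (is_a * y[:, None]).sum(axis=0)
    sum_b = (is_b * y[:, None]).sum(axis=0)
    sumsq_a = (is_a * (y**2)[:, None]).sum(axis=0)
    sumsq_b = (is_b * (y**2)[:, None]).sum(axis=0)
    ok = (n_a >= 1) & (n_b >= 1) & (n_a + n_b >= 3)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_a = sum_a / n_a
        mean_b = sum_b / n_b
        ss_a = sumsq_a - n_a * mean_a**2
        ss_b = sumsq_b - n_b * mean_b**2
        dof = n_a + n_b - 2
        pooled = (ss_a + ss_b) / dof
        se = np.sqrt(pooled * (1 / n_a + 1 / n_b))
        tval = (mean_a - mean_b) / se
        pval = 2 * stats.t.sf(np.abs(tval), dof)
    pval = np.where(ok & np.isfinite(pval), pval, 1.0)
    out = matrix.sites.copy()
    out["n_a"] = n_a.astype(int)
    out["n_b"] = n_b.astype(int)
    out["p"] = pval
    out["monomorphic"] = ~ok
    return out


def bonferroni_mtas(pvals: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Boolean MTA mask: p <= alpha / m over the m tests supplied.

    The correction is per trait, over the SNPs tested for that trait; a
    p-value exactly at the cutoff is included.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    return p <= alpha / p.size


def rmip(
    matrix: GenotypeMatrix, phenotype: np.ndarray, params: AssocParams | None = None
) -> np.ndarray:
    """Resample model inclusion probability per SNP (0..n_resamples).

    Draws ``n_resamples`` seeded subsets of floor(resample_fraction * n)
    lines without replacement, reruns association + Bonferroni on each,
    and counts how often each SNP is an MTA.
    """
    params = params or AssocParams()
    y = np.asarray(phenotype, dtype=float)
    n = matrix.n_lines
    size = int(np.floor(params.resample_fraction * n))
    if size < 30:
        raise ValueError("resample size below 30 lines")
    rng = np.random.default_rng(params.seed)
    counts = np.zeros(matrix.n_sites, dtype=int)
    for _ in range(params.n_resamples):
        pick = rng.choice(n, size=size, replace=False)
        sub = matrix.subset(line_idx=pick)
        assoc = single_marker_association(sub, y[pick])
        counts += bonferroni_mtas(assoc["p"].to_numpy(), params.alpha)
    return counts


# ---------------------------------------------------------------------------
# linkage disequilibrium

@dataclass
class LdEstimate:
    D: float
    Dmax: float
    Dprime: float
    significant: bool
    n: int


def lewontin_dprime(
    calls_i: np.ndarray,
    calls_j: np.ndarray,
    alpha: float = 0.05,
    min_scorable: int = 20,
) -> LdEstimate:
    """Lewontin's scaled D' between two loci on RIL haplotype-like lines.

    D = pAB - pA*pB; Dmax = min(pA(1-pB), (1-pA)pB) for D > 0 else
    min(pA*pB, (1-pA)(1-pB)); D' = D / Dmax.  Significance is a 2x2
    chi-square without continuity correction at ``alpha``.
    """
    both = (calls_i != MISSING) & (calls_j != MISSING)
    n = int(both.sum())
    if n < min_scorable:
        raise ValueError(f"only {n} scorable lines (< {min_scorable})")
    gi = calls_i[both]
    gj = calls_j[both]
    p_a = float((gi == A).mean())
    p_b = float((gj == A).mean())
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise ValueError("monomorphic locus: D' undefined")
    p_ab = float(((gi == A) & (gj == A)).mean())
    d = p_ab - p_a * p_b
    if d > 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    elif d < 0:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    else:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    d_prime = d / d_max if d_max > 0 else 0.0
    chi2 = n * d**2 / (p_a * (1 - p_a) * p_b * (1 - p_b))
    significant = bool(stats.chi2.sf(chi2, df=1) <= alpha)
    return LdEstimate(D=d, Dmax=d_max, Dprime=d_prime, significant=significant, n=n)


def consecutive_ld(
    matrix: GenotypeMatrix, chrom: str, alpha: float = 0.05, min_scorable: int = 20
) -> pd.DataFrame:
    """LD between consecutive SNPs along one chromosome."""
    mask = matrix.site_mask(chrom)
    idx = np.flatnonzero(mask)
    pos = matrix.sites["pos"].to_numpy()[idx]
    rows = []
    for k in range(len(idx) - 1):
        try:
            est = lewontin_dprime(
                matrix.calls[:, idx[k]],
                matrix.calls[:, idx[k + 1]],
                alpha=alpha,
                min_scorable=min_scorable,
            )
            rows.append(
                {
                    "pos_i": pos[k],
                    "pos_j": pos[k + 1],
                    "Dprime": est.Dprime,
                    "significant": est.significant,
                }
            )
        except ValueError:
            rows.append(
                {
                    "pos_i": pos[k],
                    "pos_j": pos[k + 1],
                    "Dprime": np.nan,
                    "significant": False,
                }
            )
    return pd.DataFrame(rows, columns=["pos_i", "pos_j", "Dprime", "significant"])


def median_complete_ld_distance(
    matrix: GenotypeMatrix,
    chrom: str,
    alpha: float = 0.05,
    min_scorable: int = 20,
    max_pairs: int = 200_000,
    seed: int = 0,
) -> float:
    """Median physical distance between same-chromosome SNP pairs in
    complete dependency (|D'| = 1 and significant).

    For large catalogs a seeded random sample of pairs is used.
    """
    idx = np.flatnonzero(matrix.site_mask(chrom))
    pos = matrix.sites["pos"].to_numpy()[idx]
    k = len(idx)
    if k < 2:
        raise ValueError("chromosome has fewer than 2 SNPs")
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    if len(pairs) > max_pairs:
        rng = np.random.default_rng(seed)
        pick = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[p] for p in pick]
    dists = []
    for i, j in pairs:
        try:
            est = lewontin_dprime(
                matrix.calls[:, idx[i]],
                matrix.calls[:, idx[j]],
                alpha=alpha,
                min_scorable=min_scorable,
            )
        except ValueError:
            continue
        if est.significant and abs(abs(est.Dprime) - 1.0) < 1e-9:
            dists.append(abs(int(pos[j]) - int(pos[i])))
    if not dists:
        raise ValueError("no fully dependent SNP pairs found")
    return float(np.median(dists))


def ld_block_for_gene(
    gene_start: int,
    gene_end: int,
    snp_positions: np.ndarray,
    ld_pairs: pd.DataFrame,
    fallback_pad: float | None = None,
) -> tuple[int, int, np.ndarray]:
    """Local linkage block containing a gene.

    The block is the maximal run of consecutive SNPs, each adjacent pair
    in significant LD, whose span contains the gene.  If no SNP lies
    within the gene or one inter-SNP gap of it, the block falls back to
    the gene span padded by ``fallback_pad`` (the median complete-LD
    distance).  Returns (start, end, indices of member SNPs).
    """
    pos = np.asarray(snp_positions)
    if len(pos) == 0:
        if fallback_pad is None:
            raise ValueError("no SNPs and no fallback pad")
        lo = max(1, int(gene_start - fallback_pad))
        return lo, int(gene_end + fallback_pad), np.array([], dtype=int)
    gaps = np.diff(pos)
    near_gap = float(np.median(gaps)) if len(gaps) else 0.0
    near = (pos >= gene_start - near_gap) & (pos <= gene_end + near_gap)
    if not near.any():
        if fallback_pad is None:
            raise ValueError("gene in SNP desert and no fallback pad supplied")
        lo = max(1, int(gene_start - fallback_pad))
        return lo, int(gene_end + fallback_pad), np.array([], dtype=int)
    sig = ld_pairs["significant"].to_numpy() if len(ld_pairs) else np.array([], bool)
    anchor = int(np.flatnonzero(near)[np.argmin(np.abs(pos[near] - 0.5 * (gene_start + gene_end)))])
    lo_i = anchor
    while lo_i > 0 and lo_i - 1 < len(sig) and sig[lo_i - 1]:
        lo_i -= 1
    hi_i = anchor
    while hi_i < len(pos) - 1 and hi_i < len(sig) and sig[hi_i]:
        hi_i += 1
    members = np.arange(lo_i, hi_i + 1)
    start = int(min(pos[lo_i], gene_start))
    end = int(max(pos[hi_i], gene_end))
    return start, end, members


# ---------------------------------------------------------------------------
# enrichment

@dataclass
class EnrichmentResult:
    gene_id: str
    block_start: int
    block_end: int
    n_block_snps: int
    n_block_significant: int
    colocalization_weight: float
    permutation_p: float
    hypergeometric_p: float
    enriched: bool


def hypergeometric_tail(n_pop: int, n_sig: int, n_block: int, k: int) -> float:
    """Upper-tail P(X >= k) drawing n_block from a population of n_pop
    containing n_sig significant SNPs."""
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, n_pop, n_sig, n_block))


def enrichment_test(
    gene_blocks: pd.DataFrame,
    snp_positions: np.ndarray,
    rmip_counts: np.ndarray,
    params: AssocParams | None = None,
) -> pd.DataFrame:
    """Co-localization enrichment per gene on one chromosome.

    ``gene_blocks`` needs columns gene_id, block_start, block_end.
    ``rmip_counts`` aligns with ``snp_positions`` (the chromosome SNP
    catalog); SNPs with RMIP >= rmip_min are the significant set.  The
    permutation null redraws the significant-SNP identities (carrying
    their RMIP weights) uniformly without replacement from the
    chromosome ``n_enrich_permutations`` times.
    """
    params = params or AssocParams()
    pos = np.asarray(snp_positions)
    rmip_counts = np.asarray(rmip_counts)
    sig_mask = rmip_counts >= params.rmip_min
    n_pop = len(pos)
    n_sig = int(sig_mask.sum())
    if n_sig == 0:
        raise ValueError("no significant SNPs on the chromosome")
    sig_weights = rmip_counts[sig_mask] / params.n_resamples
    sig_pos = pos[sig_mask]
    rng = np.random.default_rng(params.seed)
    perm_idx = np.empty((params.n_enrich_permutations, n_sig), dtype=int)
    for b in range(params.n_enrich_permutations):
        perm_idx[b] = rng.choice(n_pop, size=n_sig, replace=False)
    results = []
    for row in gene_blocks.itertuples(index=False):
        lo, hi = int(row.block_start), int(row.block_end)
        in_block = (pos >= lo) & (pos <= hi)
        n_block = int(in_block.sum())
        if n_block == 0:
            results.append(
                EnrichmentResult(row.gene_id, lo, hi, 0, 0, 0.0, 1.0, 1.0, False)
            )
            continue
        sig_in = (sig_pos >= lo) & (sig_pos <= hi)
        k = int(sig_in.sum())
        weight = float(sig_weights[sig_in].sum())
        hyper_p = hypergeometric_tail(n_pop, n_sig, n_block, k)
        perm_in_block = in_block[perm_idx]  # (n_perm, n_sig) membership
        perm_weights = (perm_in_block * sig_weights[None, :]).sum(axis=1)
        perm_p = float((perm_weights >= weight - 1e-12).mean())
        enriched = bool(hyper_p <= params.alpha and perm_p <= params.alpha)
        results.append(
            EnrichmentResult(
                gene_id=row.gene_id,
                block_start=lo,
                block_end=hi,
                n_block_snps=n_block,
                n_block_significant=k,
                colocalization_weight=weight,
                permutation_p=perm_p,
                hypergeometric_p=hyper_p,
                enriched=enriched,
            )
        )
    return pd.DataFrame([r.__dict__ for r in results])
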