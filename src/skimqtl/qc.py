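"""Parent-coded allele encoding and site/line filtering.

SNP calls are scored against the two parents of the cross: a call equal
to the first parent's allele becomes ``A``, equal to the second parent's
becomes ``B``, and anything else (heterozygous call, third allele, no
call) becomes missing.  Sites where the parents agree, or where either
parent is missing, carry no mapping information and are dropped.

Filtering applies the study thresholds: sites with minor allele
frequency below 0.20 are removed (a site at exactly 0.20 is kept), then
lines with 5% or more missing calls are removed (a line at exactly 5% is
dropped).  MAF is computed over non-missing calls only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import A, B, MISSING, GenotypeMatrix


@dataclass
class EncodeReport:
    n_input_sites: int = 0
    n_uninformative_dropped: int = 0  # parents agree or missing
    n_nonparental_calls: int = 0  # het / third-allele calls set to missing


def encode_alleles(
    site_table: pd.DataFrame,
    line_ids: list[str],
    line_alleles: np.ndarray,
    parent1_alleles: np.ndarray,
    parent2_alleles: np.ndarray,
) -> tuple[GenotypeMatrix, EncodeReport]:
    """Score raw allele calls as A/B against the parental alleles.

    Parameters
    ----------
    site_table : DataFrame with chrom, pos per input site.
    line_alleles : array (n_lines, n_sites) of single-character allele
        calls; "" or "." or "N" mean no call.
    parent1_alleles, parent2_alleles : per-site parental alleles.
    """
    p1 = np.asarray(parent1_alleles, dtype="<U1")
    p2 = np.asarray(parent2_alleles, dtype="<U1")
    raw = np.asarray(line_alleles, dtype="<U1")
    no_call = np.isin(p1, ("", ".", "N")) | np.isin(p2, ("", ".", "N"))
    informative = (p1 != p2) & ~no_call
    report = EncodeReport(
        n_input_sites=len(site_table),
        n_uninformative_dropped=int((~informative).sum()),
    )
    if not informative.any():
        raise ValueError("no informative sites: parents agree or are missing everywhere")
    raw = raw[:, informative]
    p1, p2 = p1[informative], p2[informative]
    calls = np.full(raw.shape, MISSING, dtype=np.int8)
    calls[raw == p1[None, :]] = A
    calls[raw == p2[None, :]] = B
    has_call = ~np.isin(raw, ("", ".", "N"))
    report.n_nonparental_calls = int((has_call & (calls == MISSING)).sum())
    matrix = GenotypeMatrix(
        sites=site_table.loc[informative, ["chrom", "pos"]],
        lines=list(line_ids),
        calls=calls,
    )
    return matrix, report


def site_stats(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-site minor allele frequency and call rate.

    MAF is min(fA, fB) over non-missing calls; a site with zero
    non-missing calls gets NaN MAF and is flagged for removal.
    """
    if matrix.n_sites == 0:
        raise ValueError("empty genotype matrix")
    calls = matrix.calls
    n_a = (calls == A).sum(axis=0)
    n_b = (calls == B).sum(axis=0)
    n_called = n_a + n_b
    with np.errstate(invalid="ignore"):
        maf = np.where(
            n_called > 0, np.minimum(n_a, n_b) / np.maximum(n_called, 1), np.nan
        )
    out = matrix.sites.copy()
    out["n_called"] = n_called
    out["maf"] = maf
    out["call_rate"] = n_called / matrix.n_lines
    out["remove"] = n_called == 0
    return out


@dataclass
class FilterReport:
    maf_min: float
    line_missing_max: float
    removed_sites: pd.DataFrame = field(default_factory=pd.DataFrame)
    removed_lines: list[str] = field(default_factory=list)

    @property
    def n_removed_sites(self) -> int:
        return len(self.removed_sites)

    @property
    def n_removed_lines(self) -> int:
        return len(self.removed_lines)


def apply_filters(
    matrix: GenotypeMatrix,
    maf_min: float = 0.20,
    line_missing_max: float = 0.05,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Drop low-MAF sites, then high-missingness lines.

    Boundary semantics follow the study's wording: a site with
    MAF >= ``maf_min`` is kept, a line with missing fraction
    >= ``line_missing_max`` is dropped.  MAF is computed once, before
    line removal, so the report is reproducible.
    """
    if not (0 < maf_min <= 0.5) or not (0 < line_missing_max < 1):
        raise ValueError("thresholds out of range")
    stats = site_stats(matrix)
    keep_sites = ((stats["maf"] >= maf_min) & ~stats["remove"]).to_numpy()
    report = FilterReport(maf_min=maf_min, line_missing_max=line_missing_max)
    report.removed_sites = stats.loc[~keep_sites, ["chrom", "pos", "maf"]].reset_index(
        drop=True
    )
    if not keep_sites.any():
        raise ValueError("all sites removed by MAF filter")
    trimmed = matrix.subset(site_idx=np.flatnonzero(keep_sites))
    missing_frac = (trimmed.calls == MISSING).mean(axis=1)
    keep_lines = missing_frac < line_missing_max
    report.removed_lines = [
        ln for ln, keep in zip(trimmed.lines, keep_lines) if not keep
    ]
    if not keep_lines.any():
        raise ValueError("all lines removed by missingness filter")
    filtered = trimmed.subset(line_idx=np.flatnonzero(keep_lines))
    return filtered, report
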