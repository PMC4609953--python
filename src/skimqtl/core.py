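"""Shared containers for genotype data, genomes and gene annotations.

Allele coding follows the biparental RIL convention: every SNP call is
scored against the two parents, ``A`` for the first parent's allele and
``B`` for the second parent's; anything else (heterozygous, third allele,
no reads) is missing.  Internally calls are stored as an int8 matrix with
``A = 0``, ``B = 1`` and ``MISSING = -1``; lines are rows, sites columns.

All genomic coordinates in in-memory tables are 1-based inclusive.  The
only place 0-based half-open coordinates appear is the BED writer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

A: int = 0
B: int = 1
MISSING: int = -1

_CODE_TO_CHAR = {A: "A", B: "B", MISSING: "-"}
_CHAR_TO_CODE = {"A": A, "B": B, "-": MISSING, ".": MISSING, "": MISSING}


def calls_to_characters(calls: np.ndarray) -> np.ndarray:
    """Map an int8 call matrix to the {A, B, -} character alphabet."""
    out = np.full(calls.shape, "-", dtype="<U1")
    out[calls == A] = "A"
    out[calls == B] = "B"
    return out


def characters_to_calls(chars: np.ndarray) -> np.ndarray:
    """Inverse of :func:`calls_to_characters`; unknown symbols become missing."""
    arr = np.asarray(chars, dtype="<U1")
    out = np.full(arr.shape, MISSING, dtype=np.int8)
    out[arr == "A"] = A
    out[arr == "B"] = B
    return out


@dataclass
class GenotypeMatrix:
    """Parent-coded SNP calls for a RIL population.

    Parameters
    ----------
    sites : pandas.DataFrame
        One row per SNP with columns ``chrom`` and ``pos`` (1-based),
        sorted by (chrom, pos) with no duplicates.
    lines : list of str
        Line identifiers, one per matrix row.
    calls : numpy.ndarray of int8, shape (n_lines, n_sites)
        Values in {A, B, MISSING}.
    """

    sites: pd.DataFrame
    lines: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.validate()

    def validate(self) -> None:
        if self.calls.shape != (len(self.lines), len(self.sites)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.lines)} lines x {len(self.sites)} sites"
            )
        if not {"chrom", "pos"}.issubset(self.sites.columns):
            raise ValueError("sites must have 'chrom' and 'pos' columns")
        if self.sites.duplicated(["chrom", "pos"]).any():
            raise ValueError("duplicate (chrom, pos) in site table")
        for _, grp in self.sites.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise ValueError("site positions must be sorted within chromosome")
        bad = ~np.isin(self.calls, (A, B, MISSING))
        if bad.any():
            raise ValueError("calls must be in {A, B, MISSING}")

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.sites["chrom"]))

    def site_mask(self, chrom: str) -> np.ndarray:
        return (self.sites["chrom"] == chrom).to_numpy()

    def subset(
        self,
        line_idx: np.ndarray | list[int] | None = None,
        site_idx: np.ndarray | list[int] | None = None,
    ) -> "GenotypeMatrix":
        line_idx = np.arange(self.n_lines) if line_idx is None else np.asarray(line_idx)
        site_idx = np.arange(self.n_sites) if site_idx is None else np.asarray(site_idx)
        return GenotypeMatrix(
            sites=self.sites.iloc[site_idx],
            lines=[self.lines[i] for i in line_idx],
            calls=self.calls[np.ix_(line_idx, site_idx)],
        )

    def to_frame(self) -> pd.DataFrame:
        """Sites-as-rows TSV layout: chrom, pos, one {A,B,-} column per line."""
        out = self.sites.copy()
        chars = calls_to_characters(self.calls)
        for i, line in enumerate(self.lines):
            out[line] = chars[i]
        return out

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GenotypeMatrix":
        lines = [c for c in frame.columns if c not in ("chrom", "pos")]
        calls = characters_to_calls(frame[lines].to_numpy(dtype="<U1").T)
        return cls(sites=frame[["chrom", "pos"]], lines=list(lines), calls=calls)


@dataclass
class GeneAnnotation:
    """Gene models as 1-based inclusive intervals.

    ``genes`` has columns ``gene_id``, ``chrom``, ``start``, ``end``,
    ``strand``; rows are sorted by (chrom, start).
    """

    genes: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["gene_id", "chrom", "start", "end", "strand"]
        )
    )

    def __post_init__(self) -> None:
        g = self.genes.reset_index(drop=True)
        if len(g) and (g["start"] > g["end"]).any():
            raise ValueError("gene start must be <= end")
        if len(g):
            g = g.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
        self.genes = g

    def __len__(self) -> int:
        return len(self.genes)

    def on_chromosome(self, chrom: str) -> pd.DataFrame:
        return self.genes[self.genes["chrom"] == chrom]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, as printed summary tables expect."""
    factor = 10.0**ndigits
    return float(np.floor(abs(x) * factor + 0.5) / factor) * (1.0 if x >= 0 else -1.0)
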