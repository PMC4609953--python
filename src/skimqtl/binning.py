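"""Sliding-window genotype calling, breakpoint placement and consensus bins.

A 15-SNP window slides one SNP at a time over each line's non-missing
calls.  A window with at least nine alleles from one parent is called
homozygous for that parent; anything less decisive is unresolved.  A
recombination breakpoint is declared at every transition between
resolved runs of opposite genotype, located as an interval between the
flanking runs with its point estimate at the interval midpoint —
unresolved windows never create breakpoints, they only widen intervals.

Population-wide consensus bins are built on a 100 kb grid anchored at
coordinate 1: a grid cell is "hit" if any line's breakpoint point
estimate falls inside it; each hit cell is a bin boundary and maximal
runs of unhit cells merge into single bins.  The bins inherit as a unit
and serve as markers for linkage mapping.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import A, B, MISSING, GeneAnnotation, GenotypeMatrix

UNRESOLVED: int = 2


@dataclass
class BinningParams:
    window_snps: int = 15
    homozygous_min: int = 9
    grid_bp: int = 100_000
    # resolved runs of at most this many windows are treated as noise and
    # collapsed (shortest-explanation rule for double transitions)
    collapse_max_windows: int = 1

    def __post_init__(self) -> None:
        if self.homozygous_min > self.window_snps:
            raise ValueError("homozygous_min cannot exceed window_snps")
        if self.grid_bp <= 0:
            raise ValueError("grid_bp must be positive")


@dataclass
class Breakpoint:
    lo: float
    hi: float

    @property
    def point(self) -> float:
        return 0.5 * (self.lo + self.hi)


@dataclass
class SegmentCall:
    """One line's resolved parental segments on one chromosome."""

    chrom: str
    segments: list[tuple[int, float, float]]  # (genotype, start, end)
    breakpoints: list[Breakpoint]


def window_genotypes(
    positions: np.ndarray, calls: np.ndarray, params: BinningParams
) -> pd.DataFrame:
    """Window calls for one line on one chromosome.

    Windows are built over the line's non-missing calls only (skim data
    is mostly missing) and advance one SNP at a time; each row carries
    the genomic coordinates of the window's first and last SNP.
    """
    keep = calls != MISSING
    pos = np.asarray(positions)[keep]
    vals = calls[keep]
    w = params.window_snps
    if len(vals) < w:
        warnings.warn(
            f"fewer than {w} non-missing calls; chromosome left unresolved",
            stacklevel=2,
        )
        return pd.DataFrame(columns=["first_pos", "last_pos", "n_a", "call"])
    is_a = (vals == A).astype(np.int64)
    n_a = np.convolve(is_a, np.ones(w, dtype=np.int64), mode="valid")
    call = np.full(len(n_a), UNRESOLVED, dtype=np.int8)
    call[n_a >= params.homozygous_min] = A
    call[(w - n_a) >= params.homozygous_min] = B
    return pd.DataFrame(
        {
            "first_pos": pos[: len(n_a)],
            "last_pos": pos[w - 1 :],
            "n_a": n_a,
            "call": call,
        }
    )


def _window_runs(call: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal runs of identically-called resolved windows as
    (call, first window index, last window index); unresolved windows are
    gaps."""
    runs: list[tuple[int, int, int]] = []
    for i, c in enumerate(call):
        if c == UNRESOLVED:
            continue
        if runs and runs[-1][0] == c and _gap_unresolved(call, runs[-1][2], i):
            runs[-1] = (c, runs[-1][1], i)
        else:
            runs.append((int(c), i, i))
    return runs


def _gap_unresolved(call: np.ndarray, last: int, nxt: int) -> bool:
    return bool((call[last + 1 : nxt] == UNRESOLVED).all())


def _collapse_runs(
    runs: list[tuple[int, int, int]], max_windows: int
) -> list[tuple[int, int, int]]:
    """Shortest-explanation collapse of double transitions: an interior
    run of at most ``max_windows`` windows flanked by runs of the
    opposite genotype is a blip — removing it trades two transitions for
    none.  Terminal runs are never removed."""
    runs = list(runs)
    changed = True
    while changed:
        changed = False
        for k in range(1, len(runs) - 1):
            if runs[k][2] - runs[k][1] + 1 <= max_windows:
                del runs[k]
                merged: list[tuple[int, int, int]] = []
                for r in runs:
                    if merged and merged[-1][0] == r[0]:
                        merged[-1] = (r[0], merged[-1][1], r[2])
                    else:
                        merged.append(r)
                runs = merged
                changed = True
                break
    return runs


def detect_breakpoints(
    windows: pd.DataFrame, params: BinningParams, chrom: str = "", length: float | None = None
) -> SegmentCall:
    """Breakpoints and resolved segments from one line's window calls.

    Each A-B transition between consecutive resolved runs yields one
    breakpoint whose interval spans from the end of the left run to the
    start of the right run (sorted, since majority-called windows can
    overhang the true crossover).  Resolved segments cover the span
    outside breakpoint intervals; genotype inside an interval is unknown.
    """
    if windows.empty:
        warnings.warn("no resolved windows; no breakpoints called", stacklevel=2)
        return SegmentCall(chrom=chrom, segments=[], breakpoints=[])
    call = windows["call"].to_numpy()
    first = windows["first_pos"].to_numpy(dtype=float)
    last = windows["last_pos"].to_numpy(dtype=float)
    runs = _collapse_runs(_window_runs(call), params.collapse_max_windows)
    if not runs:
        warnings.warn("no resolved windows; no breakpoints called", stacklevel=2)
        return SegmentCall(chrom=chrom, segments=[], breakpoints=[])
    breakpoints: list[Breakpoint] = []
    for (g_l, _, i_l), (g_r, j_r, _) in zip(runs, runs[1:]):
        assert g_l != g_r
        lo, hi = sorted((last[i_l], first[j_r]))
        breakpoints.append(Breakpoint(lo=lo, hi=hi))
    span_lo = 1.0
    span_hi = float(length) if length is not None else float(last[-1])
    segments: list[tuple[int, float, float]] = []
    cursor = span_lo
    for run, bp in zip(runs, breakpoints + [None]):
        end = bp.lo if bp is not None else span_hi
        segments.append((run[0], cursor, end))
        if bp is not None:
            cursor = bp.hi
    return SegmentCall(chrom=chrom, segments=segments, breakpoints=breakpoints)


def call_segments(
    matrix: GenotypeMatrix,
    params: BinningParams | None = None,
    chrom_lengths: dict[str, int] | None = None,
) -> dict[str, dict[str, SegmentCall]]:
    """Window-call every line on every chromosome: line -> chrom -> SegmentCall."""
    params = params or BinningParams()
    out: dict[str, dict[str, SegmentCall]] = {ln: {} for ln in matrix.lines}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for chrom in matrix.chromosomes():
            mask = matrix.site_mask(chrom)
            positions = matrix.sites["pos"].to_numpy()[mask]
            length = chrom_lengths.get(chrom) if chrom_lengths else None
            for li, line in enumerate(matrix.lines):
                win = window_genotypes(positions, matrix.calls[li, mask], params)
                out[line][chrom] = detect_breakpoints(
                    win, params, chrom=chrom, length=length
                )
    return out


# ---------------------------------------------------------------------------
# consensus bins

def chromosome_number(chrom: str) -> str:
    m = re.search(r"(\d+)$", chrom)
    return m.group(1) if m else chrom


def consensus_bins(
    segment_calls: dict[str, dict[str, SegmentCall]],
    matrix: GenotypeMatrix,
    params: BinningParams | None = None,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Population-consensus recombination bins on the 100 kb grid.

    Returns a table with bin_id, chrom, start, end, n_snps; bins tile
    each chromosome's span with no overlap, and a bin containing no SNP
    is flagged (it cannot be genotyped).
    """
    params = params or BinningParams()
    if len(segment_calls) < 2:
        raise ValueError("consensus bins require breakpoints from >= 2 lines")
    rows = []
    for chrom in matrix.chromosomes():
        mask = matrix.site_mask(chrom)
        snp_pos = matrix.sites["pos"].to_numpy()[mask]
        length = (
            chrom_lengths.get(chrom)
            if chrom_lengths
            else int(snp_pos[-1]) if len(snp_pos) else params.grid_bp
        )
        n_cells = int(np.ceil(length / params.grid_bp))
        hit = np.zeros(n_cells, dtype=bool)
        for per_chrom in segment_calls.values():
            seg = per_chrom.get(chrom)
            if seg is None:
                continue
            for bp in seg.breakpoints:
                cell = int((bp.point - 1) // params.grid_bp)
                hit[min(max(cell, 0), n_cells - 1)] = True
        # partition cells: every hit cell is a bin; unhit runs merge
        bounds = [0]
        c = 0
        while c < n_cells:
            if hit[c]:
                bounds.append(c + 1)
                c += 1
            else:
                j = c
                while j < n_cells and not hit[j]:
                    j += 1
                bounds.append(j)
                c = j
        for lo_cell, hi_cell in zip(bounds, bounds[1:]):
            start = lo_cell * params.grid_bp + 1
            end = min(hi_cell * params.grid_bp, length)
            n_snps = int(
                np.searchsorted(snp_pos, end, side="right")
                - np.searchsorted(snp_pos, start, side="left")
            )
            rows.append(
                {
                    "bin_id": f"bin_{chromosome_number(chrom)}_{start}",
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "n_snps": n_snps,
                    "no_snp": n_snps == 0,
                }
            )
    bins = pd.DataFrame(rows)
    _assert_tiling(bins)
    return bins


def _assert_tiling(bins: pd.DataFrame) -> None:
    for _, grp in bins.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        if (starts[1:] != ends[:-1] + 1).any() or (starts > ends).any():
            raise AssertionError("bins must tile the chromosome without overlap")


@dataclass
class BinGenotypeMatrix:
    """Per-line genotypes of consensus bins, used as linkage markers."""

    bins: pd.DataFrame  # bin_id, chrom, start, end, n_snps
    lines: list[str]
    calls: np.ndarray  # int8 (n_lines, n_bins), {A, B, MISSING}

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def bin_index(self) -> pd.Index:
        return pd.Index(self.bins["bin_id"])

    def to_frame(self) -> pd.DataFrame:
        from .core import calls_to_characters

        out = self.bins[["bin_id", "chrom", "start", "end"]].copy()
        chars = calls_to_characters(self.calls)
        for i, line in enumerate(self.lines):
            out[line] = chars[i]
        return out


def genotype_bins(
    bins: pd.DataFrame,
    segment_calls: dict[str, dict[str, SegmentCall]],
    mask_breakpoint_bins: bool = False,
) -> BinGenotypeMatrix:
    """Assign each line's parental genotype to each bin.

    By default a bin is scored with the genotype of the line's mosaic at
    the bin midpoint, joining resolved segments at breakpoint point
    estimates; a line is missing only where it has no resolved segments.
    With ``mask_breakpoint_bins`` every bin overlapped by a breakpoint
    interval is missing instead.  The strict masking looks safer but is
    unusable for mapping: bins tile the chromosome, so every junction
    falls inside some bin, and masking it hides every recombination
    event from the adjacent-bin recombinant fractions.
    """
    lines = list(segment_calls)
    calls = np.full((len(lines), len(bins)), MISSING, dtype=np.int8)
    bin_rows = list(bins.itertuples(index=False))
    for li, line in enumerate(lines):
        for bi, row in enumerate(bin_rows):
            seg = segment_calls[line].get(row.chrom)
            if seg is None or not seg.segments:
                continue
            if mask_breakpoint_bins:
                if any(
                    bp.lo <= row.end and bp.hi >= row.start for bp in seg.breakpoints
                ):
                    continue
                covering = {
                    g for g, s, e in seg.segments if s <= row.end and e >= row.start
                }
                if len(covering) == 1:
                    calls[li, bi] = covering.pop()
                continue
            mid = 0.5 * (row.start + row.end)
            points = [bp.point for bp in seg.breakpoints]
            k = int(np.searchsorted(points, mid))
            calls[li, bi] = seg.segments[k][0]
    return BinGenotypeMatrix(bins=bins.reset_index(drop=True), lines=lines, calls=calls)


def bin_statistics(
    bins: pd.DataFrame, annotation: GeneAnnotation | None = None
) -> dict:
    """Bin size distribution, per-chromosome counts and genes per bin.

    Gene membership uses any-overlap (1-based inclusive); a gene spanning
    a bin boundary is counted in every bin it overlaps and flagged so
    totals can be deduplicated.
    """
    sizes = (bins["end"] - bins["start"] + 1).to_numpy()
    out: dict = {
        "n_bins": len(bins),
        "bins_per_chromosome": bins.groupby("chrom", sort=False).size().to_dict(),
        "size_bp": {
            "min": int(sizes.min()) if len(sizes) else 0,
            "median": float(np.median(sizes)) if len(sizes) else 0.0,
            "mean": float(sizes.mean()) if len(sizes) else 0.0,
            "max": int(sizes.max()) if len(sizes) else 0,
        },
    }
    gene_counts = np.zeros(len(bins), dtype=int)
    boundary_spanning: set[str] = set()
    if annotation is not None and len(annotation):
        for chrom, grp in bins.groupby("chrom", sort=False):
            genes = annotation.on_chromosome(chrom)
            if genes.empty:
                continue
            gs = genes["start"].to_numpy()
            ge = genes["end"].to_numpy()
            for idx, row in zip(grp.index, grp.itertuples(index=False)):
                overlap = (gs <= row.end) & (ge >= row.start)
                gene_counts[idx] = int(overlap.sum())
                spans = overlap & ((gs < row.start) | (ge > row.end))
                boundary_spanning.update(genes["gene_id"].to_numpy()[spans])
    out["genes_per_bin"] = gene_counts.tolist()
    out["n_bins_no_gene"] = int((gene_counts == 0).sum())
    out["n_bins_one_gene"] = int((gene_counts == 1).sum())
    out["boundary_spanning_genes"] = sorted(boundary_spanning)
    return out
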