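"""Marker ordering by recombination counting and cM assignment.

Bins are ordered within each linkage group by the RECORD criterion — the
total number of observed recombination events between adjacent markers —
using greedy sequential insertion from several seeded restarts, then
polished with a sum-of-adjacent-distances (SAD) ripple that exhaustively
permutes a sliding window of positions.  Linkage groups are taken from
the bins' physical chromosomes.

Observed recombinant fractions R between RIL genotypes overstate the
per-meiosis fraction because single-seed descent accumulates crossovers;
the classical F-infinity correction r = R / (2 - 2R) is applied before
converting to map distance with the Kosambi (default) or Haldane
function.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .binning import BinGenotypeMatrix
from .core import A, B, MISSING, round_half_up


@dataclass
class MapParams:
    mapping_function: str = "kosambi"  # or "haldane"
    ril_correction: bool = True
    ripple_window: int = 5
    record_restarts: int = 10
    min_scorable: int = 20
    segregation_p_min: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ripple_window < 2:
            raise ValueError("ripple_window must be >= 2")
        if self.mapping_function not in ("kosambi", "haldane"):
            raise ValueError("mapping_function must be 'kosambi' or 'haldane'")


# ---------------------------------------------------------------------------
# pairwise recombination

def pairwise_counts(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Recombination-event and scorable-line counts for all marker pairs.

    Returns (D, N): D[i, j] = lines whose genotypes differ at markers i
    and j, N[i, j] = lines scorable at both.
    """
    a = ((calls == A)).astype(np.float64)
    b = ((calls == B)).astype(np.float64)
    m = (calls != MISSING).astype(np.float64)
    n_mat = m.T @ m
    d_mat = a.T @ b + b.T @ a
    return d_mat, n_mat


def pairwise_rf(
    calls_i: np.ndarray,
    calls_j: np.ndarray,
    ril_correction: bool = True,
    min_scorable: int = 20,
) -> tuple[float, float]:
    """Observed recombinant fraction R and corrected meiotic fraction r
    for one marker pair.

    R is the fraction of lines scorable at both markers whose genotypes
    differ; r = R / (2 - 2R) inverts the F-infinity map expansion and is
    capped at 0.4999.  R close to 1 indicates a phase/ordering artifact.
    """
    both = (calls_i != MISSING) & (calls_j != MISSING)
    n = int(both.sum())
    if n < min_scorable:
        raise ValueError(f"only {n} scorable lines (< {min_scorable}); unestimable")
    r_obs = float((calls_i[both] != calls_j[both]).mean())
    if ril_correction:
        r_cor = r_obs / (2.0 - 2.0 * r_obs) if r_obs < 1.0 else np.inf
    else:
        r_cor = r_obs
    return r_obs, float(min(r_cor, 0.4999))


# ---------------------------------------------------------------------------
# RECORD ordering

def _order_criterion(order: list[int], d_mat: np.ndarray) -> float:
    idx = np.asarray(order)
    return float(d_mat[idx[:-1], idx[1:]].sum())


def _greedy_insertion(
    sequence: list[int], d_mat: np.ndarray
) -> tuple[list[int], float]:
    order = list(sequence[:2])
    for marker in sequence[2:]:
        best_cost, best_pos = np.inf, 0
        for pos in range(len(order) + 1):
            if pos == 0:
                delta = d_mat[marker, order[0]]
            elif pos == len(order):
                delta = d_mat[order[-1], marker]
            else:
                left, right = order[pos - 1], order[pos]
                delta = d_mat[left, marker] + d_mat[marker, right] - d_mat[left, right]
            if delta < best_cost:
                best_cost, best_pos = delta, pos
        order.insert(best_pos, marker)
    return order, _order_criterion(order, d_mat)


def record_order(
    bin_matrix: BinGenotypeMatrix,
    chrom: str,
    params: MapParams | None = None,
) -> tuple[list[int], float]:
    """Order one linkage group's bins by recombination counting.

    Minimizes the COUNT criterion (sum of adjacent pairwise recombination
    events) by greedy sequential insertion of markers in seeded random
    order, keeping the best of ``record_restarts`` restarts, then
    normalizes orientation so the first bin has the smaller physical
    coordinate.  Returns (bin indices into the matrix, criterion value).
    """
    params = params or MapParams()
    idx = np.flatnonzero((bin_matrix.bins["chrom"] == chrom).to_numpy())
    if len(idx) < 3:
        raise ValueError("RECORD ordering needs at least 3 bins")
    calls = bin_matrix.calls[:, idx]
    d_mat, n_mat = pairwise_counts(calls)
    unestimable = n_mat < params.min_scorable
    np.fill_diagonal(unestimable, False)
    if unestimable.any():
        warnings.warn(
            "some marker pairs have too few scorable lines; bridged with penalty",
            stacklevel=2,
        )
        d_mat = d_mat.copy()
        d_mat[unestimable] = d_mat.max() + 1.0
    rng = np.random.default_rng(params.seed)
    best_order: list[int] | None = None
    best_value = np.inf
    for _ in range(params.record_restarts):
        seq = list(rng.permutation(len(idx)))
        order, value = _greedy_insertion(seq, d_mat)
        order = sad_ripple(order, d_mat, params)
        value = _order_criterion(order, d_mat)
        if value < best_value:
            best_order, best_value = order, value
    assert best_order is not None
    starts = bin_matrix.bins["start"].to_numpy()[idx]
    if starts[best_order[0]] > starts[best_order[-1]]:
        best_order = best_order[::-1]
    elif starts[best_order[0]] == starts[best_order[-1]]:
        best_order = min(best_order, list(reversed(best_order)))
    return [int(idx[i]) for i in best_order], best_value


def sad_ripple(
    order: list[int], d_mat: np.ndarray, params: MapParams | None = None
) -> list[int]:
    """Polish an order by exhaustive permutation inside a sliding window.

    Minimizes the sum of adjacent distances; repeats full passes until no
    window improves, so the criterion never increases.
    """
    params = params or MapParams()
    w = min(params.ripple_window, len(order))
    order = list(order)
    improved = True
    while improved:
        improved = False
        for start in range(len(order) - w + 1):
            window = order[start : start + w]
            prev_mark = order[start - 1] if start > 0 else None
            next_mark = order[start + w] if start + w < len(order) else None

            def cost(perm: tuple[int, ...]) -> float:
                c = float(d_mat[np.asarray(perm[:-1]), np.asarray(perm[1:])].sum())
                if prev_mark is not None:
                    c += d_mat[prev_mark, perm[0]]
                if next_mark is not None:
                    c += d_mat[perm[-1], next_mark]
                return c

            base = cost(tuple(window))
            best_perm, best_cost = tuple(window), base
            for perm in itertools.permutations(window):
                c = cost(perm)
                if c < best_cost - 1e-12:
                    best_perm, best_cost = perm, c
            if best_perm != tuple(window):
                order[start : start + w] = best_perm
                improved = True
    return order


# ---------------------------------------------------------------------------
# distances

def kosambi_cm(r: np.ndarray | float) -> np.ndarray | float:
    """Kosambi map distance d = 25 ln((1+2r)/(1-2r)) in cM."""
    r = np.asarray(r, dtype=float)
    if (r >= 0.5).any():
        raise ValueError("r must be < 0.5")
    return 25.0 * np.log((1 + 2 * r) / (1 - 2 * r))


def haldane_cm(r: np.ndarray | float) -> np.ndarray | float:
    """Haldane map distance d = -50 ln(1-2r) in cM."""
    r = np.asarray(r, dtype=float)
    if (r >= 0.5).any():
        raise ValueError("r must be < 0.5")
    return -50.0 * np.log(1 - 2 * r)


def inverse_mapping_r(d_cm: np.ndarray | float, mapping_function: str) -> np.ndarray:
    """Per-meiosis recombination fraction for a map distance in cM."""
    d = np.asarray(d_cm, dtype=float)
    if mapping_function == "kosambi":
        return 0.5 * np.tanh(d / 50.0)
    if mapping_function == "haldane":
        return 0.5 * (1.0 - np.exp(-d / 50.0))
    raise ValueError(mapping_function)


def ril_observed_r(r: np.ndarray | float) -> np.ndarray:
    """F-infinity RIL map expansion: observed R = 2r / (1 + 2r)."""
    r = np.asarray(r, dtype=float)
    return 2 * r / (1 + 2 * r)


@dataclass
class GeneticMap:
    """Ordered bins with cM positions, one linkage group per chromosome.

    ``table`` columns: chrom, bin_id, bin_index (into the bin matrix),
    cm, R (observed adjacent recombinant fraction), r (corrected), d
    (interval cM); first marker of each group sits at 0 cM.
    """

    table: pd.DataFrame
    mapping_function: str = "kosambi"
    unplaced: list[str] | None = None

    def group(self, chrom: str) -> pd.DataFrame:
        return self.table[self.table["chrom"] == chrom].reset_index(drop=True)

    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.table["chrom"]))

    @property
    def total_cm(self) -> float:
        return float(self.table.groupby("chrom", sort=False)["cm"].max().sum())


def placeable_bins(
    bin_matrix: BinGenotypeMatrix, params: MapParams | None = None
) -> np.ndarray:
    """Indices of bins eligible for mapping: enough scorable lines and no
    gross segregation distortion (chi-square of A:B vs 1:1)."""
    params = params or MapParams()
    keep = []
    for j in range(bin_matrix.n_bins):
        col = bin_matrix.calls[:, j]
        n_a = int((col == A).sum())
        n_b = int((col == B).sum())
        n = n_a + n_b
        if n < params.min_scorable:
            continue
        chi = (n_a - n_b) ** 2 / n
        if stats.chi2.sf(chi, df=1) < params.segregation_p_min:
            continue
        keep.append(j)
    return np.asarray(keep, dtype=int)


def map_positions(
    bin_matrix: BinGenotypeMatrix,
    orders: dict[str, list[int]],
    params: MapParams | None = None,
) -> GeneticMap:
    """Assign cM positions along each ordered linkage group."""
    params = params or MapParams()
    dist = kosambi_cm if params.mapping_function == "kosambi" else haldane_cm
    rows = []
    for chrom, order in orders.items():
        cm = 0.0
        prev = None
        for j in order:
            if prev is None:
                big_r, r, d = np.nan, np.nan, np.nan
            else:
                big_r, r = pairwise_rf(
                    bin_matrix.calls[:, prev],
                    bin_matrix.calls[:, j],
                    ril_correction=params.ril_correction,
                    min_scorable=2,  # order construction already vetted pairs
                )
                d = float(dist(r))
                cm += d
            rows.append(
                {
                    "chrom": chrom,
                    "bin_id": bin_matrix.bins["bin_id"].iloc[j],
                    "bin_index": j,
                    "cm": cm,
                    "R": big_r,
                    "r": r,
                    "d": d,
                }
            )
            prev = j
    return GeneticMap(table=pd.DataFrame(rows), mapping_function=params.mapping_function)


def build_map(
    bin_matrix: BinGenotypeMatrix, params: MapParams | None = None
) -> GeneticMap:
    """Full map construction: placement filter, RECORD + SAD per group,
    cM assignment."""
    params = params or MapParams()
    keep = placeable_bins(bin_matrix, params)
    keep_set = set(keep.tolist())
    unplaced = [
        bid
        for j, bid in enumerate(bin_matrix.bins["bin_id"])
        if j not in keep_set
    ]
    orders: dict[str, list[int]] = {}
    for chrom in dict.fromkeys(bin_matrix.bins["chrom"]):
        on_chrom = [
            j
            for j in np.flatnonzero((bin_matrix.bins["chrom"] == chrom).to_numpy())
            if j in keep_set
        ]
        if len(on_chrom) < 3:
            unplaced.extend(bin_matrix.bins["bin_id"].iloc[on_chrom])
            continue
        sub = BinGenotypeMatrix(
            bins=bin_matrix.bins.iloc[on_chrom].reset_index(drop=True),
            lines=bin_matrix.lines,
            calls=bin_matrix.calls[:, on_chrom],
        )
        sub_order, _ = record_order(sub, chrom, params)
        orders[chrom] = [on_chrom[i] for i in sub_order]
    gmap = map_positions(bin_matrix, orders, params)
    gmap.unplaced = unplaced
    return gmap


def map_summary(gmap: GeneticMap, genome_size_kb: float | None = None) -> dict:
    """Totals a mapping report prints: span, Kb/cM, mean inter-bin interval."""
    if gmap.table.empty:
        raise ValueError("empty genetic map")
    per_group = {}
    for chrom in gmap.groups():
        grp = gmap.group(chrom)
        span = float(grp["cm"].max())
        n = len(grp)
        per_group[chrom] = {
            "n_markers": n,
            "span_cm": round_half_up(span, 2),
            "mean_interval_cm": round_half_up(span / (n - 1), 2) if n > 1 else 0.0,
        }
    total = gmap.total_cm
    if total <= 0:
        raise ValueError("zero-length map")
    out = {
        "total_cm": round_half_up(total, 2),
        "n_markers": int(len(gmap.table)),
        "per_group": per_group,
    }
    if genome_size_kb is not None:
        out["kb_per_cm"] = kb_per_cm(genome_size_kb, total)
    return out


def kb_per_cm(genome_size_kb: float, total_cm: float) -> float:
    """Physical-to-genetic ratio, two decimals."""
    if total_cm <= 0:
        raise ValueError("map length must be positive")
    return round_half_up(genome_size_kb / total_cm, 2)


def placement_percentage(n_placed: int, n_total: int) -> float:
    """Share of bins integrated into the map, as a percentage (2 dp)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return round_half_up(100.0 * n_placed / n_total, 2)
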