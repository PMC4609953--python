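"""Inclusive composite interval mapping (additive model) on bin markers.

The scan is the classical two-phase ICIM procedure:

1. stepwise cofactor selection — forward-backward linear regression of
   the phenotype on all bin markers (coded +1 for the A parent, -1 for
   B, missing values mean-imputed), with entry p-value ``p_in`` and
   removal p-value ``p_out``;
2. an interval scan of the cofactor-adjusted phenotype.  At each testing
   position the phenotype is adjusted by the fitted cofactor model
   *excluding* the two markers flanking the testing interval, and
   regressed on the expected QTL genotype given the flanking bin
   genotypes (RIL conditional expectation under the mapping function in
   force).  LOD = (n/2) * log10(RSS0 / RSS1); PVE is reported against
   the adjusted phenotypic variance.

Genome-wide significance uses a permutation threshold: the phenotype is
permuted across lines, the full scan (including cofactor selection)
repeated, and the empirical (1 - alpha) quantile of the per-permutation
maximum LOD taken as the threshold.

QTLs with PVE above 10% are classified as major; the topmost QTL of a
trait is the one with the highest PVE across environments, and topmost
QTLs of different traits sharing both flanking bins delineate hotspot
sub-regions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .binning import BinGenotypeMatrix
from .core import A, MISSING, round_half_up
from .linkage import GeneticMap, inverse_mapping_r, ril_observed_r


@dataclass
class IcimParams:
    p_in: float = 0.001
    p_out: float = 0.002
    scan_step_cm: float = 1.0
    n_permutations: int = 1000
    alpha: float = 0.05
    major_pve_min: float = 10.0  # percent
    # cofactors this close (cM) to the testing position are left out of
    # the adjustment; with dense bin markers the flanking pair alone is
    # not enough, as a cofactor one bin beyond a flank is nearly
    # collinear with the tested genotype and absorbs the QTL signal
    exclude_window_cm: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p_out < self.p_in:
            raise ValueError("p_out must be >= p_in")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")


def marker_design(bin_matrix: BinGenotypeMatrix) -> np.ndarray:
    """Markers as a float matrix: +1 (A), -1 (B), NaN missing."""
    x = np.where(bin_matrix.calls == A, 1.0, -1.0)
    x[bin_matrix.calls == MISSING] = np.nan
    return x


def _mean_impute(x: np.ndarray) -> np.ndarray:
    col_mean = np.nanmean(x, axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
    out = np.where(np.isnan(x), col_mean[None, :], x)
    return out


@dataclass
class CofactorModel:
    selected: list[int]  # marker (bin) indices
    coef: np.ndarray  # intercept followed by per-cofactor coefficients
    design: np.ndarray  # imputed marker matrix used for fitting

    def adjusted_phenotype(self, y: np.ndarray, exclude: set[int]) -> np.ndarray:
        """Phenotype minus fitted cofactor contributions, skipping the
        markers in ``exclude`` (the flanks of the testing interval)."""
        adj = y.astype(float).copy()
        for k, j in enumerate(self.selected):
            if j not in exclude:
                adj -= self.coef[k + 1] * self.design[:, j]
        return adj


def _ols_pvalues(xmat: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-sided t-test p-values for each coefficient of an OLS fit with
    intercept (intercept p excluded)."""
    n, k = xmat.shape
    design = np.column_stack([np.ones(n), xmat])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    dof = n - design.shape[1]
    if dof <= 0:
        return np.ones(k)
    sigma2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.pinv(design.T @ design)
    se = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv), 1e-300))
    tvals = coef / se
    return 2 * stats.t.sf(np.abs(tvals[1:]), dof)


def select_cofactors(
    bin_matrix: BinGenotypeMatrix,
    phenotype: np.ndarray,
    params: IcimParams | None = None,
    max_steps: int = 200,
) -> CofactorModel:
    """Forward-backward stepwise marker selection for the cofactor model."""
    params = params or IcimParams()
    y = np.asarray(phenotype, dtype=float)
    if np.var(y) == 0:
        raise ValueError("phenotype has no variation")
    x = _mean_impute(marker_design(bin_matrix))
    n, m = x.shape
    if n < 30:
        raise ValueError("need at least 30 lines for cofactor selection")
    active: list[int] = []
    for _ in range(max_steps):
        changed = False
        # forward: best candidate by partial correlation with current residual
        inactive = [j for j in range(m) if j not in active]
        if inactive:
            design = np.column_stack([np.ones(n)] + [x[:, j] for j in active])
            proj, *_ = np.linalg.lstsq(design, y, rcond=None)
            ry = y - design @ proj
            px, *_ = np.linalg.lstsq(design, x[:, inactive], rcond=None)
            rx = x[:, inactive] - design @ px
            sx = np.sqrt((rx**2).sum(axis=0))
            sy = float(np.sqrt((ry**2).sum()))
            with np.errstate(invalid="ignore", divide="ignore"):
                corr = np.where(sx > 1e-12, (rx.T @ ry) / (sx * sy), 0.0)
            dof = n - len(active) - 2
            if dof > 0 and sy > 1e-12:
                tvals = corr * np.sqrt(dof / np.maximum(1 - corr**2, 1e-12))
                pvals = 2 * stats.t.sf(np.abs(tvals), dof)
                best = int(np.argmin(pvals))
                if pvals[best] <= params.p_in:
                    active.append(inactive[best])
                    changed = True
        # backward: drop the worst active marker above p_out
        if active:
            pvals = _ols_pvalues(x[:, active], y)
            worst = int(np.argmax(pvals))
            if pvals[worst] > params.p_out:
                del active[worst]
                changed = True
        if not changed:
            break
    if active:
        design = np.column_stack([np.ones(n)] + [x[:, j] for j in active])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    else:
        coef = np.array([float(np.mean(y))])
    return CofactorModel(selected=active, coef=coef, design=x)


# ---------------------------------------------------------------------------
# interval scan

def _expected_qtl_genotype(
    x_left: np.ndarray,
    x_right: np.ndarray,
    r_obs_left: float,
    r_obs_right: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Conditional expectation of the QTL genotype (+1/-1) given flanking
    bin genotypes, under a Markov RIL model with observed two-point
    recombinant fractions.  Lines missing both flanks are excluded."""
    have_l = ~np.isnan(x_left)
    have_r = ~np.isnan(x_right)
    include = have_l | have_r
    r1 = min(max(r_obs_left, 1e-9), 0.5 - 1e-9)
    r2 = min(max(r_obs_right, 1e-9), 0.5 - 1e-9)
    ex = np.zeros(len(x_left))
    both = have_l & have_r
    if both.any():
        xl, xr = x_left[both], x_right[both]
        # P(Q matches left parent phase) proportional to transition probs
        p_same_l = np.where(xl > 0, 1 - r1, r1)  # P(Q = A | left)
        p_same_l_b = 1 - p_same_l
        p_qa = p_same_l * np.where(xr > 0, 1 - r2, r2)
        p_qb = p_same_l_b * np.where(xr > 0, r2, 1 - r2)
        total = p_qa + p_qb
        ex[both] = (p_qa - p_qb) / total
    only_l = have_l & ~have_r
    ex[only_l] = x_left[only_l] * (1 - 2 * r1)
    only_r = have_r & ~have_l
    ex[only_r] = x_right[only_r] * (1 - 2 * r2)
    return ex, include


def icim_scan(
    gmap: GeneticMap,
    bin_matrix: BinGenotypeMatrix,
    phenotype: np.ndarray,
    cofactors: CofactorModel,
    params: IcimParams | None = None,
) -> pd.DataFrame:
    """LOD/PVE/effect profile along the genetic map.

    Returns one row per testing position: chrom, pos_cm, lod, pve,
    additive, left_bin, right_bin.
    """
    params = params or IcimParams()
    y = np.asarray(phenotype, dtype=float)
    if len(y) != len(bin_matrix.lines):
        raise ValueError("phenotype length does not match bin matrix lines")
    x_raw = marker_design(bin_matrix)
    marker_cm = {
        int(row.bin_index): (row.chrom, float(row.cm))
        for row in gmap.table.itertuples(index=False)
    }
    rows = []
    for chrom in gmap.groups():
        grp = gmap.group(chrom)
        cm = grp["cm"].to_numpy()
        marker_idx = grp["bin_index"].to_numpy()
        positions = np.arange(0.0, cm[-1] + 1e-9, params.scan_step_cm)
        if cm[-1] not in positions:
            positions = np.append(positions, cm[-1])
        for pos in positions:
            right_i = int(np.searchsorted(cm, pos, side="left"))
            right_i = min(right_i, len(cm) - 1)
            left_i = max(right_i - 1, 0) if cm[right_i] > pos else right_i
            if left_i == right_i:
                jl = jr = int(marker_idx[left_i])
                r1 = r2 = 0.0
            else:
                jl, jr = int(marker_idx[left_i]), int(marker_idx[right_i])
                d1, d2 = pos - cm[left_i], cm[right_i] - pos
                r1 = float(
                    ril_observed_r(inverse_mapping_r(d1, gmap.mapping_function))
                )
                r2 = float(
                    ril_observed_r(inverse_mapping_r(d2, gmap.mapping_function))
                )
            ex, include = _expected_qtl_genotype(x_raw[:, jl], x_raw[:, jr], r1, r2)
            exclude = {jl, jr}
            for j in cofactors.selected:
                at = marker_cm.get(j)
                if at and at[0] == chrom and abs(at[1] - pos) <= params.exclude_window_cm:
                    exclude.add(j)
            y_adj = cofactors.adjusted_phenotype(y, exclude=exclude)
            ex_s, y_s = ex[include], y_adj[include]
            n = len(y_s)
            if n < 10 or np.std(ex_s) < 1e-12:
                lod = pve = add = 0.0
            else:
                yc = y_s - y_s.mean()
                xc = ex_s - ex_s.mean()
                sxx = float(xc @ xc)
                sxy = float(xc @ yc)
                rss0 = float(yc @ yc)
                rss1 = max(rss0 - sxy**2 / sxx, 1e-300)
                lod = (n / 2.0) * np.log10(rss0 / rss1) if rss0 > 0 else 0.0
                pve = 100.0 * (1.0 - rss1 / rss0) if rss0 > 0 else 0.0
                add = sxy / sxx
            rows.append(
                {
                    "chrom": chrom,
                    "pos_cm": float(pos),
                    "lod": float(lod),
                    "pve": float(pve),
                    "additive": float(add),
                    "left_bin": bin_matrix.bins["bin_id"].iloc[jl],
                    "right_bin": bin_matrix.bins["bin_id"].iloc[jr],
                }
            )
    return pd.DataFrame(rows)


def scan_trait(
    gmap: GeneticMap,
    bin_matrix: BinGenotypeMatrix,
    phenotype: np.ndarray,
    params: IcimParams | None = None,
) -> pd.DataFrame:
    """Convenience: cofactor selection followed by the interval scan."""
    params = params or IcimParams()
    cof = select_cofactors(bin_matrix, phenotype, params)
    return icim_scan(gmap, bin_matrix, phenotype, cof, params)


def permutation_threshold(
    gmap: GeneticMap,
    bin_matrix: BinGenotypeMatrix,
    phenotype: np.ndarray,
    params: IcimParams | None = None,
) -> float:
    """Genome-wide LOD threshold from seeded phenotype permutations.

    The threshold is the empirical (1 - alpha) quantile — for 1000
    permutations at alpha 0.05, the 950th ascending order statistic — of
    the per-permutation maximum LOD over the full scan (cofactor
    selection re-run on each permuted phenotype).
    """
    params = params or IcimParams()
    rng = np.random.default_rng(params.seed)
    y = np.asarray(phenotype, dtype=float)
    max_lods = np.empty(params.n_permutations)
    for b in range(params.n_permutations):
        perm = rng.permutation(y)
        profile = scan_trait(gmap, bin_matrix, perm, params)
        max_lods[b] = profile["lod"].max() if len(profile) else 0.0
    k = int(np.ceil((1 - params.alpha) * params.n_permutations))
    return float(np.sort(max_lods)[k - 1])


# ---------------------------------------------------------------------------
# QTL calling

def call_qtls(
    profile: pd.DataFrame,
    threshold: float,
    params: IcimParams | None = None,
    trait: str = "",
    environment: str = "",
) -> pd.DataFrame:
    """One QTL per contiguous supra-threshold segment, at its LOD peak.

    Class is major iff PVE strictly exceeds ``major_pve_min`` (a QTL at
    exactly 10% PVE is minor).
    """
    params = params or IcimParams()
    results = []
    for chrom in dict.fromkeys(profile["chrom"]):
        grp = profile[profile["chrom"] == chrom].reset_index(drop=True)
        above = grp["lod"].to_numpy() >= threshold
        i = 0
        while i < len(grp):
            if not above[i]:
                i += 1
                continue
            j = i
            while j < len(grp) and above[j]:
                j += 1
            seg = grp.iloc[i:j]
            peak = seg.loc[seg["lod"].idxmax()]
            pve = float(peak["pve"])
            results.append(
                {
                    "trait": trait,
                    "environment": environment,
                    "chrom": chrom,
                    "pos_cm": float(peak["pos_cm"]),
                    "lod": float(peak["lod"]),
                    "pve": pve,
                    "additive": float(peak["additive"]),
                    "left_bin": peak["left_bin"],
                    "right_bin": peak["right_bin"],
                    "class": "major" if pve > params.major_pve_min else "minor",
                }
            )
            i = j
    return pd.DataFrame(
        results,
        columns=[
            "trait",
            "environment",
            "chrom",
            "pos_cm",
            "lod",
            "pve",
            "additive",
            "left_bin",
            "right_bin",
            "class",
        ],
    )


_BIN_ID = re.compile(r"^bin_(\w+?)_(\d+)$")


def parse_bin_id(bin_id: str) -> tuple[str, int]:
    m = _BIN_ID.match(bin_id)
    if not m:
        raise ValueError(f"malformed bin id: {bin_id!r}")
    return m.group(1), int(m.group(2))


def region_size_kb(left_bin: str, right_bin: str) -> float:
    """Physical span between two flanking bin ids, in Kb (2 dp).

    Bin ids encode their start coordinate (bin_<chrom>_<start>); the
    span is the absolute coordinate difference, so descending marker
    order is handled.
    """
    _, c1 = parse_bin_id(left_bin)
    _, c2 = parse_bin_id(right_bin)
    return round_half_up(abs(c2 - c1) / 1000.0, 2)


@dataclass
class HotspotRegion:
    name: str
    chrom: str
    left_bin: str
    right_bin: str
    start: int
    end: int
    traits: list[str] = field(default_factory=list)

    @property
    def size_kb(self) -> float:
        return region_size_kb(self.left_bin, self.right_bin)


def topmost_and_hotspots(
    qtls: pd.DataFrame,
) -> tuple[pd.DataFrame, list[HotspotRegion]]:
    """Per-trait topmost QTLs and the hotspot sub-regions they share.

    The topmost QTL of a trait is the one with maximum PVE over all
    environments; topmost QTLs with identical flanking-bin pairs are
    grouped, and each group covering at least two traits becomes a
    sequentially-named hotspot region spanning the flanking bins' start
    coordinates.
    """
    if qtls.empty:
        raise ValueError("no QTLs to summarize")
    top_idx = qtls.groupby("trait", sort=False)["pve"].idxmax()
    topmost = qtls.loc[top_idx].reset_index(drop=True)
    regions: list[HotspotRegion] = []
    grouped = topmost.groupby(["left_bin", "right_bin"], sort=False)
    for (left, right), grp in grouped:
        traits = sorted(set(grp["trait"]))
        if len(traits) < 2:
            continue
        chrom = grp["chrom"].iloc[0]
        _, c1 = parse_bin_id(left)
        _, c2 = parse_bin_id(right)
        regions.append(
            HotspotRegion(
                name=f"region{len(regions) + 1}",
                chrom=chrom,
                left_bin=left,
                right_bin=right,
                start=min(c1, c2),
                end=max(c1, c2),
                traits=traits,
            )
        )
    return topmost, regions
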