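"""Relative qPCR expression by the 2^-ddCt method.

Cycle-threshold (Ct) values of a target gene are normalized to an
endogenous control (e.g. GAPDH) within each sample group:
dCt = mean(Ct_target) - mean(Ct_reference).  The comparison of a test
group against a calibrator group is ddCt = dCt_test - dCt_calibrator,
and the fold change is 2^-ddCt (log2 fold = -ddCt).  Replicate-level
significance uses a two-sided Student t-test on per-replicate dCt
values (equal variances by default; Welch via ``equal_var=False``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CT_COLUMNS = ["gene", "group", "replicate", "ct_target", "ct_reference"]


@dataclass
class ExpressionRecord:
    gene: str
    test_group: str
    calibrator_group: str
    dct_test: float
    dct_calibrator: float
    ddct: float
    fold: float
    log2_fold: float
    p_value: float | None = None


def _group_rows(ct: pd.DataFrame, gene: str, group: str) -> pd.DataFrame:
    rows = ct[(ct["gene"] == gene) & (ct["group"] == group)]
    if rows.empty:
        raise ValueError(f"no Ct rows for gene {gene!r}, group {group!r}")
    if rows["ct_reference"].isna().any():
        raise ValueError(f"missing reference-gene Ct for gene {gene!r}, group {group!r}")
    return rows


def delta_ct(ct: pd.DataFrame, gene: str, group: str) -> float:
    """Mean target Ct minus mean reference Ct for one gene and group."""
    rows = _group_rows(ct, gene, group)
    return float(rows["ct_target"].mean() - rows["ct_reference"].mean())


def replicate_delta_ct(ct: pd.DataFrame, gene: str, group: str) -> np.ndarray:
    rows = _group_rows(ct, gene, group)
    return (rows["ct_target"] - rows["ct_reference"]).to_numpy(dtype=float)


def ddct_fold_change(
    ct: pd.DataFrame,
    gene: str,
    test_group: str,
    calibrator_group: str,
    with_test: bool = True,
    equal_var: bool = True,
) -> ExpressionRecord:
    """Fold change of a gene in the test group relative to the calibrator."""
    dct_t = delta_ct(ct, gene, test_group)
    dct_c = delta_ct(ct, gene, calibrator_group)
    ddct = dct_t - dct_c
    fold = float(2.0 ** (-ddct))
    p = (
        replicate_test(ct, gene, test_group, calibrator_group, equal_var=equal_var)
        if with_test
        else None
    )
    return ExpressionRecord(
        gene=gene,
        test_group=test_group,
        calibrator_group=calibrator_group,
        dct_test=dct_t,
        dct_calibrator=dct_c,
        ddct=ddct,
        fold=fold,
        log2_fold=-ddct,
        p_value=p,
    )


def replicate_test(
    ct: pd.DataFrame,
    gene: str,
    group1: str,
    group2: str,
    equal_var: bool = True,
) -> float:
    """Two-sided two-sample t-test on per-replicate dCt values."""
    d1 = replicate_delta_ct(ct, gene, group1)
    d2 = replicate_delta_ct(ct, gene, group2)
    if len(d1) < 2 or len(d2) < 2:
        raise ValueError("replicate test needs >= 2 replicates per group")
    if np.ptp(d1) == 0 and np.ptp(d2) == 0 and d1.mean() == d2.mean():
        return 1.0  # identical, zero-variance groups: no evidence of change
    res = stats.ttest_ind(d1, d2, equal_var=equal_var)
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else p
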