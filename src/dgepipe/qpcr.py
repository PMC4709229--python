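"""Relative quantification of RT-qPCR cycle thresholds by the 2^-ddCT method.

Each sample's target-gene cycle threshold (CT) is normalised against the
arithmetic mean CT of the reference genes (equivalently, the geometric mean
of their expression levels): ``dCT = CT_target - mean(CT_refs)``.  The
between-group contrast ``ddCT = mean dCT(case) - mean dCT(control)`` gives
the expression ratio ``2^-ddCT``.  Technical replicates are averaged within
a sample before any between-sample statistics; the standard error and the
two-sample t-test operate on per-sample (biological replicate) dCT values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["QpcrTable", "QpcrResult", "ddct_ratio"]

_REQUIRED_COLUMNS = ("sample_id", "group", "gene_id", "ct")


@dataclass(frozen=True)
class QpcrTable:
    """Long-format CT table: one row per technical replicate measurement.

    ``frame`` needs columns ``sample_id group gene_id ct``; every sample
    must measure every reference gene, and CT values must be positive.
    """

    frame: pd.DataFrame
    reference_genes: tuple[str, ...]

    def __post_init__(self) -> None:
        missing = [c for c in _REQUIRED_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"qPCR table missing columns: {missing}")
        if not self.reference_genes:
            raise ValueError("at least one reference gene is required")
        object.__setattr__(
            self, "reference_genes", tuple(self.reference_genes)
        )
        ct = self.frame["ct"].to_numpy(dtype=float)
        if not np.all(np.isfinite(ct)) or (ct <= 0).any():
            raise ValueError("CT values must be positive and finite")
        genes_by_sample = self.frame.groupby("sample_id")["gene_id"].agg(set)
        for sample, genes in genes_by_sample.items():
            absent = set(self.reference_genes) - genes
            if absent:
                raise ValueError(
                    f"sample {sample!r} lacks reference gene CTs: {sorted(absent)}"
                )


@dataclass(frozen=True)
class QpcrResult:
    """Fold change (case over control) with dispersion and test result."""

    gene_id: str
    fold_change: float
    se: float
    ddct: float
    p_value: float
    n_case: int
    n_control: int


def _delta_ct(table: QpcrTable, target_gene: str, group: str) -> np.ndarray:
    """Per-sample dCT for one group, technical replicates averaged first."""
    sub = table.frame[table.frame["group"] == group]
    means = sub.groupby(["sample_id", "gene_id"])["ct"].mean().unstack()
    if target_gene not in means.columns:
        raise ValueError(f"target {target_gene!r} not measured in group {group!r}")
    means = means.dropna(subset=[target_gene])
    ref = means[list(table.reference_genes)].mean(axis=1)
    return (means[target_gene] - ref).to_numpy(dtype=float)


def ddct_ratio(
    table: QpcrTable,
    target_gene: str,
    case_group: str,
    control_group: str,
) -> QpcrResult:
    """2^-ddCT fold change of ``target_gene`` in case relative to control.

    The standard error of ddCT combines the per-group standard errors of
    the biological-replicate dCT values; the fold-change SE follows by the
    delta method (``se_fc = ln 2 * fc * se_ddct``).  Group difference is
    tested by Student's two-sample t-test on dCT (requires >= 2 biological
    replicates per group; otherwise SE and p are NaN).
    """
    groups = set(table.frame["group"])
    for g in (case_group, control_group):
        if g not in groups:
            raise ValueError(f"group {g!r} absent from table")
    if case_group == control_group:
        raise ValueError("case and control groups must differ")

    dct_case = _delta_ct(table, target_gene, case_group)
    dct_control = _delta_ct(table, target_gene, control_group)
    if dct_case.size == 0 or dct_control.size == 0:
        raise ValueError(f"target {target_gene!r} missing from one group")

    ddct = float(dct_case.mean() - dct_control.mean())
    fold = 2.0 ** (-ddct)

    if dct_case.size >= 2 and dct_control.size >= 2:
        se_ddct = math.sqrt(
            dct_case.var(ddof=1) / dct_case.size
            + dct_control.var(ddof=1) / dct_control.size
        )
        se_fold = math.log(2.0) * fold * se_ddct
        p_value = float(
            stats.ttest_ind(dct_case, dct_control, equal_var=True).pvalue
        )
    else:
        se_fold = float("nan")
        p_value = float("nan")

    return QpcrResult(
        gene_id=target_gene,
        fold_change=fold,
        se=se_fold,
        ddct=ddct,
        p_value=p_value,
        n_case=int(dct_case.size),
        n_control=int(dct_control.size),
    )
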