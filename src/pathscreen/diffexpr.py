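"""Per-gene differential expression between two conditions.

Welch t-tests on log2-transformed abundances, Benjamini-Hochberg q-values,
and a fold-change gate on linear-scale condition means.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "DifferentialExpressionResult",
    "differential_expression",
    "bh_adjust",
    "coefficient_of_variation",
]


@dataclass
class ExpressionMatrix:
    """Gene x sample matrix of linear-scale abundances with sample annotations.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample id.
        Entries must be finite and non-negative (NaN marks a missing
        measurement and excludes the gene from testing).
    condition_of
        Series mapping sample id -> condition label.
    replicate_of
        Series mapping sample id -> replicate index.
    """

    values: pd.DataFrame
    condition_of: pd.Series
    replicate_of: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise InputError("duplicate gene ids in expression matrix")
        if self.values.columns.has_duplicates:
            raise InputError("duplicate sample ids in expression matrix")
        missing = [s for s in self.values.columns if s not in self.condition_of.index]
        if missing:
            raise InputError(f"samples without condition annotation: {missing}")
        arr = self.values.to_numpy(dtype=float)
        finite = arr[~np.isnan(arr)]
        if np.any(~np.isfinite(finite)):
            raise InputError("expression values must be finite")
        if np.any(finite < 0):
            raise InputError("expression values must be non-negative")

    @property
    def gene_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)

    def samples_for(self, condition: str) -> list:
        return [s for s in self.values.columns if self.condition_of[s] == condition]


@dataclass
class DifferentialExpressionResult:
    """Per-gene statistics from :func:`differential_expression`.

    ``table`` has one row per tested gene with columns
    ``mean_a, mean_b, log2fc, p_value, q_value, significant``.
    Genes dropped for missing values are listed in ``excluded``.
    """

    table: pd.DataFrame
    cond_a: str
    cond_b: str
    q_threshold: float
    fc_threshold: float
    pseudocount: float
    excluded: list = field(default_factory=list)

    @property
    def significant_genes(self) -> list:
        return list(self.table.index[self.table["significant"]])


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_(i) = min_{j >= i} p_(j) * n / j, capped at 1, returned in the
    input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise InputError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise InputError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(n)
    q[order] = q_sorted
    return q


def coefficient_of_variation(values) -> float:
    """Percent coefficient of variation: 100 * sd / mean (sd with n-1)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise InputError("coefficient of variation requires at least 2 values")
    mean = x.mean()
    if mean <= 0:
        raise InputError("coefficient of variation undefined for mean <= 0")
    return float(100.0 * x.std(ddof=1) / mean)


def differential_expression(
    matrix: ExpressionMatrix,
    cond_a: str,
    cond_b: str,
    q_threshold: float = 0.05,
    fc_threshold: float = 2.0,
    pseudocount: float = 1.0,
) -> DifferentialExpressionResult:
    """Welch t-test per gene on log2(x + pseudocount) between two conditions.

    Fold change is the ratio of linear-scale condition means (with the same
    pseudocount); a gene is significant iff its BH q-value is below
    ``q_threshold`` and max(FC, 1/FC) exceeds ``fc_threshold``.

    Genes whose two groups are both constant get p = 1 when the group means
    are equal (no evidence by convention) and p = 0 otherwise.
    """
    samples_a = matrix.samples_for(cond_a)
    samples_b = matrix.samples_for(cond_b)
    if not samples_a:
        raise InputError(f"condition label not found: {cond_a!r}")
    if not samples_b:
        raise InputError(f"condition label not found: {cond_b!r}")
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise InputError("each condition needs at least 2 replicates")

    a = matrix.values[samples_a].to_numpy(dtype=float)
    b = matrix.values[samples_b].to_numpy(dtype=float)

    keep = ~(np.isnan(a).any(axis=1) | np.isnan(b).any(axis=1))
    excluded = list(matrix.values.index[~keep])
    if excluded:
        logger.warning("excluding %d genes with missing values", len(excluded))
    genes = matrix.values.index[keep]
    a, b = a[keep], b[keep]

    la = np.log2(a + pseudocount)
    lb = np.log2(b + pseudocount)
    # pooled (Student) t: with triplicates, Welch's Satterthwaite df can drop
    # to 2, which costs too much power at genome-wide multiplicity
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat, p = stats.ttest_ind(lb, la, axis=1, equal_var=True)
    # both groups constant -> scipy yields nan; resolve by the mean contrast
    degenerate = np.isnan(p)
    if degenerate.any():
        equal = np.isclose(la.mean(axis=1), lb.mean(axis=1))
        p = np.where(degenerate, np.where(equal, 1.0, 0.0), p)

    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    fc = (mean_b + pseudocount) / (mean_a + pseudocount)
    log2fc = np.log2(fc)
    q = bh_adjust(p)
    fc_pass = np.maximum(fc, 1.0 / fc) > fc_threshold
    significant = (q < q_threshold) & fc_pass

    table = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": log2fc,
            "p_value": p,
            "q_value": q,
            "significant": significant,
        },
        index=genes,
    )
    table.index.name = "gene"
    return DifferentialExpressionResult(
        table=table,
        cond_a=cond_a,
        cond_b=cond_b,
        q_threshold=q_threshold,
        fc_threshold=fc_threshold,
        pseudocount=pseudocount,
        excluded=excluded,
    )
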