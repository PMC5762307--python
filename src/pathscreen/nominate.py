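"""Candidate-gene nomination from IPL scores and expression filters.

Filter chain: (1) |IPL - median| beyond k standard deviations, (2) CV band,
(3) non-zero expression in a minimum number of samples. Controls are
appended with explicit roles and never alter the candidate list.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffexpr import ExpressionMatrix
from .errors import InputError
from .ipl import IPLResult, PathwayGraph

logger = logging.getLogger(__name__)

__all__ = [
    "CandidateSet",
    "ipl_outlier_nodes",
    "expression_filters",
    "add_controls",
    "nominate_candidates",
]

CONTROL_ROLES = ("negative", "positive_viability", "biological")


@dataclass
class CandidateSet:
    """Outcome of the nomination chain.

    ``table`` holds one row per evaluated gene with columns
    ``ipl, cv, n_nonzero, passed_ipl, passed_cv, passed_nonzero``;
    ``candidates`` are the genes passing all flags. ``controls`` maps
    gene -> role; a control that is also a candidate stays in both.
    """

    nominated_nodes: set = field(default_factory=set)
    gene_nodes: set = field(default_factory=set)
    table: pd.DataFrame = field(default_factory=pd.DataFrame)
    candidates: list = field(default_factory=list)
    controls: dict = field(default_factory=dict)

    @property
    def dual_role_genes(self) -> set:
        return set(self.controls) & set(self.candidates)


def ipl_outlier_nodes(result: IPLResult, k_sd: float = 2.0) -> set:
    """Nodes with |ipl - median| > k_sd * sd over all finite scores.

    Spread is the sample standard deviation (n-1); all scores identical
    yields an empty set with a warning.
    """
    items = [(n, v) for n, v in result.ipl.items() if np.isfinite(v)]
    if len(items) < 2:
        raise InputError("need at least 2 finite IPL scores")
    scores = np.array([v for _, v in items])
    med = float(np.median(scores))
    sd = float(scores.std(ddof=1))
    if sd == 0.0:
        logger.warning("all IPL scores identical; no outliers")
        return set()
    return {n for n, v in items if abs(v - med) > k_sd * sd}


def expression_filters(
    genes,
    matrix: ExpressionMatrix,
    cv_min: float = 10.0,
    cv_max: float = 200.0,
    min_nonzero_samples: int = 2,
    ipl_scores: dict | None = None,
) -> CandidateSet:
    """Apply the CV band and non-zero-expression filters to ``genes``.

    CV is computed on linear-scale values across all samples. Genes absent
    from the matrix are dropped (logged). A gene with undefined CV
    (non-positive mean) fails the CV flag; it is caught by the non-zero
    filter anyway.
    """
    genes = sorted(set(genes), key=str)
    present = [g for g in genes if g in matrix.values.index]
    if len(present) < len(genes):
        logger.info("%d nominated genes absent from the matrix", len(genes) - len(present))

    rows = []
    for g in present:
        x = matrix.values.loc[g].to_numpy(dtype=float)
        n_nonzero = int((x > 0).sum())
        mean = x.mean()
        if mean > 0 and x.size >= 2:
            cv = float(100.0 * x.std(ddof=1) / mean)
            passed_cv = bool(cv_min <= cv <= cv_max)
        else:
            cv = np.nan
            passed_cv = False
        rows.append(
            {
                "gene": g,
                "ipl": (ipl_scores or {}).get(g, np.nan),
                "cv": cv,
                "n_nonzero": n_nonzero,
                "passed_ipl": True,
                "passed_cv": passed_cv,
                "passed_nonzero": n_nonzero >= min_nonzero_samples,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "gene", "ipl", "cv", "n_nonzero",
            "passed_ipl", "passed_cv", "passed_nonzero",
        ],
    ).set_index("gene")
    passed = table["passed_ipl"] & table["passed_cv"] & table["passed_nonzero"]
    return CandidateSet(
        nominated_nodes=set(genes),
        gene_nodes=set(present),
        table=table,
        candidates=list(table.index[passed]),
    )


def add_controls(
    candidates: CandidateSet,
    negative,
    positive,
    biological,
) -> CandidateSet:
    """Append control genes with roles; the candidate list is unchanged."""
    roles = {}
    for gene, role in (
        [(negative, "negative")]
        + [(g, "positive_viability") for g in positive]
        + [(g, "biological") for g in biological]
    ):
        if gene is None or gene == "":
            raise InputError("control ids must be non-empty")
        if gene in roles and roles[gene] != role:
            raise InputError(f"control {gene!r} given conflicting roles")
        roles[gene] = role
    candidates.controls = {**candidates.controls, **roles}
    dual = candidates.dual_role_genes
    if dual:
        logger.info("controls also nominated as candidates: %s", sorted(dual, key=str))
    return candidates


def nominate_candidates(
    ipl_result: IPLResult,
    graph: PathwayGraph,
    matrix: ExpressionMatrix,
    k_sd: float = 2.0,
    cv_min: float = 10.0,
    cv_max: float = 200.0,
    min_nonzero_samples: int = 2,
) -> CandidateSet:
    """Full chain: IPL outlier cut -> gene-type subset -> expression filters."""
    nominated = ipl_outlier_nodes(ipl_result, k_sd=k_sd)
    gene_nodes = nominated & set(graph.gene_nodes())
    cs = expression_filters(
        gene_nodes,
        matrix,
        cv_min=cv_min,
        cv_max=cv_max,
        min_nonzero_samples=min_nonzero_samples,
        ipl_scores=ipl_result.ipl,
    )
    cs.nominated_nodes = nominated
    cs.gene_nodes = gene_nodes
    return cs
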