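"""Plate-based viability normalization and resistance-specific hit calling.

Raw absorbances are divided by a local-linear (loess-style) spatial surface
fitted over plate row/column positions, then by the plate's negative-control
summary (plate median when no negative controls exist). Hits require a
Wilcoxon q-value below threshold, a minimum kill fraction in the resistant
line, and greater kill in the resistant than the sensitive line.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .errors import InputError, NormalizationError

logger = logging.getLogger(__name__)

__all__ = [
    "NEGATIVE_CONTROL",
    "POSITIVE_CONTROL",
    "EMPTY",
    "Plate",
    "PlateSet",
    "NormalizedViability",
    "HitTable",
    "fit_spatial_surface",
    "normalize_plate",
    "normalize_plates",
    "wilcoxon_rank_sum",
    "call_hits",
]

NEGATIVE_CONTROL = "negative_control"
POSITIVE_CONTROL = "positive_control"
EMPTY = "empty"
_RESERVED = {NEGATIVE_CONTROL, POSITIVE_CONTROL, EMPTY}

FAIL_Q = "q_ge_threshold"
FAIL_KILL = "kill_lt_15pct"
FAIL_DIRECTION = "not_greater_kill"


@dataclass
class Plate:
    """One physical plate: layout plus raw MTS absorbances.

    ``wells`` has columns (row, col, content, raw_mts); content is a gene
    id or one of the reserved labels. raw_mts is NaN exactly for empty
    wells and must be positive elsewhere.
    """

    plate_id: str
    cell_line: str
    replicate: int
    n_rows: int
    n_cols: int
    wells: pd.DataFrame

    def __post_init__(self) -> None:
        w = self.wells
        pos = list(zip(w["row"], w["col"]))
        if len(pos) != len(set(pos)):
            raise InputError(f"plate {self.plate_id}: duplicate well positions")
        if (w["row"] < 0).any() or (w["row"] >= self.n_rows).any():
            raise InputError(f"plate {self.plate_id}: row index out of range")
        if (w["col"] < 0).any() or (w["col"] >= self.n_cols).any():
            raise InputError(f"plate {self.plate_id}: col index out of range")
        occupied = w["content"] != EMPTY
        if w.loc[occupied, "raw_mts"].isna().any():
            raise InputError(f"plate {self.plate_id}: occupied well without raw_mts")
        if (w.loc[occupied, "raw_mts"] <= 0).any():
            raise InputError(f"plate {self.plate_id}: raw_mts must be > 0")
        if w.loc[~occupied, "raw_mts"].notna().any():
            raise InputError(f"plate {self.plate_id}: empty well with raw_mts")

    @property
    def occupied(self) -> pd.DataFrame:
        return self.wells[self.wells["content"] != EMPTY]

    @property
    def fully_occupied(self) -> bool:
        return len(self.occupied) == self.n_rows * self.n_cols

    def gene_wells(self) -> pd.DataFrame:
        return self.wells[~self.wells["content"].isin(_RESERVED)]


@dataclass
class PlateSet:
    plates: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for p in self.plates:
            f = p.wells.copy()
            f.insert(0, "plate_id", p.plate_id)
            f.insert(1, "cell_line", p.cell_line)
            f.insert(2, "replicate", p.replicate)
            frames.append(f)
        return pd.concat(frames, ignore_index=True)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, n_rows: int = 8, n_cols: int = 12):
        plates = []
        for (pid, line, rep), grp in frame.groupby(
            ["plate_id", "cell_line", "replicate"], sort=True
        ):
            plates.append(
                Plate(
                    plate_id=str(pid),
                    cell_line=str(line),
                    replicate=int(rep),
                    n_rows=n_rows,
                    n_cols=n_cols,
                    wells=grp[["row", "col", "content", "raw_mts"]].reset_index(drop=True),
                )
            )
        return cls(plates)


@dataclass
class NormalizedViability:
    """Normalized viabilities: one row per (gene, cell_line, replicate).

    Columns: gene, cell_line, replicate, viability, plate_id, control_basis.
    """

    table: pd.DataFrame

    def for_gene(self, gene, cell_line) -> np.ndarray:
        t = self.table
        sel = (t["gene"] == gene) & (t["cell_line"] == cell_line)
        return t.loc[sel, "viability"].to_numpy(dtype=float)


@dataclass
class HitTable:
    """Per-gene test results; is_hit iff fail_reasons is empty."""

    table: pd.DataFrame
    resistant: str
    sensitive: str
    q_threshold: float
    kill_threshold: float

    @property
    def hits(self) -> list:
        return list(self.table.index[self.table["is_hit"]])


def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.clip(1.0 - np.abs(u) ** 3, 0.0, None) ** 3
    return w


def fit_spatial_surface(plate: Plate, span: float) -> pd.Series:
    """Local linear fit of raw_mts on (row, col); fitted value per occupied well.

    For each occupied well the surface is a weighted linear regression over
    its ceil(span * n) nearest occupied wells (Euclidean distance in
    row/col units) with tricube weights. All occupied wells, controls
    included, participate. A degenerate (collinear) design falls back to a
    global unweighted linear fit with a warning.
    """
    if not (0 < span <= 1):
        raise InputError("span must lie in (0, 1]")
    occ = plate.occupied
    n = len(occ)
    if n < 6:
        raise InputError(f"plate {plate.plate_id}: need >= 6 occupied wells, got {n}")
    rows = occ["row"].to_numpy(dtype=float)
    cols = occ["col"].to_numpy(dtype=float)
    y = occ["raw_mts"].to_numpy(dtype=float)
    design = np.column_stack([np.ones(n), rows, cols])
    k = max(3, math.ceil(span * n))

    global_fit = None
    if np.linalg.matrix_rank(design) < 3:
        logger.warning("plate %s: collinear layout; global linear fallback", plate.plate_id)
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        global_fit = design @ coef

    fitted = np.empty(n)
    for t in range(n):
        if global_fit is not None:
            fitted[t] = global_fit[t]
            continue
        d = np.hypot(rows - rows[t], cols - cols[t])
        nearest = np.argpartition(d, k - 1)[:k]
        dmax = d[nearest].max()
        if dmax == 0:
            fitted[t] = y[nearest].mean()
            continue
        w = _tricube(d[nearest] / dmax)
        pos = w > 0
        a = design[nearest][pos] * np.sqrt(w[pos])[:, None]
        b = y[nearest][pos] * np.sqrt(w[pos])
        if np.linalg.matrix_rank(a) < 3:
            coef, *_ = np.linalg.lstsq(design[nearest], y[nearest], rcond=None)
        else:
            coef, *_ = np.linalg.lstsq(a, b, rcond=None)
        fitted[t] = coef @ design[t]
    return pd.Series(fitted, index=occ.index)


def normalize_plate(
    plate: Plate, full_span: float = 1.0, partial_span: float = 0.2
) -> NormalizedViability:
    """Two-step normalization of one plate.

    Step 1 divides each raw value by its fitted spatial surface value
    (span = ``full_span`` when every well is occupied, else
    ``partial_span``). Step 2 divides by the median step-1 value of the
    plate's negative-control wells; when the plate has none, the plate
    median of step-1 values is used and ``control_basis`` records it.
    Wells with a non-positive fitted value are dropped with a log entry.
    """
    span = full_span if plate.fully_occupied else partial_span
    fitted = fit_spatial_surface(plate, span)
    occ = plate.occupied
    bad = fitted <= 0
    if bad.any():
        logger.warning(
            "plate %s: dropping %d wells with non-positive fitted values",
            plate.plate_id,
            int(bad.sum()),
        )
        occ = occ[~bad]
        fitted = fitted[~bad]
        if occ.empty:
            raise NormalizationError(f"plate {plate.plate_id}: no wells survived")
    step1 = occ["raw_mts"].to_numpy(dtype=float) / fitted.to_numpy(dtype=float)

    is_neg = (occ["content"] == NEGATIVE_CONTROL).to_numpy()
    if is_neg.any():
        basis_value = float(np.median(step1[is_neg]))
        basis = NEGATIVE_CONTROL
    else:
        basis_value = float(np.median(step1))
        basis = "plate_median"
        logger.info("plate %s: no negative controls; plate median basis", plate.plate_id)
    if basis_value <= 0:
        raise NormalizationError(f"plate {plate.plate_id}: non-positive control basis")

    viability = step1 / basis_value
    is_gene = ~occ["content"].isin(_RESERVED)
    table = pd.DataFrame(
        {
            "gene": occ.loc[is_gene, "content"].to_numpy(),
            "cell_line": plate.cell_line,
            "replicate": plate.replicate,
            "viability": viability[is_gene.to_numpy()],
            "plate_id": plate.plate_id,
            "control_basis": basis,
        }
    )
    return NormalizedViability(table=table)


def normalize_plates(
    plates: PlateSet, full_span: float = 1.0, partial_span: float = 0.2
) -> NormalizedViability:
    tables = [
        normalize_plate(p, full_span=full_span, partial_span=partial_span).table
        for p in plates.plates
    ]
    return NormalizedViability(table=pd.concat(tables, ignore_index=True))


def wilcoxon_rank_sum(xs, ys) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact null permutation distribution when total n <= 10 with no ties;
    otherwise the normal approximation with tie and continuity corrections.
    """
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InputError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if pooled.size <= 10 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.pvalue)


def call_hits(
    nv: NormalizedViability,
    resistant: str,
    sensitive: str,
    q_threshold: float = 0.2,
    kill_threshold: float = 0.15,
) -> HitTable:
    """Wilcoxon + BH hit calling with kill-fraction and direction gates.

    Per gene: p from the rank-sum test of resistant vs sensitive replicate
    viabilities; q by BH across all tested genes. A hit needs q below
    ``q_threshold``, resistant mean viability <= 1 - ``kill_threshold``,
    and resistant mean below sensitive mean; failures are recorded in
    ``fail_reasons``. Genes missing a cell line are excluded (logged).
    """
    t = nv.table
    lines = set(t["cell_line"])
    for label in (resistant, sensitive):
        if label not in lines:
            raise InputError(f"cell line {label!r} not present in viability table")

    genes = sorted(set(t["gene"]), key=str)
    rows = []
    excluded = []
    for g in genes:
        res_vals = nv.for_gene(g, resistant)
        sen_vals = nv.for_gene(g, sensitive)
        if res_vals.size == 0 or sen_vals.size == 0:
            excluded.append(g)
            continue
        rows.append(
            {
                "gene": g,
                "mean_viability_resistant": float(res_vals.mean()),
                "mean_viability_sensitive": float(sen_vals.mean()),
                "p_value": wilcoxon_rank_sum(res_vals, sen_vals),
            }
        )
    if excluded:
        logger.warning("excluding %d genes missing a cell line", len(excluded))
    if not rows:
        raise InputError("no genes with replicates in both cell lines")

    table = pd.DataFrame(rows).set_index("gene")
    table["q_value"] = bh_adjust(table["p_value"].to_numpy())

    reasons = []
    for _, r in table.iterrows():
        fr = []
        if not r["q_value"] < q_threshold:
            fr.append(FAIL_Q)
        if not r["mean_viability_resistant"] <= 1.0 - kill_threshold:
            fr.append(FAIL_KILL)
        if not r["mean_viability_resistant"] < r["mean_viability_sensitive"]:
            fr.append(FAIL_DIRECTION)
        reasons.append(fr)
    table["fail_reasons"] = reasons
    table["is_hit"] = [not fr for fr in reasons]
    return HitTable(
        table=table,
        resistant=resistant,
        sensitive=sensitive,
        q_threshold=q_threshold,
        kill_threshold=kill_threshold,
    )
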