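"""Copy-number segmentation and gene-level log2 ratios.

Circular binary segmentation: recursively split each chromosome's ordered
probe log2 ratios at the arc maximizing a pooled two-sample t statistic,
accepting splits whose within-segment permutation p-value clears ``alpha``.
Pruning/undo heuristics of legacy implementations are intentionally absent.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import InputError

logger = logging.getLogger(__name__)

__all__ = [
    "ProbeLogRatio",
    "Segment",
    "GeneModel",
    "GeneCopyNumber",
    "segment_profile",
    "gene_level_log_ratio",
]


@dataclass(frozen=True)
class ProbeLogRatio:
    """One probe's log2 ratio (derived over parental), 0-based half-open."""

    probe_id: str
    chrom: str
    start: int
    end: int
    log2_ratio: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise InputError(f"probe {self.probe_id}: start must be < end")
        if not np.isfinite(self.log2_ratio):
            raise InputError(f"probe {self.probe_id}: log2_ratio must be finite")


@dataclass(frozen=True)
class Segment:
    chrom: str
    start: int
    end: int
    mean_log2: float
    n_probes: int


@dataclass(frozen=True)
class GeneModel:
    """Gene interval (BED convention); strand carried but ignored for overlap."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise InputError(f"gene {self.gene_id}: start must be < end")


@dataclass(frozen=True)
class GeneCopyNumber:
    gene_id: str
    log2_ratio: float
    n_overlapping_segments: int


def _arc_pairs(m: int, min_width: int):
    """All (i, j) arc boundaries with min_width <= j-i <= m-min_width.

    Ordered by (i, arc length) so a first-maximum scan realizes the
    tie-break: smallest left boundary, then smallest arc.
    """
    i, j = np.triu_indices(m + 1, k=min_width)
    keep = (j - i) <= m - min_width
    # flanking remainders must be empty or themselves >= min_width
    keep &= (i == 0) | (i >= min_width)
    keep &= (j == m) | (m - j >= min_width)
    return i[keep], j[keep]


def _max_arc_stat(x: np.ndarray, i: np.ndarray, j: np.ndarray):
    """Best arc split of ``x``: (statistic, i, j) of the first maximum."""
    m = x.size
    s = np.concatenate(([0.0], np.cumsum(x)))
    ss = np.concatenate(([0.0], np.cumsum(x * x)))
    k = (j - i).astype(float)
    l = m - k
    sum_in = s[j] - s[i]
    sum_out = s[m] - sum_in
    ss_in = ss[j] - ss[i]
    ss_out = ss[m] - ss_in
    rss = np.maximum(ss_in - sum_in**2 / k, 0.0) + np.maximum(ss_out - sum_out**2 / l, 0.0)
    diff = np.abs(sum_in / k - sum_out / l)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(rss / (m - 2) * (1.0 / k + 1.0 / l))
        t = diff / se
    t = np.where(se == 0.0, np.where(diff > 0.0, np.inf, 0.0), t)
    best = int(np.argmax(t))
    return float(t[best]), int(i[best]), int(j[best])


def _split_p_value(x, obs_stat, i, j, n_perm, rng) -> float:
    """Permutation p-value of the observed max arc statistic."""
    hits = 0
    for _ in range(n_perm):
        perm_stat, _, _ = _max_arc_stat(rng.permutation(x), i, j)
        if perm_stat >= obs_stat:
            hits += 1
    return (1 + hits) / (1 + n_perm)


def _segment_chromosome(values, alpha, n_perm, min_width, rng):
    """Probe index breakpoints [0, b1, ..., m] for one chromosome."""
    m = values.size
    bounds = {0, m}
    stack = [(0, m)]
    while stack:
        lo, hi = stack.pop()
        seg = values[lo:hi]
        n = seg.size
        if n < 2 * min_width or np.all(seg == seg[0]):
            continue
        i, j = _arc_pairs(n, min_width)
        stat, bi, bj = _max_arc_stat(seg, i, j)
        if stat <= 0.0:
            continue
        p = _split_p_value(seg, stat, i, j, n_perm, rng)
        if p >= alpha:
            continue
        cuts = sorted({lo, lo + bi, lo + bj, hi})
        for a, b in zip(cuts[:-1], cuts[1:]):
            bounds.add(a)
            bounds.add(b)
            stack.append((a, b))
    return sorted(bounds)


def segment_profile(
    probes: list[ProbeLogRatio],
    alpha: float = 0.01,
    n_perm: int = 1000,
    min_width: int = 3,
    seed: int = 0,
) -> list[Segment]:
    """Segment ordered probe log2 ratios into piecewise-constant segments.

    Each chromosome is processed independently. Breakpoint coordinates are
    chosen so segments tile the probed extent exactly: a segment runs from
    its first probe's start to the next segment's first probe start (the
    last segment ends at the last probe's end). Chromosomes with fewer than
    ``2 * min_width`` probes are returned as a single segment.

    Deterministic given ``seed`` (permutation null is seeded per call).
    """
    if not probes:
        return []
    keys = [(p.chrom, p.start) for p in probes]
    if keys != sorted(keys):
        raise InputError("probes must be sorted by (chrom, start)")
    if alpha <= 0 or alpha > 1:
        raise InputError("alpha must lie in (0, 1]")

    rng = np.random.default_rng(seed)
    segments: list[Segment] = []
    chrom_order = []
    by_chrom: dict[str, list[ProbeLogRatio]] = {}
    for p in probes:
        if p.chrom not in by_chrom:
            chrom_order.append(p.chrom)
        by_chrom.setdefault(p.chrom, []).append(p)

    for chrom in chrom_order:
        plist = by_chrom[chrom]
        values = np.array([p.log2_ratio for p in plist], dtype=float)
        bounds = _segment_chromosome(values, alpha, n_perm, min_width, rng)
        for a, b in zip(bounds[:-1], bounds[1:]):
            start = plist[a].start
            end = plist[b].start if b < len(plist) else plist[-1].end
            segments.append(
                Segment(
                    chrom=chrom,
                    start=start,
                    end=end,
                    mean_log2=float(values[a:b].mean()),
                    n_probes=b - a,
                )
            )
    return segments


def gene_level_log_ratio(
    segments: list[Segment], genes: list[GeneModel]
) -> list[GeneCopyNumber]:
    """Overlap-length-weighted mean segment log2 ratio per gene.

    Genes overlapping no segment are omitted (logged).
    """
    by_chrom: dict[str, list[Segment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)

    out: list[GeneCopyNumber] = []
    skipped = 0
    for gene in genes:
        total_w = 0.0
        total = 0.0
        n_overlap = 0
        for seg in by_chrom.get(gene.chrom, ()):
            w = min(gene.end, seg.end) - max(gene.start, seg.start)
            if w > 0:
                total_w += w
                total += w * seg.mean_log2
                n_overlap += 1
        if n_overlap == 0:
            skipped += 1
            continue
        out.append(
            GeneCopyNumber(
                gene_id=gene.gene_id,
                log2_ratio=total / total_w,
                n_overlapping_segments=n_overlap,
            )
        )
    if skipped:
        logger.info("%d genes overlapped no segment and were omitted", skipped)
    return out
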