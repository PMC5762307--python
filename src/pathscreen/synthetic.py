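"""Synthetic inputs with known ground truth for every pipeline stage.

Each data modality draws from its own RNG stream derived from the master
seed, so changing plate parameters never perturbs the expression draws.
Identical configurations (including seed) produce bit-identical outputs.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .copynumber import GeneModel, ProbeLogRatio
from .diffexpr import ExpressionMatrix
from .errors import ConfigurationError, LayoutError
from .ipl import NodeObservation, PathwayGraph
from .screen import EMPTY, NEGATIVE_CONTROL, POSITIVE_CONTROL, Plate, PlateSet

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_expression",
    "simulate_copy_number",
    "simulate_pathway",
    "planted_observations",
    "simulate_gene_models",
    "simulate_screen",
]

# fixed stream indices: plate tweaks must not move expression draws
_STREAMS = {"expression": 0, "copynumber": 1, "pathway": 2, "screen": 3, "observations": 4}

CONDITION_A = "sensitive"
CONDITION_B = "resistant"

PROBE_SPACING = 1000
PROBE_LENGTH = 500


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    # expression
    n_genes: int = 1000
    n_samples_per_condition: int = 3
    de_fraction: float = 0.05
    de_log2fc: float = 2.0
    expr_noise_sd: float = 0.25
    # copy number
    n_probes: int = 100
    cn_events: tuple = ()  # (chrom, start_probe, end_probe, log2_shift)
    probe_noise_sd: float = 0.2
    # pathway
    graph_n_nodes: int = 60
    graph_edge_prob: float = 0.05
    planted_subnetwork_size: int = 8
    gene_node_fraction: float = 0.75
    # screen
    plate_rows: int = 8
    plate_cols: int = 12
    gradient_amplitude: float = 0.3
    gradient_bump: float = 0.0
    kill_effect_resistant: float = 0.4
    kill_effect_sensitive: float = 0.05
    positive_control_kill: float = 0.8
    n_planted_hits: int = 10
    well_noise_cv: float = 0.05

    def validate(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_samples_per_condition": self.n_samples_per_condition,
            "n_probes": self.n_probes,
            "graph_n_nodes": self.graph_n_nodes,
            "planted_subnetwork_size": self.planted_subnetwork_size,
            "plate_rows": self.plate_rows,
            "plate_cols": self.plate_cols,
        }
        for name, v in counts.items():
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise ConfigurationError(f"{name} must be a positive integer")
        proportions = {
            "de_fraction": self.de_fraction,
            "graph_edge_prob": self.graph_edge_prob,
            "gene_node_fraction": self.gene_node_fraction,
            "kill_effect_resistant": self.kill_effect_resistant,
            "kill_effect_sensitive": self.kill_effect_sensitive,
            "positive_control_kill": self.positive_control_kill,
            "well_noise_cv": self.well_noise_cv,
        }
        for name, v in proportions.items():
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        for name in ("expr_noise_sd", "probe_noise_sd", "gradient_amplitude"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.planted_subnetwork_size > self.graph_n_nodes:
            raise ConfigurationError(
                "planted_subnetwork_size must not exceed graph_n_nodes"
            )
        if self.n_planted_hits < 0:
            raise ConfigurationError("n_planted_hits must be >= 0")
        self._validate_events()

    def _validate_events(self) -> None:
        by_chrom: dict = {}
        for ev in self.cn_events:
            chrom, start, end, _shift = ev
            if not (0 <= start < end <= self.n_probes):
                raise ConfigurationError(
                    f"cn_events: probe range [{start}, {end}) outside [0, {self.n_probes})"
                )
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, spans in by_chrom.items():
            spans.sort()
            for (s1, e1), (s2, _e2) in zip(spans[:-1], spans[1:]):
                if s2 < e1:
                    raise ConfigurationError(f"cn_events overlap on {chrom}")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAMS[stream]])

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class GroundTruth:
    """Planted effects; only the fields of the simulated modality are filled."""

    de_genes: dict = field(default_factory=dict)  # gene -> signed log2fc
    cn_segments: list = field(default_factory=list)  # (chrom, start_probe, end_probe, shift)
    active_nodes: set = field(default_factory=set)
    true_hits: dict = field(default_factory=dict)  # gene -> (eff_resistant, eff_sensitive)

    def to_dict(self) -> dict:
        return {
            "de_genes": {str(k): float(v) for k, v in self.de_genes.items()},
            "cn_segments": [list(s) for s in self.cn_segments],
            "active_nodes": sorted(str(n) for n in self.active_nodes),
            "true_hits": {str(k): list(v) for k, v in self.true_hits.items()},
        }


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def simulate_expression(config: SimulationConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Two conditions x n replicates of log-normal abundances.

    Non-DE genes share a condition-independent log2 mean; DE genes are
    shifted by +/- de_log2fc in the resistant condition. Noise is Gaussian
    on the log2 scale.
    """
    config.validate()
    rng = config.rng("expression")
    genes = _gene_ids(config.n_genes)
    n_rep = config.n_samples_per_condition

    base = rng.uniform(4.0, 9.0, size=config.n_genes)
    n_de = int(round(config.de_fraction * config.n_genes))
    de_idx = rng.choice(config.n_genes, size=n_de, replace=False) if n_de else np.array([], int)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    shift = np.zeros(config.n_genes)
    shift[de_idx] = signs * config.de_log2fc

    samples = [f"{CONDITION_A}_r{r}" for r in range(1, n_rep + 1)] + [
        f"{CONDITION_B}_r{r}" for r in range(1, n_rep + 1)
    ]
    mu = np.column_stack([base] * n_rep + [base + shift] * n_rep)
    noise = rng.normal(0.0, config.expr_noise_sd, size=mu.shape)
    values = np.power(2.0, mu + noise)

    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples),
        condition_of=pd.Series(
            [CONDITION_A] * n_rep + [CONDITION_B] * n_rep, index=samples
        ),
        replicate_of=pd.Series(list(range(1, n_rep + 1)) * 2, index=samples),
    )
    truth = GroundTruth(
        de_genes={genes[i]: float(shift[i]) for i in sorted(de_idx)}
    )
    return matrix, truth


def _probe_chroms(config: SimulationConfig) -> list[str]:
    chroms = sorted({ev[0] for ev in config.cn_events})
    return chroms if chroms else ["chr1"]


def simulate_copy_number(config: SimulationConfig) -> tuple[list[ProbeLogRatio], GroundTruth]:
    """Piecewise-constant probe log2-ratio profiles with Gaussian noise.

    Each chromosome named in ``cn_events`` (or chr1 when none) carries
    ``n_probes`` evenly spaced probes; probe i spans
    [i*1000, i*1000 + 500), 0-based half-open.
    """
    config.validate()
    rng = config.rng("copynumber")
    probes: list[ProbeLogRatio] = []
    for chrom in _probe_chroms(config):
        values = np.zeros(config.n_probes)
        for ev_chrom, start, end, delta in config.cn_events:
            if ev_chrom == chrom:
                values[start:end] += delta
        values = values + rng.normal(0.0, config.probe_noise_sd, size=config.n_probes)
        for i in range(config.n_probes):
            probes.append(
                ProbeLogRatio(
                    probe_id=f"{chrom}_p{i:05d}",
                    chrom=chrom,
                    start=i * PROBE_SPACING,
                    end=i * PROBE_SPACING + PROBE_LENGTH,
                    log2_ratio=float(values[i]),
                )
            )
    truth = GroundTruth(cn_segments=[tuple(ev) for ev in config.cn_events])
    return probes, truth


def simulate_gene_models(config: SimulationConfig) -> list[GeneModel]:
    """Deterministic gene intervals tiling the probed extent.

    Genes cycle across the probed chromosomes; each spans two probe
    spacings so it overlaps real probe territory.
    """
    config.validate()
    chroms = _probe_chroms(config)
    extent = config.n_probes * PROBE_SPACING
    span = 2 * PROBE_SPACING
    genes = []
    for k, gid in enumerate(_gene_ids(config.n_genes)):
        chrom = chroms[k % len(chroms)]
        start = (k // len(chroms)) * span % max(extent - span, span)
        genes.append(GeneModel(gene_id=gid, chrom=chrom, start=start, end=start + span))
    return genes


def simulate_pathway(config: SimulationConfig) -> tuple[PathwayGraph, GroundTruth]:
    """Connected signed directed graph with a flagged planted subnetwork.

    A random recursive tree guarantees connectivity; extra edges appear
    with probability ``graph_edge_prob``. Gene-type nodes reuse the
    expression gene ids so the modalities line up downstream. Edges inside
    the planted subnetwork are activating (+1) so positive evidence on its
    members coheres.
    """
    config.validate()
    rng = config.rng("pathway")
    n = config.graph_n_nodes
    n_gene = max(1, int(round(config.gene_node_fraction * n))) if n > 1 else 1
    gene_ids = _gene_ids(max(config.n_genes, n_gene))[:n_gene]
    other_types = ["complex", "family", "abstract"]
    node_list = [(g, "gene") for g in gene_ids] + [
        (f"N{i:04d}", other_types[i % 3]) for i in range(n - n_gene)
    ]
    order = rng.permutation(n)
    node_list = [node_list[i] for i in order]
    ids = [nid for nid, _ in node_list]

    edges = []
    edge_set = set()
    for i in range(1, n):
        j = int(rng.integers(0, i))
        edges.append((ids[j], ids[i]))
        edge_set.add(frozenset((ids[j], ids[i])))
    if config.graph_edge_prob > 0 and n > 2:
        for i in range(n):
            for j in range(i + 1, n):
                key = frozenset((ids[i], ids[j]))
                if key in edge_set:
                    continue
                if rng.random() < config.graph_edge_prob:
                    if rng.random() < 0.5:
                        edges.append((ids[i], ids[j]))
                    else:
                        edges.append((ids[j], ids[i]))
                    edge_set.add(key)

    # planted subnetwork: BFS over the undirected view from a random start
    adjacency: dict = {nid: set() for nid in ids}
    for u, v in edges:
        adjacency[u].add(v)
        adjacency[v].add(u)
    start = ids[int(rng.integers(0, n))]
    active = [start]
    active_set = {start}
    frontier = [start]
    while len(active) < config.planted_subnetwork_size and frontier:
        node = frontier.pop(0)
        for nb in sorted(adjacency[node], key=str):
            if nb not in active_set:
                active.append(nb)
                active_set.add(nb)
                frontier.append(nb)
                if len(active) == config.planted_subnetwork_size:
                    break
    if len(active) < config.planted_subnetwork_size:
        raise ConfigurationError(
            "planted_subnetwork_size unreachable: graph component too small"
        )

    kinds = ["transcriptional", "component", "member", "other"]
    typed_edges = []
    for u, v in edges:
        if u in active_set and v in active_set:
            sign = 1
        else:
            sign = -1 if rng.random() < 0.3 else 1
        kind = kinds[int(rng.integers(0, len(kinds)))]
        if kind in ("component", "member"):
            sign = 1
        typed_edges.append((u, v, sign, kind))

    graph = PathwayGraph.build(node_list, typed_edges)
    return graph, GroundTruth(active_nodes=active_set)


def planted_observations(
    config: SimulationConfig,
    graph: PathwayGraph,
    truth: GroundTruth,
    z_active: float = 2.0,
    z_noise_sd: float = 0.5,
) -> list[NodeObservation]:
    """Expression z-scores that make the planted subnetwork stand out.

    Gene members of the planted subnetwork get z = ``z_active``; the other
    gene nodes draw z ~ N(0, z_noise_sd). Non-gene nodes carry no evidence.
    """
    rng = config.rng("observations")
    obs = []
    for g in graph.gene_nodes():
        if g in truth.active_nodes:
            z = z_active
        else:
            z = float(rng.normal(0.0, z_noise_sd))
        obs.append(NodeObservation(node_id=g, z_expr=z))
    return obs


def _control_positions(n_rows: int, n_cols: int):
    neg = [(0, 0), (0, n_cols - 1), (n_rows - 1, 0), (n_rows - 1, n_cols - 1)]
    pos = [(0, 1), (n_rows - 1, n_cols - 2)]
    return neg, pos


def _spatial_surface(config: SimulationConfig, row, col) -> float:
    r = row / max(config.plate_rows - 1, 1) - 0.5
    c = col / max(config.plate_cols - 1, 1) - 0.5
    surface = 1.0 + config.gradient_amplitude * (r + c)
    if config.gradient_bump:
        surface += config.gradient_bump * float(np.exp(-(r * r + c * c) / 0.08))
    return surface


def simulate_screen(
    config: SimulationConfig, genes: list, plantable: list | None = None
) -> tuple[PlateSet, GroundTruth]:
    """One plate per (cell line, replicate) with planted differential kill.

    ``plantable`` restricts which genes may receive a planted kill effect
    (defaults to all of ``genes``); useful when filler wells are screened
    purely to keep the plate occupied.

    Raw MTS = base * (1 - kill) * spatial_surface(row, col) * noise, with
    log-normal multiplicative noise of coefficient of variation
    ``well_noise_cv``. Four negative-control wells (zero kill) and two
    positive-control wells (strong kill in both lines) sit at fixed
    corner/edge positions; genes fill the remaining wells row-major and
    left-over wells stay empty.
    """
    config.validate()
    genes = list(genes)
    if not genes:
        raise LayoutError("genes must be non-empty")
    if len(set(genes)) != len(genes):
        raise LayoutError("duplicate gene ids in screen layout")
    rng = config.rng("screen")
    n_rows, n_cols = config.plate_rows, config.plate_cols
    neg_pos, pos_pos = _control_positions(n_rows, n_cols)
    control_positions = set(neg_pos) | set(pos_pos)
    capacity = n_rows * n_cols - len(control_positions)
    if len(genes) > capacity:
        raise LayoutError(
            f"{len(genes)} genes exceed plate capacity {capacity} "
            f"({n_rows}x{n_cols} minus {len(control_positions)} control wells)"
        )

    pool = genes if plantable is None else [g for g in genes if g in set(plantable)]
    n_hits = min(config.n_planted_hits, len(pool))
    hit_idx = rng.choice(len(pool), size=n_hits, replace=False)
    true_hits = {
        pool[i]: (config.kill_effect_resistant, config.kill_effect_sensitive)
        for i in sorted(hit_idx)
    }

    kill = {
        "resistant": {g: 0.0 for g in genes},
        "sensitive": {g: 0.0 for g in genes},
    }
    for g, (er, es) in true_hits.items():
        kill["resistant"][g] = er
        kill["sensitive"][g] = es
    positive_kill = config.positive_control_kill
    base = 1.0
    sigma = float(np.sqrt(np.log1p(config.well_noise_cv**2)))

    gene_positions = [
        (r, c)
        for r in range(n_rows)
        for c in range(n_cols)
        if (r, c) not in control_positions
    ]

    plates = []
    for line in ("resistant", "sensitive"):
        for rep in (1, 2, 3):
            rows = []
            layout = {}
            for p in neg_pos:
                layout[p] = NEGATIVE_CONTROL
            for p in pos_pos:
                layout[p] = POSITIVE_CONTROL
            for g, p in zip(genes, gene_positions):
                layout[p] = g
            for r in range(n_rows):
                for c in range(n_cols):
                    content = layout.get((r, c), EMPTY)
                    if content == EMPTY:
                        raw = np.nan
                    else:
                        if content == NEGATIVE_CONTROL:
                            k = 0.0
                        elif content == POSITIVE_CONTROL:
                            k = positive_kill
                        else:
                            k = kill[line][content]
                        noise = (
                            float(np.exp(rng.normal(-sigma * sigma / 2.0, sigma)))
                            if sigma > 0
                            else 1.0
                        )
                        raw = base * (1.0 - k) * _spatial_surface(config, r, c) * noise
                    rows.append({"row": r, "col": c, "content": content, "raw_mts": raw})
            plates.append(
                Plate(
                    plate_id=f"{line}_rep{rep}",
                    cell_line=line,
                    replicate=rep,
                    n_rows=n_rows,
                    n_cols=n_cols,
                    wells=pd.DataFrame(rows),
                )
            )
    return PlateSet(plates), GroundTruth(true_hits=true_hits)
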