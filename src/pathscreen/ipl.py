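"""Integrated pathway level (IPL) scoring on a signed pathway graph.

Each node carries a ternary activity state s in {-1, 0, +1}. Evidence from
expression and copy number enters through a node factor
phi(s) = exp(s * (beta_expr * z + beta_cn * c)); every edge couples its
endpoint states through psi(s_u, s_v) = exp(lambda_edge * sign * s_u * s_v).
Marginal beliefs come from damped sum-product message passing (exact on
trees); the IPL of a node is log10 of its active/inactive belief ratio, so
a node's score reflects both its own data and its neighbours' scores.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import networkx as nx

from .errors import InputError, SizeError

logger = logging.getLogger(__name__)

__all__ = [
    "PathwayGraph",
    "NodeObservation",
    "IPLParams",
    "IPLResult",
    "build_observations",
    "infer_ipl",
    "exact_ipl",
    "first_neighbor_subnetwork",
]

NODE_TYPES = ("gene", "complex", "family", "abstract")
EDGE_KINDS = ("transcriptional", "component", "member", "other")

_STATES = np.array([-1.0, 0.0, 1.0])


@dataclass
class PathwayGraph:
    """Typed nodes and signed directed edges wrapped around a DiGraph.

    Node attribute ``node_type`` in {gene, complex, family, abstract};
    edge attributes ``sign`` in {+1, -1} and ``kind``.
    """

    graph: nx.DiGraph

    def __post_init__(self) -> None:
        for n, data in self.graph.nodes(data=True):
            if data.get("node_type") not in NODE_TYPES:
                raise InputError(f"node {n!r}: missing or invalid node_type")
        for u, v, data in self.graph.edges(data=True):
            if u == v:
                raise InputError(f"self-loop on node {u!r}")
            if data.get("sign") not in (1, -1):
                raise InputError(f"edge {u!r}->{v!r}: sign must be +1 or -1")

    @classmethod
    def build(cls, nodes, edges) -> "PathwayGraph":
        """From (id, node_type) pairs and (source, target, sign, kind) tuples."""
        g = nx.DiGraph()
        seen = set()
        for node_id, node_type in nodes:
            if node_id in seen:
                raise InputError(f"duplicate node id {node_id!r}")
            seen.add(node_id)
            g.add_node(node_id, node_type=node_type)
        for u, v, sign, kind in edges:
            if u not in seen or v not in seen:
                raise InputError(f"edge {u!r}->{v!r} references unknown node")
            g.add_edge(u, v, sign=int(sign), kind=kind)
        return cls(g)

    @property
    def node_ids(self) -> list:
        return list(self.graph.nodes)

    def gene_nodes(self) -> list:
        return [n for n, d in self.graph.nodes(data=True) if d["node_type"] == "gene"]

    def subgraph(self, nodes) -> "PathwayGraph":
        return PathwayGraph(self.graph.subgraph(nodes).copy())


@dataclass(frozen=True)
class NodeObservation:
    """Evidence attached to a gene node; either channel may be absent."""

    node_id: object
    z_expr: float | None = None
    c_cn: float | None = None

    def __post_init__(self) -> None:
        for name, v in (("z_expr", self.z_expr), ("c_cn", self.c_cn)):
            if v is not None and not np.isfinite(v):
                raise InputError(f"observation for {self.node_id!r}: {name} not finite")


@dataclass(frozen=True)
class IPLParams:
    beta_expr: float = 1.0
    beta_cn: float = 1.0
    lambda_edge: float = 0.5
    max_iter: int = 500
    damping: float = 0.5
    tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.beta_expr < 0 or self.beta_cn < 0 or self.lambda_edge < 0:
            raise InputError("coupling weights must be >= 0")
        if not (0 <= self.damping < 1):
            raise InputError("damping must lie in [0, 1)")
        if self.tol <= 0:
            raise InputError("tol must be > 0")


@dataclass
class IPLResult:
    """Per-node IPL scores (log10 odds of active vs inactive) and beliefs."""

    ipl: dict
    beliefs: dict
    converged: bool = True
    n_iter: int = 0

    def as_array(self, nodes) -> np.ndarray:
        return np.array([self.ipl[n] for n in nodes], dtype=float)


def _node_fields(graph: PathwayGraph, obs, params: IPLParams) -> dict:
    """Evidence field h_n = beta_expr * z + beta_cn * c (missing -> 0)."""
    known = set(graph.graph.nodes)
    h = {n: 0.0 for n in known}
    for o in obs:
        if o.node_id not in known:
            raise InputError(f"observation for unknown node {o.node_id!r}")
        v = 0.0
        if o.z_expr is not None:
            v += params.beta_expr * o.z_expr
        if o.c_cn is not None:
            v += params.beta_cn * o.c_cn
        h[o.node_id] += v
    return h


def _pair_couplings(graph: PathwayGraph, params: IPLParams) -> dict:
    """Undirected coupling J_uv = lambda_edge * sum of edge signs."""
    J: dict = {}
    for u, v, data in graph.graph.edges(data=True):
        key = (u, v) if str(u) <= str(v) else (v, u)
        J[key] = J.get(key, 0.0) + params.lambda_edge * data["sign"]
    return J


def _result_from_beliefs(beliefs: dict, converged: bool, n_iter: int) -> IPLResult:
    ipl = {}
    for n, b in beliefs.items():
        with np.errstate(divide="ignore"):
            ipl[n] = float(np.log10(b[2]) - np.log10(b[0]))
    return IPLResult(ipl=ipl, beliefs=beliefs, converged=converged, n_iter=n_iter)


def infer_ipl(graph: PathwayGraph, obs, params: IPLParams | None = None) -> IPLResult:
    """Sum-product marginals on the pairwise model; IPL = log10 b(+1)/b(-1).

    Damped sequential message passing; the schedule is sorted by
    (source id, target id) for determinism. Exact on trees; approximate on
    loopy graphs. Non-convergence is reported via ``converged=False``.
    """
    if params is None:
        params = IPLParams()
    if graph.graph.number_of_nodes() == 0:
        raise InputError("empty graph")
    h = _node_fields(graph, obs, params)
    J = _pair_couplings(graph, params)

    phi = {n: np.exp(_STATES * h[n]) for n in graph.graph.nodes}
    psi = {key: np.exp(j * np.outer(_STATES, _STATES)) for key, j in J.items()}

    neighbors: dict = {n: [] for n in graph.graph.nodes}
    for u, v in J:
        neighbors[u].append(v)
        neighbors[v].append(u)

    messages = {}
    for u, v in J:
        messages[(u, v)] = np.full(3, 1.0 / 3.0)
        messages[(v, u)] = np.full(3, 1.0 / 3.0)
    schedule = sorted(messages, key=lambda e: (str(e[0]), str(e[1])))

    converged = False
    n_iter = 0
    for n_iter in range(1, params.max_iter + 1):
        delta = 0.0
        for u, v in schedule:
            prod = phi[u].copy()
            for w in neighbors[u]:
                if w != v:
                    prod = prod * messages[(w, u)]
            key = (u, v) if str(u) <= str(v) else (v, u)
            mat = psi[key]
            new = prod @ mat if key == (u, v) else mat @ prod
            new = new / new.sum()
            new = params.damping * messages[(u, v)] + (1 - params.damping) * new
            delta = max(delta, float(np.abs(new - messages[(u, v)]).max()))
            messages[(u, v)] = new
        if delta < params.tol:
            converged = True
            break
    if messages and not converged:
        logger.warning("sum-product did not converge in %d iterations", params.max_iter)
    if not messages:
        converged = True

    beliefs = {}
    for n in graph.graph.nodes:
        b = phi[n].copy()
        for w in neighbors[n]:
            b = b * messages[(w, n)]
        beliefs[n] = b / b.sum()
    return _result_from_beliefs(beliefs, converged, n_iter)


def exact_ipl(graph: PathwayGraph, obs, params: IPLParams | None = None) -> IPLResult:
    """Exact marginals by exhaustive 3^n enumeration (oracle; n <= 12)."""
    if params is None:
        params = IPLParams()
    nodes = list(graph.graph.nodes)
    n = len(nodes)
    if n == 0:
        raise InputError("empty graph")
    if n > 12:
        raise SizeError(f"exact enumeration limited to 12 nodes, got {n}")
    index = {node: k for k, node in enumerate(nodes)}
    h = _node_fields(graph, obs, params)
    J = _pair_couplings(graph, params)

    marginals = {node: np.zeros(3) for node in nodes}
    hvec = np.array([h[node] for node in nodes])
    pairs = [(index[u], index[v], j) for (u, v), j in J.items()]
    for states in itertools.product((-1.0, 0.0, 1.0), repeat=n):
        s = np.array(states)
        logw = float(hvec @ s) + sum(j * s[a] * s[b] for a, b, j in pairs)
        w = np.exp(logw)
        for k, node in enumerate(nodes):
            marginals[node][int(states[k]) + 1] += w
    beliefs = {node: m / m.sum() for node, m in marginals.items()}
    return _result_from_beliefs(beliefs, converged=True, n_iter=0)


def build_observations(de, cn, graph: PathwayGraph) -> list[NodeObservation]:
    """Map differential expression and gene-level copy number onto gene nodes.

    z_expr is each matched gene's log2 fold change divided by the robust
    scale (MAD x 1.4826) of all matched fold changes; c_cn passes through
    unstandardized. Unmatched ids are logged; no expression match at all is
    an error.
    """
    gene_node_set = set(graph.gene_nodes())
    de_genes = [g for g in de.table.index if g in gene_node_set]
    if not de_genes:
        raise InputError("no expression gene ids match gene-type graph nodes")
    n_unmatched = len(de.table.index) - len(de_genes)
    if n_unmatched:
        logger.info("%d expression genes not present in the graph", n_unmatched)

    diffs = de.table.loc[de_genes, "log2fc"].to_numpy(dtype=float)
    mad = float(np.median(np.abs(diffs - np.median(diffs))))
    scale = mad * 1.4826
    if scale == 0.0:
        scale = float(diffs.std(ddof=1)) if diffs.size > 1 else 0.0
    if scale == 0.0:
        scale = 1.0
        logger.warning("degenerate fold-change spread; z scale fixed at 1")
    z = {g: d / scale for g, d in zip(de_genes, diffs)}

    c = {}
    for record in cn:
        if record.gene_id in gene_node_set:
            c[record.gene_id] = record.log2_ratio

    out = []
    for g in sorted(set(z) | set(c), key=str):
        out.append(NodeObservation(node_id=g, z_expr=z.get(g), c_cn=c.get(g)))
    return out


def first_neighbor_subnetwork(graph: PathwayGraph, seeds) -> PathwayGraph:
    """Induced subgraph on seeds plus their in/out neighbours."""
    seeds = set(seeds)
    unknown = seeds - set(graph.graph.nodes)
    if unknown:
        raise InputError(f"unknown seed ids: {sorted(unknown, key=str)}")
    keep = set(seeds)
    for s in seeds:
        keep.update(graph.graph.successors(s))
        keep.update(graph.graph.predecessors(s))
    return graph.subgraph(keep)
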