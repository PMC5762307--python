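import numpy as np
import pandas as pd
import pytest

from pathscreen import (
    ExpressionMatrix,
    NodeObservation,
    PathwayGraph,
    Plate,
    SimulationConfig,
)


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    samples = ["a1", "a2", "a3", "b1", "b2", "b3"]
    values = pd.DataFrame(
        {
            "a1": [10.0, 5.0, 100.0],
            "a2": [12.0, 6.0, 110.0],
            "a3": [11.0, 4.0, 90.0],
            "b1": [40.0, 5.5, 95.0],
            "b2": [45.0, 4.5, 105.0],
            "b3": [50.0, 5.0, 100.0],
        },
        index=pd.Index(["g1", "g2", "g3"], name="gene"),
    )
    return ExpressionMatrix(
        values=values,
        condition_of=pd.Series(["A"] * 3 + ["B"] * 3, index=samples),
        replicate_of=pd.Series([1, 2, 3, 1, 2, 3], index=samples),
    )


def make_plate(
    raw,
    contents=None,
    plate_id="p1",
    cell_line="resistant",
    replicate=1,
    n_rows=None,
    n_cols=None,
) -> Plate:
    """Plate from a 2-D raw array; contents defaults to one gene per well."""
    raw = np.asarray(raw, dtype=float)
    n_rows = n_rows or raw.shape[0]
    n_cols = n_cols or raw.shape[1]
    rows = []
    for r in range(raw.shape[0]):
        for c in range(raw.shape[1]):
            content = contents[r][c] if contents is not None else f"gene_{r}_{c}"
            value = raw[r, c] if content != "empty" else np.nan
            rows.append({"row": r, "col": c, "content": content, "raw_mts": value})
    return Plate(
        plate_id=plate_id,
        cell_line=cell_line,
        replicate=replicate,
        n_rows=n_rows,
        n_cols=n_cols,
        wells=pd.DataFrame(rows),
    )


def chain_graph(signs, node_type="gene") -> PathwayGraph:
    """Path graph n0 -> n1 -> ... with the given edge signs."""
    nodes = [(f"n{i}", node_type) for i in range(len(signs) + 1)]
    edges = [(f"n{i}", f"n{i+1}", s, "other") for i, s in enumerate(signs)]
    return PathwayGraph.build(nodes, edges)


def random_tree_graph(seed, n_extra_chords=0, min_loop=4):
    """Random tree (optionally plus chords closing loops of >= min_loop)."""
    import networkx as nx

    r = np.random.default_rng(seed)
    n = int(r.integers(5, 9))
    nodes = [(f"n{i}", "gene") for i in range(n)]
    parents = [int(r.integers(0, i)) for i in range(1, n)]
    edges = [
        (f"n{p}", f"n{i}", int(r.choice([-1, 1])), "other")
        for i, p in zip(range(1, n), parents)
    ]
    tree = nx.Graph([(p, i) for i, p in zip(range(1, n), parents)])
    cand = [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if not tree.has_edge(i, j)
        and nx.shortest_path_length(tree, i, j) >= min_loop - 1
    ]
    r.shuffle(cand)
    for i, j in cand[:n_extra_chords]:
        edges.append((f"n{i}", f"n{j}", int(r.choice([-1, 1])), "other"))
    graph = PathwayGraph.build(nodes, edges)
    obs = [
        NodeObservation(f"n{i}", z_expr=float(z))
        for i, z in enumerate(r.normal(0.0, 1.0, size=n))
    ]
    return graph, obs


@pytest.fixture
def base_config() -> SimulationConfig:
    return SimulationConfig(seed=1, n_genes=100)
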