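"""Readers and writers for the pipeline's plain-text formats.

Expression TSV + sample annotations, probe TSV, SEG, BED6, the
tab-delimited pathway interaction file, SIF + node attributes, plate CSV,
and the ground-truth JSON.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .copynumber import GeneCopyNumber, GeneModel, ProbeLogRatio, Segment
from .diffexpr import ExpressionMatrix
from .errors import InputError
from .ipl import IPLResult, PathwayGraph
from .screen import HitTable, NormalizedViability, PlateSet
from .synthetic import GroundTruth

__all__ = [
    "write_expression", "read_expression",
    "write_probes", "read_probes",
    "write_seg", "write_gene_cn", "read_gene_cn",
    "write_bed", "read_bed",
    "write_pathway", "read_pathway",
    "write_sif", "write_node_attributes",
    "write_plates", "read_plates",
    "write_truth", "read_truth",
    "write_diffexpr_table", "write_viability", "write_hits", "write_candidates",
]


# -- expression ---------------------------------------------------------------

def write_expression(matrix: ExpressionMatrix, values_path, annotations_path) -> None:
    matrix.values.to_csv(values_path, sep="\t")
    ann = pd.DataFrame(
        {
            "sample": list(matrix.values.columns),
            "condition": [matrix.condition_of[s] for s in matrix.values.columns],
            "replicate": [matrix.replicate_of[s] for s in matrix.values.columns],
        }
    )
    ann.to_csv(annotations_path, sep="\t", index=False)


def read_expression(values_path, annotations_path) -> ExpressionMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    ann = pd.read_csv(annotations_path, sep="\t", dtype={"sample": str})
    ann = ann.set_index("sample")
    return ExpressionMatrix(
        values=values,
        condition_of=ann["condition"],
        replicate_of=ann["replicate"],
    )


# -- copy number --------------------------------------------------------------

def write_probes(probes: list[ProbeLogRatio], path) -> None:
    pd.DataFrame(
        {
            "probe_id": [p.probe_id for p in probes],
            "chrom": [p.chrom for p in probes],
            "start": [p.start for p in probes],
            "end": [p.end for p in probes],
            "log2_ratio": [p.log2_ratio for p in probes],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_probes(path) -> list[ProbeLogRatio]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return [
        ProbeLogRatio(
            probe_id=str(r.probe_id),
            chrom=str(r.chrom),
            start=int(r.start),
            end=int(r.end),
            log2_ratio=float(r.log2_ratio),
        )
        for r in df.itertuples()
    ]


def write_seg(segments: list[Segment], path, sample: str = "derived_vs_parental") -> None:
    pd.DataFrame(
        {
            "sample": sample,
            "chrom": [s.chrom for s in segments],
            "start": [s.start for s in segments],
            "end": [s.end for s in segments],
            "n_probes": [s.n_probes for s in segments],
            "mean_log2": [s.mean_log2 for s in segments],
        }
    ).to_csv(path, sep="\t", index=False)


def write_gene_cn(records: list[GeneCopyNumber], path) -> None:
    pd.DataFrame(
        {
            "gene": [r.gene_id for r in records],
            "log2_ratio": [r.log2_ratio for r in records],
            "n_overlapping_segments": [r.n_overlapping_segments for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def read_gene_cn(path) -> list[GeneCopyNumber]:
    df = pd.read_csv(path, sep="\t")
    return [
        GeneCopyNumber(
            gene_id=str(r.gene),
            log2_ratio=float(r.log2_ratio),
            n_overlapping_segments=int(r.n_overlapping_segments),
        )
        for r in df.itertuples()
    ]


def write_bed(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def read_bed(path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise InputError(f"BED line with fewer than 4 fields: {line!r}")
            strand = parts[5] if len(parts) >= 6 else "+"
            genes.append(
                GeneModel(
                    gene_id=parts[3],
                    chrom=parts[0],
                    start=int(parts[1]),
                    end=int(parts[2]),
                    strand=strand,
                )
            )
    return genes


# -- pathway ------------------------------------------------------------------

def write_pathway(graph: PathwayGraph, path) -> None:
    """Tab-delimited interaction file: node lines then edge lines."""
    with open(path, "w") as fh:
        for n, data in graph.graph.nodes(data=True):
            fh.write(f"{data['node_type']}\t{n}\n")
        for u, v, data in graph.graph.edges(data=True):
            fh.write(f"{u}\t{v}\t{data['kind']}\t{data['sign']:+d}\n")


def read_pathway(path) -> PathwayGraph:
    nodes, edges = [], []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) == 2:
                nodes.append((parts[1], parts[0]))
            elif len(parts) == 4:
                edges.append((parts[0], parts[1], int(parts[3]), parts[2]))
            else:
                raise InputError(f"malformed pathway line: {line!r}")
    return PathwayGraph.build(nodes, edges)


def write_sif(graph: PathwayGraph, path) -> None:
    """SIF export; the relation encodes kind and sign (e.g. activates)."""
    with open(path, "w") as fh:
        connected = set()
        for u, v, data in graph.graph.edges(data=True):
            rel = "activates" if data["sign"] > 0 else "inhibits"
            fh.write(f"{u}\t{rel}-{data['kind']}\t{v}\n")
            connected.add(u)
            connected.add(v)
        for n in graph.graph.nodes:
            if n not in connected:
                fh.write(f"{n}\n")


def write_node_attributes(result: IPLResult, path) -> None:
    pd.DataFrame(
        {"id": list(result.ipl), "ipl": [result.ipl[n] for n in result.ipl]}
    ).to_csv(path, sep="\t", index=False)


# -- screen -------------------------------------------------------------------

def write_plates(plates: PlateSet, path) -> None:
    plates.to_frame().to_csv(path, index=False)


def read_plates(path, n_rows: int = 8, n_cols: int = 12) -> PlateSet:
    frame = pd.read_csv(path)
    return PlateSet.from_frame(frame, n_rows=n_rows, n_cols=n_cols)


def write_viability(nv: NormalizedViability, path) -> None:
    nv.table.to_csv(path, sep="\t", index=False)


def write_hits(hits: HitTable, path) -> None:
    out = hits.table.copy()
    out["fail_reasons"] = [";".join(fr) for fr in out["fail_reasons"]]
    out.to_csv(path, sep="\t")


# -- misc tables --------------------------------------------------------------

def write_diffexpr_table(result, path) -> None:
    out = result.table.rename(columns={"p_value": "p", "q_value": "q"})
    out.to_csv(path, sep="\t")


def write_candidates(candidates, path) -> None:
    out = candidates.table.copy()
    out["role"] = [candidates.controls.get(g, "") for g in out.index]
    control_only = [g for g in candidates.controls if g not in out.index]
    if control_only:
        extra = pd.DataFrame(
            {
                "ipl": np.nan, "cv": np.nan, "n_nonzero": 0,
                "passed_ipl": False, "passed_cv": False, "passed_nonzero": False,
                "role": [candidates.controls[g] for g in control_only],
            },
            index=pd.Index(control_only, name="gene"),
        )
        out = pd.concat([out, extra])
    out.to_csv(path, sep="\t")


# -- truth --------------------------------------------------------------------

def write_truth(truth: GroundTruth, path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=2, sort_keys=True))


def read_truth(path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    return GroundTruth(
        de_genes=d.get("de_genes", {}),
        cn_segments=[tuple(s) for s in d.get("cn_segments", [])],
        active_nodes=set(d.get("active_nodes", [])),
        true_hits={k: tuple(v) for k, v in d.get("true_hits", {}).items()},
    )
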