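"""Plain-text readers and writers for all pipeline artifacts.

Formats: edge list TSV (node_a, node_b, confidence), DE table TSV (gene,
log2fc, pvalue[, ...]), expression TSV (genes x samples, header = sample
ids), labels TSV (sample, group), truth JSON, feature TSV (node + the 11
topology columns), GraphML for subnetworks.  All writers are deterministic:
fixed row order, fixed float formatting via pandas.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

from .errors import SchemaError, ValidationError
from .synthetic import PlantedTruth

__all__ = [
    "read_network",
    "write_network",
    "read_de_table",
    "write_de_table",
    "read_expression",
    "write_expression",
    "read_labels",
    "write_labels",
    "read_truth",
    "write_truth",
    "read_features",
    "write_features",
    "write_graphml",
    "read_gene_list",
]


def read_network(path) -> nx.Graph:
    """Edge list TSV ``node_a<TAB>node_b<TAB>confidence`` (no header)."""
    frame = pd.read_csv(path, sep="\t", header=None,
                        names=["node_a", "node_b", "confidence"], dtype=str)
    graph = nx.Graph()
    for a, b, c in frame.itertuples(index=False):
        conf = float(c) if c is not None and c == c else 1.0
        if a == b:
            raise ValidationError(f"self-loop on node {a!r}")
        graph.add_edge(a, b, confidence=conf)
    return graph


def write_network(graph: nx.Graph, path) -> None:
    rows = [
        (u, v, f"{graph.edges[u, v].get('confidence', 1.0):.6f}")
        for u, v in sorted(tuple(sorted(e)) for e in graph.edges())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_de_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    if "gene" not in table.columns:
        raise SchemaError("DE table needs a 'gene' column")
    table = table.set_index("gene")
    missing = {"log2fc", "pvalue"} - set(table.columns)
    if missing:
        raise SchemaError(f"DE table lacks columns: {sorted(missing)}")
    return table


def write_de_table(table: pd.DataFrame, path) -> None:
    table.sort_index().to_csv(path, sep="\t", float_format="%.10g")


def read_expression(path) -> pd.DataFrame:
    expr = pd.read_csv(path, sep="\t", index_col=0)
    expr.index.name = "gene"
    return expr


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.sort_index().to_csv(path, sep="\t", float_format="%.10g")


def read_labels(path) -> pd.Series:
    frame = pd.read_csv(path, sep="\t")
    missing = {"sample", "group"} - set(frame.columns)
    if missing:
        raise SchemaError(f"labels file lacks columns: {sorted(missing)}")
    return frame.set_index("sample")["group"]


def write_labels(labels: pd.Series, path) -> None:
    labels.rename("group").rename_axis("sample").to_csv(path, sep="\t")


def read_truth(path) -> PlantedTruth:
    with open(path) as fh:
        d = json.load(fh)
    return PlantedTruth(
        module_nodes=set(d["module_nodes"]),
        biomarker_nodes=set(d["biomarker_nodes"]),
        effect_sizes={k: float(v) for k, v in d.get("effect_sizes", {}).items()},
    )


def write_truth(truth: PlantedTruth, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "module_nodes": sorted(truth.module_nodes),
                "biomarker_nodes": sorted(truth.biomarker_nodes),
                "effect_sizes": {k: truth.effect_sizes[k]
                                 for k in sorted(truth.effect_sizes)},
            },
            fh,
            indent=1,
        )


def read_features(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    if "node" not in table.columns:
        raise SchemaError("feature table needs a 'node' column")
    return table.set_index("node")


def write_features(features: pd.DataFrame, path) -> None:
    features.sort_index().to_csv(path, sep="\t", float_format="%.10g")


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)


def read_gene_list(path) -> list[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out
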