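"""Node-topology feature battery (NetworkAnalyzer-style conventions).

Computes, for every node of a simple undirected graph, the eleven named
statistics used as the machine-learning design matrix:

degree; average_shortest_path_length (mean unweighted distance to the nodes
reachable from v); closeness_centrality (its reciprocal); betweenness
centrality normalized by (n-1)(n-2)/2 unordered pairs of the node's connected
component; stress (total number of shortest paths over unordered pairs
{s, t}, s ≠ v ≠ t, passing through v); eccentricity; clustering coefficient;
neighborhood_connectivity (mean degree of the neighbors); number_of_directed
edges (the incident-edge count — equal to degree on a simple undirected
graph, kept for fidelity to the conventional 11-feature list); radiality
((diam + 1 - asp) / diam with diam the component diameter, 1.0 for a
single-node component); and the topological coefficient

    T(v) = mean_{m in S(v)} J(v, m) / k(v),

where S(v) are the nodes other than v sharing at least one neighbor with v
and J(v, m) = |N(v) ∩ N(m)|, plus one if v–m is itself an edge; T(v) = 0 when
k(v) <= 1 or S(v) is empty.

Distances are unweighted hops; edge confidences do not enter.  Betweenness and
stress are accumulated in a single Brandes-style BFS sweep per source, so the
whole battery is exact and O(V·E) per component.
"""

from __future__ import annotations

from collections import deque

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["FEATURE_NAMES", "compute_features"]

FEATURE_NAMES: tuple[str, ...] = (
    "degree",
    "average_shortest_path_length",
    "closeness_centrality",
    "betweenness_centrality",
    "stress",
    "eccentricity",
    "clustering_coefficient",
    "neighborhood_connectivity",
    "number_of_directed_edges",
    "radiality",
    "topological_coefficient",
)


def _brandes_component(
    sub: nx.Graph,
) -> tuple[dict, dict, dict, dict]:
    """Per-node asp, eccentricity, betweenness (raw), stress on one component."""
    nodes = list(sub.nodes())
    asp = {v: 0.0 for v in nodes}
    ecc = {v: 0 for v in nodes}
    betw = {v: 0.0 for v in nodes}
    stress = {v: 0.0 for v in nodes}
    adj = {v: list(sub.neighbors(v)) for v in nodes}

    for s in nodes:
        dist = {s: 0}
        sigma = {s: 1.0}
        preds: dict = {s: []}
        order = []
        queue = deque([s])
        while queue:
            v = queue.popleft()
            order.append(v)
            for w in adj[v]:
                if w not in dist:
                    dist[w] = dist[v] + 1
                    sigma[w] = 0.0
                    preds[w] = []
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)

        if len(order) > 1:
            d = np.fromiter((dist[v] for v in order), dtype=float)
            asp[s] = float(d.sum() / (len(order) - 1))
            ecc[s] = int(d.max())

        delta_b = {v: 0.0 for v in order}
        delta_s = {v: 0.0 for v in order}
        for w in reversed(order):
            for v in preds[w]:
                frac = sigma[v] / sigma[w]
                delta_b[v] += frac * (1.0 + delta_b[w])
                delta_s[v] += sigma[v] * (1.0 + delta_s[w] / sigma[w])
            if w != s:
                betw[w] += delta_b[w]
                stress[w] += delta_s[w]

    # each unordered {s, t} pair was visited from both endpoints
    for v in nodes:
        betw[v] /= 2.0
        stress[v] /= 2.0
    return asp, ecc, betw, stress


def _topological_coefficient(graph: nx.Graph, v) -> float:
    k = graph.degree(v)
    if k <= 1:
        return 0.0
    shared: dict = {}
    for u in graph.neighbors(v):
        for w in graph.neighbors(u):
            if w != v:
                shared[w] = shared.get(w, 0) + 1
    if not shared:
        return 0.0
    total = sum(
        count + (1 if graph.has_edge(v, m) else 0) for m, count in shared.items()
    )
    return total / (len(shared) * k)


def compute_features(network: nx.Graph) -> pd.DataFrame:
    """The 11-feature design matrix, one row per node, fixed column order."""
    if network.is_directed():
        raise ValidationError("network must be undirected")
    if network.is_multigraph():
        raise ValidationError("network must be a simple graph, not a multigraph")
    if any(u == v for u, v in nx.selfloop_edges(network)):
        raise ValidationError("network must not contain self-loops")

    nodes = sorted(network.nodes())
    feat = pd.DataFrame(0.0, index=pd.Index(nodes, name="node"), columns=list(FEATURE_NAMES))

    degree = dict(network.degree())
    clustering = nx.clustering(network)
    for v in nodes:
        feat.at[v, "degree"] = degree[v]
        feat.at[v, "number_of_directed_edges"] = degree[v]
        feat.at[v, "clustering_coefficient"] = clustering[v]
        nbrs = list(network.neighbors(v))
        feat.at[v, "neighborhood_connectivity"] = (
            float(np.mean([degree[u] for u in nbrs])) if nbrs else 0.0
        )
        feat.at[v, "topological_coefficient"] = _topological_coefficient(network, v)

    for comp in nx.connected_components(network):
        sub = network.subgraph(comp)
        n = sub.number_of_nodes()
        asp, ecc, betw, stress = _brandes_component(sub)
        diam = max(ecc.values()) if n > 1 else 0
        pair_norm = (n - 1) * (n - 2) / 2.0 if n > 2 else 0.0
        for v in comp:
            feat.at[v, "average_shortest_path_length"] = asp[v]
            feat.at[v, "eccentricity"] = ecc[v]
            feat.at[v, "closeness_centrality"] = 1.0 / asp[v] if asp[v] > 0 else 0.0
            feat.at[v, "betweenness_centrality"] = (
                betw[v] / pair_norm if pair_norm > 0 else 0.0
            )
            feat.at[v, "stress"] = stress[v]
            feat.at[v, "radiality"] = (
                (diam + 1.0 - asp[v]) / diam if diam > 0 else 1.0
            )
    return feat
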