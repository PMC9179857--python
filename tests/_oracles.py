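"""Independent brute-force oracles used to validate the fast implementations.

These deliberately use different algorithms from the package: distance-layer
dynamic programming for shortest-path counts (not Brandes accumulation),
explicit pairwise comparisons for AUC, and exhaustive connected-subset
enumeration for module search.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pandas as pd


def bfs_paths(graph: nx.Graph, source):
    """Distances and shortest-path counts from one source via layered DP."""
    dist = {source: 0}
    sigma = {source: 1}
    layer = [source]
    while layer:
        nxt = []
        for v in layer:
            for w in graph.neighbors(v):
                if w not in dist:
                    dist[w] = dist[v] + 1
                    sigma[w] = 0
                    nxt.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
        layer = nxt
    return dist, sigma


def feature_matrix_bruteforce(graph: nx.Graph) -> pd.DataFrame:
    """All 11 topology features by explicit enumeration (small graphs only)."""
    nodes = sorted(graph.nodes())
    dist = {}
    sigma = {}
    for s in nodes:
        dist[s], sigma[s] = bfs_paths(graph, s)

    rows = {}
    for v in nodes:
        deg = graph.degree(v)
        nbrs = set(graph.neighbors(v))
        reach = [w for w in dist[v] if w != v]
        asp = float(np.mean([dist[v][w] for w in reach])) if reach else 0.0
        ecc = max((dist[v][w] for w in reach), default=0)

        comp = set(dist[v])
        diam = max(
            (dist[s][t] for s in comp for t in dist[s]), default=0
        )

        # stress & betweenness: pairwise over the component
        stress = 0.0
        bet = 0.0
        others = [w for w in comp if w != v]
        for s, t in itertools.combinations(others, 2):
            if t not in dist[s]:
                continue
            if dist[s].get(v, np.inf) + dist[v].get(t, np.inf) == dist[s][t]:
                through = sigma[s][v] * sigma[v][t]
                stress += through
                bet += through / sigma[s][t]
        n_comp = len(comp)
        pair_norm = (n_comp - 1) * (n_comp - 2) / 2.0
        bet_norm = bet / pair_norm if pair_norm > 0 else 0.0

        e_among = sum(
            1 for a, b in itertools.combinations(sorted(nbrs), 2) if graph.has_edge(a, b)
        )
        clust = 2.0 * e_among / (deg * (deg - 1)) if deg >= 2 else 0.0
        nc = float(np.mean([graph.degree(u) for u in nbrs])) if nbrs else 0.0
        radiality = (diam + 1.0 - asp) / diam if diam > 0 else 1.0

        if deg <= 1:
            tc = 0.0
        else:
            shared = {}
            for m in nodes:
                if m == v:
                    continue
                inter = nbrs & set(graph.neighbors(m))
                if inter:
                    shared[m] = len(inter) + (1 if graph.has_edge(v, m) else 0)
            tc = float(np.mean(list(shared.values()))) / deg if shared else 0.0

        rows[v] = {
            "degree": float(deg),
            "average_shortest_path_length": asp,
            "closeness_centrality": 1.0 / asp if asp > 0 else 0.0,
            "betweenness_centrality": bet_norm,
            "stress": stress,
            "eccentricity": float(ecc),
            "clustering_coefficient": clust,
            "neighborhood_connectivity": nc,
            "number_of_directed_edges": float(deg),
            "radiality": radiality,
            "topological_coefficient": tc,
        }
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()


def auc_pairwise(scores, labels) -> float:
    """AUC by direct case-control pair counting with half credit for ties."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, bool)
    cases, ctrls = s[y], s[~y]
    wins = 0.0
    for c in cases:
        for k in ctrls:
            if c > k:
                wins += 1.0
            elif c == k:
                wins += 0.5
    return wins / (len(cases) * len(ctrls))


def best_connected_subset(graph: nx.Graph, z: dict, normalization: str = "stouffer"):
    """Exhaustive maximum of z(A) over every connected node subset (n <= ~15)."""
    nodes = sorted(graph.nodes())
    best_score, best_set = -np.inf, None
    for r in range(1, len(nodes) + 1):
        for combo in itertools.combinations(nodes, r):
            sub = graph.subgraph(combo)
            if not nx.is_connected(sub):
                continue
            total = sum(z[v] for v in combo)
            denom = np.sqrt(r) if normalization == "stouffer" else r
            score = total / denom
            if score > best_score:
                best_score, best_set = score, set(combo)
    return best_score, best_set
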