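"""Active-subnetwork extraction by Stouffer-Z scoring and greedy search.

Each gene's differential-expression p-value is mapped to a standard-normal
deviate z = Phi⁻¹(1 - p), so small p-values become large positive z.  A
candidate subnetwork A with k nodes is scored by the Stouffer aggregate

    z(A) = (1/sqrt(k)) * sum_{i in A} z_i                     (default)

which is standard normal for any fixed A under the global null; a "mean"
normalization (1/k) is available as a documented alternative.  The search
greedily grows a module from each of the highest-z seed nodes, always adding
the neighboring node that maximally increases z(A), and keeps the best module
across restarts.  A disease-specific subnetwork (high-z genes plus, for each,
its single best-z neighbor) can then be induced for topology profiling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import special

from .errors import MissingStatisticError, ValidationError

__all__ = [
    "ModuleResult",
    "p_to_z",
    "zmap_from_table",
    "aggregate_score",
    "greedy_module_search",
    "build_ccs_ppin",
    "filter_by_confidence",
]

_P_EPS = 1e-16

MIN_CONFIDENCE_DEFAULT = 0.7
ITERATIONS_DEFAULT = 10


@dataclass
class ModuleResult:
    """Best module found by the greedy search.

    ``trace`` holds one entry per restart: the final score of that restart's
    growth run.  ``seed_node`` is the seed from which the winner grew.
    """

    nodes: set[str]
    score: float
    k: int
    trace: list[float] = field(default_factory=list)
    seed_node: str | None = None


def p_to_z(p):
    """Inverse-normal transform z = Phi⁻¹(1 - p); vectorized.

    Values are clamped to [1e-16, 1 - 1e-16] before transforming, so extreme
    p-values give large finite z.  Smaller p → larger z.
    """
    arr = np.asarray(p, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr < 0) or np.any(arr > 1):
        raise ValidationError("p-values must be finite and lie in [0, 1]")
    z = -special.ndtri(np.clip(arr, _P_EPS, 1.0 - _P_EPS))
    return float(z) if np.isscalar(p) else z


def zmap_from_table(de_table: pd.DataFrame) -> pd.Series:
    """Gene → z series from a DE table's ``pvalue`` column."""
    return pd.Series(p_to_z(de_table["pvalue"].to_numpy()), index=de_table.index, name="z")


def _normalizer(k: int, normalization: str) -> float:
    if normalization == "stouffer":
        return float(np.sqrt(k))
    if normalization == "mean":
        return float(k)
    raise ValidationError(f"unknown normalization {normalization!r}")


def aggregate_score(zmap: pd.Series, nodes, normalization: str = "stouffer") -> float:
    """z(A) of a node set: sum of z over the set, over sqrt(k) (or k)."""
    nodes = list(nodes)
    if not nodes:
        raise ValidationError("cannot score an empty node set")
    missing = [n for n in nodes if n not in zmap.index]
    if missing:
        raise MissingStatisticError(f"no z-score for nodes: {missing[:5]}")
    return float(zmap.loc[nodes].sum() / _normalizer(len(nodes), normalization))


def _grow_from_seed(
    network: nx.Graph,
    z: dict[str, float],
    seed_node: str,
    max_size: int,
    normalization: str,
) -> tuple[set[str], float]:
    """One greedy growth run; ties broken lexicographically by node id."""
    module = {seed_node}
    total = z[seed_node]
    score = total / _normalizer(1, normalization)
    frontier = set(network.neighbors(seed_node))
    while len(module) < max_size and frontier:
        # for both normalizations the best addition is the max-z neighbor
        best = min(frontier, key=lambda v: (-z[v], v))
        new_total = total + z[best]
        new_score = new_total / _normalizer(len(module) + 1, normalization)
        if new_score <= score + 1e-12:
            break
        module.add(best)
        total, score = new_total, new_score
        frontier.discard(best)
        frontier.update(v for v in network.neighbors(best) if v not in module)
    return module, score


def greedy_module_search(
    network: nx.Graph,
    zmap: pd.Series,
    iterations: int = ITERATIONS_DEFAULT,
    max_size: int = 30,
    n_seeds: int | None = None,
    seed: int = 0,
    normalization: str = "stouffer",
) -> ModuleResult:
    """Best-scoring connected module across greedy restarts.

    Restarts launch from the ``iterations`` (or ``n_seeds``) distinct nodes
    with the highest z.  Genes absent from ``zmap`` are imputed at z = 0
    (p = 0.5), which is neutral under both normalizations.  The procedure is
    deterministic given the inputs; ``seed`` is accepted for interface
    stability but tie-breaks are lexicographic, not random.
    """
    del seed
    if network.number_of_nodes() == 0:
        raise ValidationError("network is empty")
    if max_size < 1:
        raise ValidationError("max_size must be at least 1")
    if iterations < 1:
        raise ValidationError("iterations must be at least 1")
    n_restarts = int(n_seeds) if n_seeds is not None else int(iterations)

    z = {v: float(zmap.get(v, 0.0)) for v in network.nodes()}
    seeds = sorted(z, key=lambda v: (-z[v], v))[:n_restarts]

    best: ModuleResult | None = None
    trace: list[float] = []
    for s in seeds:
        module, score = _grow_from_seed(network, z, s, max_size, normalization)
        trace.append(score)
        if best is None or score > best.score + 1e-12:
            best = ModuleResult(nodes=module, score=score, k=len(module), seed_node=s)
    assert best is not None
    best.trace = trace
    return best


def build_ccs_ppin(network: nx.Graph, zmap: pd.Series, z_threshold: float) -> nx.Graph:
    """Disease-specific subnetwork: high-z genes plus each one's best neighbor.

    Nodes are {g : z_g > z_threshold} together with, for each such gene, its
    single neighbor of highest z (ties broken lexicographically); the result
    is the subgraph induced by that node set.  May be empty.
    """
    if not np.isfinite(z_threshold):
        raise ValidationError("z_threshold must be finite")
    z = {v: float(zmap.get(v, 0.0)) for v in network.nodes()}
    high = {v for v in network.nodes() if z[v] > z_threshold}
    keep = set(high)
    for v in high:
        nbrs = list(network.neighbors(v))
        if nbrs:
            keep.add(min(nbrs, key=lambda u: (-z[u], u)))
    return network.subgraph(keep).copy()


def filter_by_confidence(
    network: nx.Graph, min_confidence: float = MIN_CONFIDENCE_DEFAULT
) -> nx.Graph:
    """Drop edges whose confidence is not strictly above ``min_confidence``."""
    out = network.copy()
    drop = [
        (u, v)
        for u, v, c in out.edges(data="confidence", default=1.0)
        if not c > min_confidence
    ]
    out.remove_edges_from(drop)
    return out
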