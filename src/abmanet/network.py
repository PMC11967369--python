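"""Weighted directed interaction networks: global metrics, centralities, hubs.

Graphs are directed and simple (no self-loops, one edge per ordered pair)
with integer edge weights counting supporting references.  Conventions,
chosen once and used throughout:

* density is the directed one, m / (n * (n - 1)) — the only convention
  under which the reported densities of sparse literature networks are
  self-consistent with their node/edge counts;
* average path length, diameter and clustering are computed on the
  undirected, unweighted projection of the largest connected component
  (directed reachability in sparse digraphs inflates or breaks these);
* centralities are unweighted: in/out-degree normalised by (n - 1),
  betweenness on the directed graph with standard pair normalisation,
  eigenvector centrality on the undirected projection scaled to max 1.
* edge weights enter only the total-weight statistic.

Hub calling is a consensus: nodes are ranked under each of the four
centralities (average ranks over ties) and the top k by mean rank are the
hubs, with a lexicographic tie-break for determinism.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "NetworkMetrics",
    "build_graph",
    "edge_density",
    "global_metrics",
    "centralities",
    "hub_genes",
]


@dataclass(frozen=True)
class NetworkMetrics:
    n_nodes: int
    n_edges: int
    density: float
    avg_path_length: float
    avg_clustering: float
    diameter: int
    n_components: int
    total_weight: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _merge_signs(s1: str, s2: str) -> str:
    return s1 if s1 == s2 else "?"


def build_graph(edges: pd.DataFrame, node_subset=None) -> nx.DiGraph:
    """Build a simple weighted digraph from an edge-list table.

    ``edges`` needs columns ``source, target, weight`` (optional ``sign``).
    If ``node_subset`` is given, the induced subgraph on those nodes is
    returned, keeping isolated subset members as nodes.  Duplicate rows for
    the same ordered pair are merged by summing weights (conflicting signs
    merge to ``?``); self-loops are rejected.
    """
    required = {"source", "target", "weight"}
    missing = required - set(edges.columns)
    if missing:
        raise ValueError(f"edge table missing columns: {sorted(missing)}")
    has_sign = "sign" in edges.columns
    graph = nx.DiGraph()
    if node_subset is not None:
        keep = set(node_subset)
        graph.add_nodes_from(sorted(keep))
    else:
        keep = None
    for i, row in enumerate(edges.itertuples(index=False)):
        u, v, w = row.source, row.target, row.weight
        if u == v:
            raise ValueError(f"self-loop at edge row {i}: {u!r}")
        try:
            w = int(w)
        except (TypeError, ValueError):
            raise ValueError(f"non-integer weight at edge row {i}: {w!r}") from None
        if w < 1:
            raise ValueError(f"weight must be >= 1 at edge row {i}: {w}")
        if keep is not None and (u not in keep or v not in keep):
            continue
        sign = getattr(row, "sign", "?") if has_sign else "?"
        if graph.has_edge(u, v):
            graph[u][v]["weight"] += w
            graph[u][v]["sign"] = _merge_signs(graph[u][v]["sign"], sign)
        else:
            graph.add_edge(u, v, weight=w, sign=sign)
    return graph


def edge_density(n_nodes: int, n_edges: int, directed: bool = True) -> float:
    """Edge count over the maximum possible (n(n-1) directed, half undirected)."""
    if n_nodes < 2:
        raise ValueError("density undefined for fewer than 2 nodes")
    denom = n_nodes * (n_nodes - 1)
    if not directed:
        denom //= 2
    return n_edges / denom


def global_metrics(graph: nx.DiGraph) -> NetworkMetrics:
    """Global statistics of a weighted digraph (conventions in module docs)."""
    n = graph.number_of_nodes()
    m = graph.number_of_edges()
    if n < 2:
        raise ValueError("global metrics undefined for fewer than 2 nodes")
    und = graph.to_undirected()
    components = list(nx.connected_components(und))
    giant = und.subgraph(max(components, key=lambda c: (len(c), sorted(c)[0])))
    if giant.number_of_nodes() > 1:
        apl = nx.average_shortest_path_length(giant)
        diam = nx.diameter(giant)
    else:
        apl, diam = 0.0, 0
    return NetworkMetrics(
        n_nodes=n,
        n_edges=m,
        density=edge_density(n, m, directed=True),
        avg_path_length=float(apl),
        avg_clustering=float(nx.average_clustering(und)),
        diameter=int(diam),
        n_components=len(components),
        total_weight=int(sum(d["weight"] for _, _, d in graph.edges(data=True))),
    )


def centralities(graph: nx.DiGraph) -> pd.DataFrame:
    """Per-node centrality table, indexed by node, sorted lexicographically.

    Columns: ``in_degree`` and ``out_degree`` normalised by n-1,
    ``betweenness`` (directed, pair-normalised), ``eigenvector``
    (undirected projection, power iteration, rescaled to max 1).
    """
    n = graph.number_of_nodes()
    if n < 2:
        raise ValueError("centralities undefined for fewer than 2 nodes")
    indeg = {v: d / (n - 1) for v, d in graph.in_degree()}
    outdeg = {v: d / (n - 1) for v, d in graph.out_degree()}
    btw = nx.betweenness_centrality(graph, normalized=True)
    und = graph.to_undirected()
    giant = max(nx.connected_components(und), key=lambda c: (len(c), sorted(c)[0]))
    eig = dict.fromkeys(graph.nodes, 0.0)
    if len(giant) > 1:
        try:
            sub_eig = nx.eigenvector_centrality(
                und.subgraph(giant), max_iter=1000, tol=1e-10, weight=None
            )
        except nx.PowerIterationFailedConvergence as exc:
            raise ArithmeticError(
                f"eigenvector power iteration failed to converge on the "
                f"{len(giant)}-node component containing {sorted(giant)[0]!r}"
            ) from exc
        peak = max(sub_eig.values())
        eig.update({v: x / peak for v, x in sub_eig.items()})
    nodes = sorted(graph.nodes)
    return pd.DataFrame(
        {
            "in_degree": [indeg[v] for v in nodes],
            "out_degree": [outdeg[v] for v in nodes],
            "betweenness": [btw[v] for v in nodes],
            "eigenvector": [eig[v] for v in nodes],
        },
        index=pd.Index(nodes, name="gene_id"),
    )


def hub_genes(table: pd.DataFrame, k: int = 5) -> list[str]:
    """Top-k consensus hubs by mean rank across the four centralities.

    Rank 1 is the highest value of a measure; ties get average ranks; the
    final ordering breaks mean-rank ties lexicographically.
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if k > len(table):
        raise ValueError(f"k={k} exceeds node count {len(table)}")
    measures = ["in_degree", "out_degree", "betweenness", "eigenvector"]
    ranks = np.column_stack(
        [rankdata(-table[m].to_numpy(), method="average") for m in measures]
    )
    mean_rank = ranks.mean(axis=1)
    order = sorted(zip(mean_rank, table.index))
    return [name for _, name in order[:k]]


def annotate_hubs(table: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """Return the centrality table with ``mean_rank`` and ``hub`` columns added."""
    hubs = set(hub_genes(table, k))
    measures = ["in_degree", "out_degree", "betweenness", "eigenvector"]
    out = table.copy()
    out["mean_rank"] = np.column_stack(
        [rankdata(-table[m].to_numpy(), method="average") for m in measures]
    ).mean(axis=1)
    out["hub"] = [v in hubs for v in table.index]
    return out
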