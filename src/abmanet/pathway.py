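"""Signed disease-gene-disease pathway graphs.

Significant gene-disease associations become directed edges between typed
nodes (disease or gene), oriented by an explicit direction map
(disease -> gene or gene -> disease) and coloured by the association's
polarity: positive, negative, or unknown (ties and unresolved directions).
A gene g is an intermediary from disease A to disease B when the graph
contains A -> g and g -> B; the composed sign along the chain follows the
product rule (two negatives make a positive) with unknown absorbing.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

__all__ = [
    "compose_signs",
    "build_pathway",
    "intermediary_genes",
    "to_edge_table",
    "to_dot",
]

POLARITIES = ("positive", "negative", "unknown")

_SIGN_CHAR = {"positive": "+", "negative": "-", "unknown": "?"}


def compose_signs(s1: str, s2: str) -> str:
    """Product-rule composition over {positive, negative}; unknown absorbs."""
    for s in (s1, s2):
        if s not in POLARITIES:
            raise ValueError(f"invalid polarity: {s!r}")
    if "unknown" in (s1, s2):
        return "unknown"
    return "positive" if s1 == s2 else "negative"


def build_pathway(
    assoc: pd.DataFrame,
    direction_map: dict[tuple[str, str], str],
    diseases=None,
) -> nx.DiGraph:
    """Assemble the polarity graph from a scored association table.

    ``assoc`` is the adjusted-binomial result table; only significant rows
    become edges.  ``direction_map`` maps ``(gene_id, disease_id)`` to
    ``"disease->gene"`` or ``"gene->disease"``; significant relations
    missing from the map are collected under the graph attribute
    ``unmapped`` and omitted.  Edge polarity is the association direction
    (ties map to unknown) and edge weight is the total report count.
    """
    graph = nx.DiGraph()
    diseases = set(diseases) if diseases is not None else set(assoc.get("disease_id", []))
    for d in sorted(diseases):
        graph.add_node(d, kind="disease")
    unmapped: list[tuple[str, str]] = []
    if not assoc.empty:
        for row in assoc.loc[assoc["significant"]].itertuples(index=False):
            key = (row.gene_id, row.disease_id)
            orientation = direction_map.get(key)
            if orientation is None:
                unmapped.append(key)
                continue
            if orientation == "disease->gene":
                u, v = row.disease_id, row.gene_id
            elif orientation == "gene->disease":
                u, v = row.gene_id, row.disease_id
            else:
                raise ValueError(
                    f"invalid orientation {orientation!r} for {key}; expected "
                    "'disease->gene' or 'gene->disease'"
                )
            polarity = row.direction if row.direction in ("positive", "negative") else "unknown"
            weight = int(row.n_pos + row.n_neg + row.n_incon)
            graph.add_node(row.gene_id, kind="gene")
            graph.add_node(row.disease_id, kind="disease")
            graph.add_edge(u, v, polarity=polarity, weight=weight)
    graph.graph["unmapped"] = unmapped
    return graph


def intermediary_genes(
    graph: nx.DiGraph, source_disease: str, target_disease: str
) -> list[tuple[str, str]]:
    """Genes mediating source -> gene -> target, with composed chain signs.

    Returns ``(gene, composed_polarity)`` pairs sorted by gene id.  The
    two orientations of a disease pair are independent queries.
    """
    for d in (source_disease, target_disease):
        if d not in graph or graph.nodes[d].get("kind") != "disease":
            raise ValueError(f"unknown disease: {d!r}")
    out = []
    for g in graph.successors(source_disease):
        if graph.nodes[g].get("kind") != "gene":
            continue
        if graph.has_edge(g, target_disease):
            sign = compose_signs(
                graph[source_disease][g]["polarity"], graph[g][target_disease]["polarity"]
            )
            out.append((g, sign))
    return sorted(out)


def to_edge_table(graph: nx.DiGraph) -> pd.DataFrame:
    """Edge list with columns ``source target polarity weight``."""
    rows = [
        {
            "source": u,
            "target": v,
            "polarity": d["polarity"],
            "weight": d.get("weight", 1),
        }
        for u, v, d in sorted(graph.edges(data=True))
    ]
    return pd.DataFrame(rows, columns=["source", "target", "polarity", "weight"])


def to_dot(graph: nx.DiGraph) -> str:
    """GraphViz DOT export: green positive, red negative, black unknown."""
    color = {"positive": "green", "negative": "red", "unknown": "black"}
    lines = ["digraph pathway {"]
    for v in sorted(graph.nodes):
        shape = "box" if graph.nodes[v].get("kind") == "disease" else "ellipse"
        lines.append(f'  "{v}" [shape={shape}];')
    for u, v, d in sorted(graph.edges(data=True)):
        lines.append(
            f'  "{u}" -> "{v}" [color={color[d["polarity"]]}, '
            f'label="{_SIGN_CHAR[d["polarity"]]}"];'
        )
    lines.append("}")
    return "\n".join(lines) + "\n"
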