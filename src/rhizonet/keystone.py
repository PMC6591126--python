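"""Keystone-taxon identification and influence summaries.

Keystone taxa are operationally defined as nodes that combine high degree,
high closeness centrality, and low betweenness centrality — taxa embedded in
densely interconnected neighborhoods rather than acting as fragile bridges.
Two selection modes are provided because both appear in practice: joint
thresholds on the three attributes, and the intersection of the top-k ranked
nodes on each attribute.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from rhizonet.network import TopologySummary, node_centralities, topology_summary

__all__ = [
    "KeystoneCriteria",
    "KeystoneReport",
    "select_keystones",
    "proportional_influence",
    "remove_keystones_and_summarize",
    "OVERALL_CRITERIA",
    "PER_SYSTEM_CRITERIA",
]

# conventional cut-offs for a pooled (meta) network and for smaller
# group-specific networks built from fewer samples
OVERALL_CRITERIA_PARAMS = dict(min_degree=50, min_closeness=0.44, max_betweenness=0.12)
PER_SYSTEM_CRITERIA_PARAMS = dict(min_degree=10, min_closeness=0.28, max_betweenness=0.18)


@dataclass
class KeystoneCriteria:
    """Selection rule: exactly one of threshold or top-k mode.

    Threshold mode keeps nodes with degree > min_degree, closeness >
    min_closeness, and betweenness < max_betweenness (all strict). Top-k
    mode intersects the k best-ranked nodes on each attribute, ties broken
    by node id for determinism.
    """

    mode: str = "threshold"
    min_degree: float = 10
    min_closeness: float = 0.28
    max_betweenness: float = 0.18
    k: int = 10

    def __post_init__(self) -> None:
        if self.mode not in ("threshold", "top_k"):
            raise ValueError("mode must be 'threshold' or 'top_k'")


OVERALL_CRITERIA = KeystoneCriteria(mode="threshold", **OVERALL_CRITERIA_PARAMS)
PER_SYSTEM_CRITERIA = KeystoneCriteria(mode="threshold", **PER_SYSTEM_CRITERIA_PARAMS)


@dataclass
class KeystoneReport:
    keystones: pd.DataFrame  # index OTU; degree, closeness, betweenness, order
    counts_per_order: dict[str, int] = field(default_factory=dict)

    @property
    def otus(self) -> list:
        return list(self.keystones.index)


def _top_k_ids(attrs: pd.DataFrame, column: str, k: int, ascending: bool) -> set:
    ranked = attrs[column].sort_values(ascending=ascending, kind="mergesort")
    # deterministic tie-break on node id within equal attribute values
    df = pd.DataFrame({"v": ranked})
    df["id"] = df.index.astype(str)
    df = df.sort_values(["v", "id"], ascending=[ascending, True], kind="mergesort")
    return set(df.index[:k])


def select_keystones(
    attrs: pd.DataFrame,
    criteria: KeystoneCriteria,
    taxonomy: pd.DataFrame | None = None,
) -> KeystoneReport:
    """Apply a :class:`KeystoneCriteria` to a node-attribute table.

    ``attrs`` is the output of :func:`rhizonet.network.node_centralities`.
    Returns the selected nodes with the attribute values that qualified
    them, annotated with taxonomic order when a taxonomy is given.
    """
    if attrs.empty:
        return KeystoneReport(
            keystones=pd.DataFrame(
                columns=["degree", "closeness", "betweenness", "order"]
            )
        )
    if criteria.mode == "threshold":
        mask = (
            (attrs["degree"] > criteria.min_degree)
            & (attrs["closeness"] > criteria.min_closeness)
            & (attrs["betweenness"] < criteria.max_betweenness)
        )
        selected = attrs[mask]
    else:
        ids = (
            _top_k_ids(attrs, "degree", criteria.k, ascending=False)
            & _top_k_ids(attrs, "closeness", criteria.k, ascending=False)
            & _top_k_ids(attrs, "betweenness", criteria.k, ascending=True)
        )
        selected = attrs.loc[sorted(ids, key=str)]
    out = selected[["degree", "closeness", "betweenness"]].copy()
    if taxonomy is not None:
        orders = [
            (taxonomy.loc[o, "order"] if o in taxonomy.index else "") or "Unclassified"
            for o in out.index
        ]
        out["order"] = orders
    else:
        out["order"] = "Unclassified"
    counts = out["order"].value_counts().to_dict()
    return KeystoneReport(keystones=out, counts_per_order=counts)


def proportional_influence(
    net: nx.Graph,
    taxonomy: pd.DataFrame,
    orientation: str = "edges_per_node",
) -> dict[str, float]:
    """Per-order influence: incident edges relative to member nodes.

    The default orientation reports E/N — edges incident to at least one
    node of the order, divided by the order's node count — so that orders
    whose members are highly connected score high. ``orientation=
    "nodes_per_edge"`` reports the literal N/E ratio instead. Orders with no
    edges score 0.
    """
    if orientation not in ("edges_per_node", "nodes_per_edge"):
        raise ValueError("unknown orientation")
    order_of = {}
    for node in net.nodes:
        if "order" in net.nodes[node]:
            order_of[node] = net.nodes[node]["order"] or "Unclassified"
        elif node in taxonomy.index:
            order_of[node] = taxonomy.loc[node, "order"] or "Unclassified"
        else:
            order_of[node] = "Unclassified"
    orders = sorted(set(order_of.values()))
    out: dict[str, float] = {}
    for order in orders:
        members = [n for n, o in order_of.items() if o == order]
        n_nodes = len(members)
        member_set = set(members)
        n_edges = sum(
            1 for u, v in net.edges if u in member_set or v in member_set
        )
        if n_edges == 0:
            out[order] = 0.0
        elif orientation == "edges_per_node":
            out[order] = n_edges / n_nodes
        else:
            out[order] = n_nodes / n_edges
    return out


def remove_keystones_and_summarize(
    net: nx.Graph, keystones
) -> tuple[TopologySummary | None, dict]:
    """Topology of the network after deleting the keystone nodes.

    Returns the recomputed summary of the induced subgraph on the remaining
    nodes (None when removal empties the graph) together with the change in
    edge count and clustering coefficient.
    """
    keystones = set(keystones)
    unknown = keystones - set(net.nodes)
    if unknown:
        raise ValueError(f"keystones not in network: {sorted(unknown, key=str)}")
    before = topology_summary(net)
    remaining = [n for n in net.nodes if n not in keystones]
    deltas = {
        "n_removed": len(keystones),
        "delta_edges": None,
        "delta_clustering": None,
    }
    if not remaining:
        return None, deltas
    sub = net.subgraph(remaining).copy()
    after = topology_summary(sub)
    deltas["delta_edges"] = after.n_edges - before.n_edges
    deltas["delta_clustering"] = (
        after.clustering_coefficient - before.clustering_coefficient
    )
    return after, deltas
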