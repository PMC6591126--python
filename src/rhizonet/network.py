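"""Co-occurrence network construction, topology, and random-graph baselines.

Networks are undirected simple :class:`networkx.Graph` objects whose nodes
are OTU ids (taxonomy-annotated when available) and whose edges are the
FDR-significant associations. Edges are unweighted: an association either
survives FDR or it does not. Centralities are computed per connected
component: closeness is the reciprocal of the mean shortest-path length to
reachable nodes, and betweenness is normalized by (N-1)(N-2)/2 within the
component, so a star center scores exactly 1 on both.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "build_network",
    "node_centralities",
    "topology_summary",
    "powerlaw_fit",
    "barabasi_albert",
    "compare_to_random",
    "TopologySummary",
    "write_graphml",
    "write_sif",
]


@dataclass
class TopologySummary:
    n_nodes: int
    n_edges: int
    diameter: float
    avg_neighbors: float
    clustering_coefficient: float
    mean_shortest_path: float
    powerlaw_gamma: float
    powerlaw_r2: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def build_network(
    assoc: pd.DataFrame,
    alpha: float = 0.05,
    taxonomy: pd.DataFrame | None = None,
) -> nx.Graph:
    """Graph of OTU pairs whose association q-value is below ``alpha``.

    Nodes are the OTUs incident to at least one significant edge; OTUs with
    no significant association are simply absent. Edge attributes carry the
    relationship class and the low-support flag when present.
    """
    if "q_value" not in assoc.columns:
        raise ValueError("association table lacks q-values")
    sig = assoc[assoc["q_value"] < alpha]
    g = nx.Graph()
    for row in sig.itertuples(index=False):
        attrs = {}
        if hasattr(row, "relationship"):
            attrs["relationship"] = row.relationship
        if hasattr(row, "low_support"):
            attrs["low_support"] = bool(row.low_support)
        g.add_edge(row.otu_a, row.otu_b, **attrs)
    if taxonomy is not None:
        for node in g.nodes:
            if node in taxonomy.index:
                order = taxonomy.loc[node, "order"]
                g.nodes[node]["order"] = order if order else "Unclassified"
            else:
                g.nodes[node]["order"] = "Unclassified"
    return g


def node_centralities(net: nx.Graph) -> pd.DataFrame:
    """Degree, closeness, betweenness, and local clustering per node.

    Closeness and betweenness are computed within each connected component
    (component-wise normalization); local clustering of a degree-<2 node
    is 0.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    rows = {}
    clustering = nx.clustering(net)
    for comp in nx.connected_components(net):
        sub = net.subgraph(comp)
        close = nx.closeness_centrality(sub, wf_improved=False)
        betw = nx.betweenness_centrality(sub, normalized=True)
        for node in comp:
            rows[node] = (
                net.degree[node],
                close[node] if len(comp) > 1 else 0.0,
                betw[node],
                clustering[node],
            )
    df = pd.DataFrame.from_dict(
        rows,
        orient="index",
        columns=["degree", "closeness", "betweenness", "local_clustering"],
    )
    return df.loc[list(net.nodes)]


def powerlaw_fit(degree_sequence) -> tuple[float, float]:
    """Exponent and R^2 of a least-squares log-log fit to the degree law.

    Fits log P(k) against log k over observed degrees k >= 1 and returns
    (gamma, r2) with gamma the positive exponent of P(k) ~ k^-gamma; NaNs
    when fewer than 3 distinct positive degrees are observed.
    """
    degrees = np.asarray(list(degree_sequence), dtype=float)
    degrees = degrees[degrees >= 1]
    if degrees.size == 0:
        return (np.nan, np.nan)
    ks, counts = np.unique(degrees, return_counts=True)
    if ks.size < 3:
        return (np.nan, np.nan)
    pk = counts / counts.sum()
    logk = np.log10(ks)
    logp = np.log10(pk)
    slope, intercept = np.polyfit(logk, logp, 1)
    pred = slope * logk + intercept
    ss_res = ((logp - pred) ** 2).sum()
    ss_tot = ((logp - logp.mean()) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return (float(-slope), float(r2))


def topology_summary(net: nx.Graph) -> TopologySummary:
    """Whole-network topology: size, diameter, path length, clustering.

    Diameter and mean shortest path are taken over connected node pairs
    only, so fragmented graphs still yield finite values. The clustering
    coefficient averages local clustering over all nodes, with degree-<2
    nodes contributing 0.
    """
    n = net.number_of_nodes()
    if n == 0:
        raise ValueError("empty network")
    diam = 0
    total = 0
    n_pairs = 0
    for comp in nx.connected_components(net):
        sub = net.subgraph(comp)
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            for d in dists.values():
                if d > 0:
                    total += d
                    n_pairs += 1
                    diam = max(diam, d)
    mean_sp = total / n_pairs if n_pairs else 0.0
    clustering = float(np.mean(list(nx.clustering(net).values())))
    degrees = [d for _, d in net.degree()]
    gamma, r2 = powerlaw_fit(degrees)
    return TopologySummary(
        n_nodes=n,
        n_edges=net.number_of_edges(),
        diameter=float(diam),
        avg_neighbors=float(np.mean(degrees)),
        clustering_coefficient=clustering,
        mean_shortest_path=float(mean_sp),
        powerlaw_gamma=gamma,
        powerlaw_r2=r2,
    )


def barabasi_albert(n_nodes: int, m_attach: int, seed: int | None = None) -> nx.Graph:
    """Preferential-attachment graph from a complete seed graph.

    Starts from K_{m+1}; each of the remaining n - m - 1 nodes attaches
    ``m_attach`` edges to existing nodes with probability proportional to
    degree, without multi-edges, giving exactly C(m+1, 2) + (n - m - 1) * m
    edges.
    """
    if not 1 <= m_attach < n_nodes:
        raise ValueError("need 1 <= m_attach < n_nodes")
    rng = np.random.default_rng(seed)
    g = nx.complete_graph(m_attach + 1)
    # repeated-node list: each endpoint occurrence is one unit of degree
    repeated: list[int] = [u for e in g.edges for u in e]
    for new in range(m_attach + 1, n_nodes):
        targets: set[int] = set()
        while len(targets) < m_attach:
            targets.add(repeated[rng.integers(len(repeated))])
        for t in targets:
            g.add_edge(new, t)
            repeated.extend((new, t))
    return g


def _erdos_renyi_matched(n: int, n_edges: int, rng: np.random.Generator) -> nx.Graph:
    g = nx.gnm_random_graph(n, n_edges, seed=int(rng.integers(2**31)))
    return g


def compare_to_random(
    net: nx.Graph, n_rand: int = 100, seed: int | None = None
) -> dict:
    """Observed clustering and path length against BA and ER null ensembles.

    Generates ``n_rand`` size-matched Barabasi-Albert graphs (attachment
    parameter m = round(E/N), at least 1) and Erdos-Renyi graphs with the
    same node and edge counts, and reports the observed statistics with
    their percentile locations in each null distribution.
    """
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    n = net.number_of_nodes()
    e = net.number_of_edges()
    if n == 0:
        raise ValueError("empty network")
    obs = topology_summary(net)
    rng = np.random.default_rng(seed)
    m = max(1, round(e / n)) if n else 1
    m = min(m, n - 1)
    stats: dict[str, dict[str, list[float]]] = {
        "ba": {"clustering": [], "mean_shortest_path": []},
        "er": {"clustering": [], "mean_shortest_path": []},
    }
    for _ in range(n_rand):
        ba = barabasi_albert(n, m, seed=int(rng.integers(2**31)))
        er = _erdos_renyi_matched(n, e, rng)
        for name, g in (("ba", ba), ("er", er)):
            ts = topology_summary(g)
            stats[name]["clustering"].append(ts.clustering_coefficient)
            stats[name]["mean_shortest_path"].append(ts.mean_shortest_path)
    report = {
        "observed": {
            "clustering": obs.clustering_coefficient,
            "mean_shortest_path": obs.mean_shortest_path,
        },
        "n_rand": n_rand,
    }
    for name in ("ba", "er"):
        for key in ("clustering", "mean_shortest_path"):
            null = np.asarray(stats[name][key])
            obs_val = report["observed"][key]
            pct = 100.0 * np.mean(null < obs_val)
            report[f"{name}_{key}_null_mean"] = float(null.mean())
            report[f"{name}_{key}_percentile"] = float(pct)
    return report


def write_graphml(net: nx.Graph, path) -> None:
    nx.write_graphml(net, path)


def write_sif(net: nx.Graph, path) -> None:
    """Cytoscape SIF export: one line per edge, relationship as interaction."""
    with open(path, "w") as fh:
        for u, v, data in net.edges(data=True):
            rel = data.get("relationship") or "assoc"
            fh.write(f"{u}\t{rel}\t{v}\n")
        for node in nx.isolates(net):
            fh.write(f"{node}\n")
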