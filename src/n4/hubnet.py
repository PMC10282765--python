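"""Hub-gene detection on a weighted interaction network.

Edges below a confidence threshold are dropped at load time; the
remaining graph is treated as unweighted for topology.  Hubs are ranked
by Maximal Clique Centrality,

    MCC(v) = sum over maximal cliques C containing v of (|C| - 1)!,

with the convention that an isolated node (whose only maximal clique is
the singleton {v}) scores 0.  Dense clusters are extracted by a
k-core-seeded greedy expansion in the style of the MCODE algorithm:
each node is weighted by the highest core number of its closed
neighborhood's densest k-core times that core's density; clusters grow
from high-weight seeds by admitting neighbors whose weight stays within
a percentage of the seed's.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import factorial
from pathlib import Path

import networkx as nx
import pandas as pd

DEFAULT_SCORE_THRESHOLD = 0.4
NODE_CAP = 5000


def load_network(
    edges: pd.DataFrame | str | Path,
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
) -> nx.Graph:
    """Build a graph from an edge list (node_a, node_b, score).

    Edges scoring below ``score_threshold`` are dropped; duplicate pairs
    keep the maximum score; self-loops are rejected.
    """
    if not isinstance(edges, pd.DataFrame):
        edges = pd.read_csv(edges, sep="\t", comment="#")
    for col in ("node_a", "node_b", "score"):
        if col not in edges.columns:
            raise ValueError(f"edge list missing column {col!r}")
    g = nx.Graph()
    for a, b, s in edges[["node_a", "node_b", "score"]].itertuples(index=False):
        if a == b:
            raise ValueError(f"self-loop on node {a!r}")
        g.add_nodes_from((a, b))  # endpoints stay even if the edge is dropped
        s = float(s)
        if s < score_threshold:
            continue
        if g.has_edge(a, b):
            g[a][b]["score"] = max(g[a][b]["score"], s)
        else:
            g.add_edge(a, b, score=s)
    return g


@dataclass
class HubResult:
    mcc: dict[str, int]
    degree: dict[str, int]
    top_k: list[str] = field(default_factory=list)

    def table(self) -> pd.DataFrame:
        rows = [
            {"node": v, "mcc": self.mcc[v], "degree": self.degree[v]}
            for v in sorted(self.mcc, key=lambda v: (-self.mcc[v], -self.degree[v], v))
        ]
        df = pd.DataFrame(rows, columns=["node", "mcc", "degree"])
        df["rank"] = range(1, len(df) + 1)
        return df


def mcc_scores(g: nx.Graph, top_k: int = 10) -> HubResult:
    """Maximal clique centrality for every node.

    Ties in the ranking break by degree, then lexicographic node id.
    """
    if g.number_of_nodes() > NODE_CAP:
        raise ValueError(
            f"network has {g.number_of_nodes()} nodes (cap {NODE_CAP}); "
            "maximal-clique enumeration is exponential in the worst case — "
            "threshold the edge list harder or restrict to a module first"
        )
    mcc = {v: 0 for v in g.nodes}
    for clique in nx.find_cliques(g):
        if len(clique) < 2:
            continue  # singleton maximal cliques (isolated nodes) score 0
        w = factorial(len(clique) - 1)
        for v in clique:
            mcc[v] += w
    degree = dict(g.degree())
    order = sorted(mcc, key=lambda v: (-mcc[v], -degree[v], v))
    return HubResult(mcc=mcc, degree=degree, top_k=order[:top_k])


@dataclass
class DenseCluster:
    members: list[str]
    density: float
    seed_node: str


def _graph_density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def _node_weights(g: nx.Graph) -> dict[str, float]:
    weights = {}
    core = nx.core_number(g) if g.number_of_edges() else {v: 0 for v in g.nodes}
    for v in g.nodes:
        nbhd = g.subgraph(list(g.neighbors(v)) + [v])
        if nbhd.number_of_edges() == 0:
            weights[v] = 0.0
            continue
        local_core = nx.core_number(nbhd)
        kmax = max(local_core.values())
        kcore_nodes = [u for u, c in local_core.items() if c >= kmax]
        kcore = nbhd.subgraph(kcore_nodes)
        weights[v] = kmax * _graph_density(kcore)
    return weights


def dense_clusters(
    g: nx.Graph,
    node_weight_percentage: float = 0.2,
    k_core_min: int = 2,
    min_cluster_size: int = 3,
) -> list[DenseCluster]:
    """MCODE-style seeded growth of dense regions.

    Returns clusters of >= ``min_cluster_size`` nodes, sorted by
    density x size (descending), each with its seed node.
    """
    if g.number_of_edges() == 0:
        return []
    core = nx.core_number(g)
    weights = _node_weights(g)
    visited: set[str] = set()
    clusters: list[DenseCluster] = []
    for seed in sorted(g.nodes, key=lambda v: (-weights[v], v)):
        if seed in visited or core.get(seed, 0) < k_core_min:
            continue
        cutoff = (1.0 - node_weight_percentage) * weights[seed]
        members = {seed}
        frontier = [seed]
        visited.add(seed)
        while frontier:
            v = frontier.pop()
            for u in g.neighbors(v):
                if u in visited or weights[u] < cutoff:
                    continue
                visited.add(u)
                members.add(u)
                frontier.append(u)
        if len(members) >= min_cluster_size:
            sub = g.subgraph(members)
            clusters.append(
                DenseCluster(
                    members=sorted(members),
                    density=_graph_density(sub),
                    seed_node=seed,
                )
            )
    clusters.sort(key=lambda c: (-c.density * len(c.members), c.seed_node))
    return clusters


def neighborhood(g: nx.Graph, seeds: list[str], radius: int = 1) -> nx.Graph:
    """Induced subgraph on all nodes within ``radius`` hops of any seed."""
    missing = [s for s in seeds if s not in g]
    if missing:
        raise ValueError(f"unknown seed node(s): {missing}")
    keep: set[str] = set()
    for s in seeds:
        keep.update(nx.single_source_shortest_path_length(g, s, cutoff=radius))
    return g.subgraph(keep).copy()


def write_hub_table(result: HubResult, path: str | Path) -> None:
    result.table().to_csv(path, sep="\t", index=False)


def write_clusters(clusters: list[DenseCluster], path: str | Path) -> None:
    rows = []
    for i, c in enumerate(clusters, 1):
        for v in c.members:
            rows.append(
                {"cluster": i, "node": v, "density": c.density, "seed": c.seed_node}
            )
    pd.DataFrame(rows, columns=["cluster", "node", "density", "seed"]).to_csv(
        path, sep="\t", index=False
    )
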