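"""Network- and node-level topology statistics for scored PPI networks.

Definitions follow the Cytoscape NetworkAnalyzer conventions that are the
de-facto standard for descriptive PPI network reports:

* closeness centrality: reciprocal of the mean shortest-path distance from a
  node to every *reachable* node (0 for isolated nodes);
* betweenness centrality: Brandes pair-dependency sum over ordered
  source-target pairs excluding the node, normalised by (N-1)(N-2) so values
  lie in [0, 1]; shortest-path ties split dependency fractionally;
* characteristic path length: mean shortest-path distance over all connected
  ordered pairs; diameter: maximum finite distance;
* clustering coefficient: mean over nodes of the local coefficient
  C_i = 2 e_i / (k_i (k_i - 1)), with C_i = 0 for degree < 2;
* network heterogeneity: coefficient of variation of the degree distribution,
  sqrt(population variance) / mean degree (divide-by-N variance);
* network centralization: (N/(N-2)) * (max_degree/(N-1) - density).

All statistics are computed on the simple undirected graph; edge scores play
no role here. Disconnected inputs are handled by restricting path statistics
to connected pairs and flagging the report.
"""

from __future__ import annotations

import json
import math
from collections import deque
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd

from .netcore import ScoredNetwork, logger, normalize_symbol


@dataclass(frozen=True)
class NodeTopology:
    """Per-node centrality record (Table-style reporting)."""

    node: str
    degree: int
    closeness: float
    betweenness: float
    local_clustering: float


@dataclass(frozen=True)
class NetworkTopology:
    """Whole-network topology summary.

    ``n_edges_undirected`` counts each unordered pair once;
    ``n_edges_directed_pairs`` is twice that, the convention STRING exports
    and some figure legends use. Both are reported because published counts
    mix the two conventions.
    """

    name: str
    n_nodes: int
    n_edges_undirected: int
    n_edges_directed_pairs: int
    avg_neighbors: float
    density: float
    diameter: int
    char_path_length: float
    clustering_coefficient: float
    heterogeneity: float
    centralization: float
    connected: bool


# ---------------------------------------------------------------------------
# Shortest paths (BFS; unweighted)
# ---------------------------------------------------------------------------

def _bfs_distances(net: ScoredNetwork, source: str) -> dict[str, int]:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in net.neighbors(u):
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def degree(net: ScoredNetwork, node: str) -> int:
    """Number of distinct neighbors of ``node``."""
    return net.degree(node)


def closeness(net: ScoredNetwork, node: str) -> float:
    """Closeness centrality: 1 / mean distance to reachable nodes; 0 if isolated."""
    node = normalize_symbol(node)
    dist = _bfs_distances(net, node)
    reachable = [d for n, d in dist.items() if n != node]
    if not reachable:
        return 0.0
    return len(reachable) / sum(reachable)


def betweenness(net: ScoredNetwork, node: str | None = None):
    """Brandes betweenness centrality, normalised to [0, 1].

    With ``node`` given, returns that node's value; otherwise a dict over
    all nodes (one Brandes sweep serves every node, so batch queries should
    use the dict form). Normalisation divides the ordered-pair dependency
    sum by (N-1)(N-2); graphs with fewer than 3 nodes score 0 everywhere.
    """
    nodes = net.nodes
    if node is not None and normalize_symbol(node) not in net.node_set:
        raise KeyError(f"unknown node {node!r} in network {net.name!r}")
    bc = dict.fromkeys(nodes, 0.0)
    for s in nodes:
        # single-source shortest paths with path counts
        sigma = dict.fromkeys(nodes, 0.0)
        sigma[s] = 1.0
        dist = {s: 0}
        preds: dict[str, list[str]] = {n: [] for n in nodes}
        stack: list[str] = []
        queue = deque([s])
        while queue:
            u = queue.popleft()
            stack.append(u)
            for v in net.neighbors(u):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    queue.append(v)
                if dist[v] == dist[u] + 1:
                    sigma[v] += sigma[u]
                    preds[v].append(u)
        # back-propagate dependencies
        delta = dict.fromkeys(nodes, 0.0)
        while stack:
            w = stack.pop()
            for u in preds[w]:
                delta[u] += sigma[u] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
        del preds
    n = len(nodes)
    scale = 1.0 / ((n - 1) * (n - 2)) if n >= 3 else 0.0
    bc = {v: b * scale for v, b in bc.items()}
    if node is not None:
        return bc[normalize_symbol(node)]
    return bc


def local_clustering(net: ScoredNetwork, node: str) -> float:
    """Local clustering coefficient C_i = 2 e_i / (k_i (k_i - 1)); 0 for degree < 2."""
    nbrs = net.neighbors(node)
    k = len(nbrs)
    if k < 2:
        return 0.0
    links = sum(
        1 for i, u in enumerate(nbrs) for v in nbrs[i + 1 :] if net.has_edge(u, v)
    )
    return 2.0 * links / (k * (k - 1))


# ---------------------------------------------------------------------------
# Whole-network summary
# ---------------------------------------------------------------------------

def network_topology(net: ScoredNetwork) -> NetworkTopology:
    """Compute the full NetworkAnalyzer-style summary for a network."""
    n = net.n_nodes
    if n < 1:
        raise ValueError("network must have at least one node")
    e = net.n_edges
    degs = list(net.degrees().values())
    mean_deg = 2.0 * e / n
    density = 2.0 * e / (n * (n - 1)) if n >= 2 else 0.0

    # path statistics over connected ordered pairs
    total_dist = 0
    n_pairs = 0
    diameter = 0
    connected = True
    for s in net.nodes:
        dist = _bfs_distances(net, s)
        if len(dist) < n:
            connected = False
        for t, d in dist.items():
            if t != s:
                total_dist += d
                n_pairs += 1
                diameter = max(diameter, d)
    cpl = total_dist / n_pairs if n_pairs else 0.0
    if not connected:
        logger.warning("network %s is disconnected; path statistics use connected pairs only", net.name)

    clustering = (
        sum(local_clustering(net, v) for v in net.nodes) / n if n else 0.0
    )
    if mean_deg > 0:
        var = sum((d - mean_deg) ** 2 for d in degs) / n  # population variance
        heterogeneity = math.sqrt(var) / mean_deg
    else:
        heterogeneity = 0.0
    if n >= 3:
        centralization = (n / (n - 2.0)) * (max(degs) / (n - 1.0) - density)
    else:
        centralization = 0.0
        logger.warning("network %s has fewer than 3 nodes; centralization reported as 0", net.name)

    return NetworkTopology(
        name=net.name,
        n_nodes=n,
        n_edges_undirected=e,
        n_edges_directed_pairs=2 * e,
        avg_neighbors=mean_deg,
        density=density,
        diameter=diameter,
        char_path_length=cpl,
        clustering_coefficient=clustering,
        heterogeneity=heterogeneity,
        centralization=centralization,
        connected=connected,
    )


def node_topology(net: ScoredNetwork) -> list[NodeTopology]:
    """Per-node degree and centrality records, sorted by degree descending."""
    bc = betweenness(net)
    records = [
        NodeTopology(
            node=v,
            degree=net.degree(v),
            closeness=closeness(net, v),
            betweenness=bc[v],
            local_clustering=local_clustering(net, v),
        )
        for v in net.nodes
    ]
    records.sort(key=lambda r: (-r.degree, r.node))
    return records


# ---------------------------------------------------------------------------
# Report output
# ---------------------------------------------------------------------------

def _display_round(report: NetworkTopology) -> dict:
    """Round fields the way descriptive tables print them.

    One decimal for the average neighbor count, two decimals for
    unit-interval statistics; counts stay integral. Full precision stays
    available on the dataclass itself.
    """
    d = asdict(report)
    d["avg_neighbors"] = round(report.avg_neighbors, 1)
    for key in ("density", "char_path_length", "clustering_coefficient",
                "heterogeneity", "centralization"):
        d[key] = round(d[key], 2)
    return d


def topology_frame(reports: list[NetworkTopology], rounded: bool = True) -> pd.DataFrame:
    """One row per network; ``rounded`` applies display rounding."""
    rows = [_display_round(r) if rounded else asdict(r) for r in reports]
    return pd.DataFrame(rows)


def write_topology_report(
    reports: list[NetworkTopology], tsv_path: str | Path, json_path: str | Path | None = None
) -> None:
    """Write the per-network report as TSV, with an optional JSON mirror."""
    frame = topology_frame(reports, rounded=True)
    frame.to_csv(tsv_path, sep="\t", index=False, lineterminator="\n")
    if json_path is not None:
        payload = [asdict(r) for r in reports]
        Path(json_path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def write_node_report(records: list[NodeTopology], tsv_path: str | Path) -> None:
    """Per-node TSV: node, degree, closeness, betweenness, local_clustering."""
    with Path(tsv_path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("node\tdegree\tcloseness\tbetweenness\tlocal_clustering\n")
        for r in records:
            fh.write(
                f"{r.node}\t{r.degree}\t{r.closeness:.6g}\t{r.betweenness:.6g}\t{r.local_clustering:.6g}\n"
            )
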