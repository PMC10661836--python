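"""Key-protein selection: high-degree hubs, high-score interactors, subnetwork.

The selection procedure ranks proteins by degree (high-degree proteins,
HDPs), fixes a combined-score threshold at a percentile of the network's
edge-score distribution (default the 90th), and takes as high-score
interaction proteins (HSIPs) every neighbor of an HDP joined by an edge
whose combined score strictly exceeds that threshold. The key subnetwork is
the induced subgraph on the breadth-first closure of the HDPs along
above-threshold edges, up to a configurable depth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .netcore import CHANNELS, ScoredNetwork, normalize_symbol
from .topology import NetworkTopology, betweenness, closeness, network_topology


@dataclass(frozen=True)
class HDPRecord:
    """A high-degree protein with the centralities reported alongside it."""

    node: str
    degree: int
    closeness: float
    betweenness: float


@dataclass(frozen=True)
class HSIPRecord:
    """A high-score interaction partner of an HDP."""

    partner: str
    combined: int
    channels: dict[str, int] = field(default_factory=dict, hash=False, compare=False)


@dataclass
class KeyProteinResult:
    """Full output of the key-protein procedure for one network."""

    network: str
    hdps: list[HDPRecord]
    tie_flag: bool
    cs_threshold: float
    hsips: dict[str, list[HSIPRecord]]
    subnetwork: ScoredNetwork
    subnetwork_topology: NetworkTopology


def select_hdps(net: ScoredNetwork, k: int = 2) -> tuple[list[HDPRecord], bool]:
    """The ``k`` highest-degree nodes, expanding ties at the k-th rank.

    Returns ``(records, tie_flag)``. If several nodes share the k-th degree,
    all of them are included and ``tie_flag`` is True — degree ranking alone
    cannot order them, and silently dropping some would bias the selection.
    Records carry closeness and betweenness for descriptive reporting and are
    sorted by degree descending, then alphabetically.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = net.n_nodes
    if n == 0:
        raise ValueError("network is empty")
    if k > n:
        raise ValueError(f"k={k} exceeds node count {n}")
    degs = net.degrees()
    ranked = sorted(degs, key=lambda v: (-degs[v], v))
    kth_degree = degs[ranked[k - 1]]
    chosen = [v for v in ranked if degs[v] >= kth_degree]
    tie_flag = len(chosen) > k
    bc = betweenness(net)
    records = [
        HDPRecord(node=v, degree=degs[v], closeness=closeness(net, v), betweenness=bc[v])
        for v in chosen
    ]
    return records, tie_flag


def cs_percentile_threshold(
    net: ScoredNetwork, q: float = 0.90, rule: str = "nearest_rank"
) -> float:
    """The q-quantile of the edge combined-score multiset.

    ``nearest_rank`` (default) returns the ceil(q*m)-th order statistic — an
    attainable score value, which keeps the strict ``combined > threshold``
    criterion interpretable. ``linear`` interpolates between order statistics
    and may return a non-integral value.
    """
    if not (0.0 < q < 1.0):
        raise ValueError("q must lie strictly between 0 and 1")
    values = sorted(e.combined for e in net.edges)
    if not values:
        raise ValueError(f"network {net.name!r} has no edges")
    if rule == "nearest_rank":
        idx = math.ceil(q * len(values))
        return float(values[idx - 1])
    if rule == "linear":
        return float(np.quantile(np.asarray(values, dtype=float), q))
    raise ValueError(f"unknown quantile rule: {rule!r}")


def select_hsips(
    net: ScoredNetwork, hdps: list[HDPRecord] | list[str], threshold: float
) -> dict[str, list[HSIPRecord]]:
    """Per-HDP neighbors joined by an edge with combined score > threshold.

    Strictly exceeding edges only; partners are sorted by combined score
    descending then alphabetically. An HDP with no qualifying neighbor maps
    to an empty list.
    """
    if not (0 <= threshold <= 999):
        raise ValueError("threshold must lie in [0, 999]")
    result: dict[str, list[HSIPRecord]] = {}
    for hdp in hdps:
        node = hdp.node if isinstance(hdp, HDPRecord) else normalize_symbol(hdp)
        partners = [
            HSIPRecord(partner=e.other(node), combined=e.combined, channels=dict(e.channels))
            for e in net.incident_edges(node)
            if e.combined > threshold
        ]
        partners.sort(key=lambda r: (-r.combined, r.partner))
        result[node] = partners
    return result


def extract_key_subnetwork(
    net: ScoredNetwork,
    hdps: list[HDPRecord] | list[str],
    threshold: float,
    max_depth: int = 2,
    edge_policy: str = "all_member_edges",
    name: str | None = None,
) -> ScoredNetwork:
    """Key subnetwork: BFS closure from the HDPs along above-threshold edges.

    Nodes reachable from any HDP within ``max_depth`` steps, moving only
    along edges with combined score strictly above ``threshold``, form the
    member set. ``edge_policy`` fixes which edges the subnetwork keeps:
    ``all_member_edges`` (default) retains every network edge among members
    (an induced subgraph), ``above_threshold_only`` retains only the
    above-threshold ones.
    """
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    if edge_policy not in ("all_member_edges", "above_threshold_only"):
        raise ValueError(f"unknown edge_policy: {edge_policy!r}")
    seeds = [h.node if isinstance(h, HDPRecord) else normalize_symbol(h) for h in hdps]
    members = set(seeds)
    frontier = set(seeds)
    for _ in range(max_depth):
        nxt = set()
        for u in frontier:
            for e in net.incident_edges(u):
                v = e.other(u)
                if e.combined > threshold and v not in members:
                    nxt.add(v)
        members |= nxt
        frontier = nxt
        if not frontier:
            break
    sub = net.subgraph(members, name=name or f"{net.name}-key")
    if edge_policy == "above_threshold_only":
        trimmed = ScoredNetwork(sub.name, nodes=sub.nodes)
        for e in sub.edges:
            if e.combined > threshold:
                trimmed.add_edge(e)
        sub = trimmed
    return sub


def key_protein_analysis(
    net: ScoredNetwork,
    k: int = 2,
    q: float = 0.90,
    quantile_rule: str = "nearest_rank",
    max_depth: int = 2,
    edge_policy: str = "all_member_edges",
) -> KeyProteinResult:
    """Run the full procedure on one network and bundle the results."""
    hdps, tie_flag = select_hdps(net, k)
    threshold = cs_percentile_threshold(net, q, quantile_rule)
    hsips = select_hsips(net, hdps, threshold)
    sub = extract_key_subnetwork(net, hdps, threshold, max_depth, edge_policy)
    return KeyProteinResult(
        network=net.name,
        hdps=hdps,
        tie_flag=tie_flag,
        cs_threshold=threshold,
        hsips=hsips,
        subnetwork=sub,
        subnetwork_topology=network_topology(sub),
    )


def write_key_protein_report(results: list[KeyProteinResult], path: str | Path) -> None:
    """TSV report, one row per HDP-HSIP pair.

    Columns: network, hdp, degree, close, betw, hsip, coexp, exp, text, cs,
    cs_threshold. HDPs without qualifying interactors get one row with empty
    HSIP columns so the selection is still visible in the report.
    """
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(
            "network\thdp\tdegree\tclose\tbetw\thsip\tcoexp\texp\ttext\tcs\tcs_threshold\n"
        )
        for res in results:
            for hdp in res.hdps:
                partners = res.hsips.get(hdp.node, [])
                rows = partners or [None]
                for rec in rows:
                    base = (
                        f"{res.network}\t{hdp.node}\t{hdp.degree}"
                        f"\t{hdp.closeness:.2f}\t{hdp.betweenness:.2f}"
                    )
                    if rec is None:
                        fh.write(base + "\t\t\t\t\t" + f"\t{res.cs_threshold:g}\n")
                    else:
                        ch = "\t".join(str(rec.channels.get(c, 0)) for c in CHANNELS)
                        fh.write(
                            base + f"\t{rec.partner}\t{ch}\t{rec.combined}\t{res.cs_threshold:g}\n"
                        )
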