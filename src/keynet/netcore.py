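"""Core data model and file I/O for scored gene lists and scored PPI networks.

The central containers are :class:`ScoredGeneList` (gene symbols with a
relevance score, e.g. a GeneCards keyword score) and :class:`ScoredNetwork`
(a simple undirected graph whose edges carry STRING-style per-channel
evidence scores and a combined score on the canonical 0-999 integer scale).

Gene symbols are normalised to uppercase with surrounding whitespace
stripped; case drift between tools is the main join hazard for
symbol-keyed data, so normalisation happens once at the boundary and every
downstream module assumes it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

logger = logging.getLogger("keynet")

#: canonical combined-score scale (STRING "millis" convention)
SCORE_MAX = 999

#: expected evidence-channel column names, in report order
CHANNELS = ("coexpression", "experimental", "textmining")


def normalize_symbol(symbol: str) -> str:
    """Uppercase and strip a gene symbol."""
    s = str(symbol).strip().upper()
    if not s:
        raise ValueError("empty gene symbol")
    return s


# ---------------------------------------------------------------------------
# Scored gene lists
# ---------------------------------------------------------------------------

@dataclass
class ScoredGeneList:
    """A named, ordered list of gene symbols with non-negative relevance scores.

    Parameters
    ----------
    name
        Label of the list (e.g. the keyword it was compiled for).
    entries
        Ordered ``(symbol, relevance)`` records. Symbols are normalised and
        must be unique after normalisation; relevance must be >= 0.
    """

    name: str
    entries: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene list name must be non-empty")
        seen: dict[str, float] = {}
        norm: list[tuple[str, float]] = []
        for symbol, score in self.entries:
            sym = normalize_symbol(symbol)
            score = float(score)
            if score < 0:
                raise ValueError(f"negative relevance score for {sym}: {score}")
            if sym in seen:
                raise ValueError(f"duplicate symbol in gene list {self.name!r}: {sym}")
            seen[sym] = score
            norm.append((sym, score))
        self.entries = norm

    @property
    def symbols(self) -> list[str]:
        return [s for s, _ in self.entries]

    @property
    def symbol_set(self) -> set[str]:
        return {s for s, _ in self.entries}

    def score(self, symbol: str) -> float:
        sym = normalize_symbol(symbol)
        for s, v in self.entries:
            if s == sym:
                return v
        raise KeyError(sym)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, symbol: str) -> bool:
        return normalize_symbol(symbol) in self.symbol_set


def read_gene_list(path: str | Path, name: str) -> ScoredGeneList:
    """Read a gene list from a two-column text table.

    Accepts tab- or comma-separated files with a symbol column and an
    optional score column; a header line starting with ``symbol`` is
    skipped. Duplicate symbols (after case normalisation) are collapsed
    keeping the maximum score, with a warning. Missing scores default to 0.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines()]
    best: dict[str, float] = {}
    order: list[str] = []
    n_rows = 0
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        sep = "\t" if "\t" in line else ","
        parts = [p.strip() for p in line.split(sep)]
        if lineno == 1 and parts[0].lower() in ("symbol", "gene", "gene_symbol"):
            continue
        try:
            sym = normalize_symbol(parts[0])
            score = float(parts[1]) if len(parts) > 1 and parts[1] != "" else 0.0
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}: unparseable row at line {lineno}: {raw!r}") from exc
        if score < 0:
            raise ValueError(f"{path}: negative score at line {lineno}: {raw!r}")
        n_rows += 1
        if sym in best:
            logger.warning(
                "%s: duplicate symbol %s (line %d); keeping max score", path, sym, lineno
            )
            best[sym] = max(best[sym], score)
        else:
            best[sym] = score
            order.append(sym)
    if n_rows == 0:
        raise ValueError(f"{path}: empty gene list")
    return ScoredGeneList(name, [(s, best[s]) for s in order])


def write_gene_list(glist: ScoredGeneList, path: str | Path) -> None:
    """Write a gene list as TSV with header ``symbol<TAB>score``."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("symbol\tscore\n")
        for sym, score in glist.entries:
            fh.write(f"{sym}\t{score:g}\n")


# ---------------------------------------------------------------------------
# Scored edges and networks
# ---------------------------------------------------------------------------

def _check_score(value: int, what: str) -> int:
    v = int(value)
    if not (0 <= v <= SCORE_MAX):
        raise ValueError(f"{what} score out of range [0, {SCORE_MAX}]: {value}")
    return v


@dataclass
class ScoredEdge:
    """An undirected interaction between two proteins with evidence scores.

    Endpoints are stored in sorted order so that ``(a, b)`` is a canonical
    unordered pair. ``channels`` maps evidence-channel names (coexpression,
    experimental, textmining) to integer scores on the 0-999 scale;
    ``combined`` is the integrated confidence on the same scale.
    """

    a: str
    b: str
    combined: int
    channels: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.a = normalize_symbol(self.a)
        self.b = normalize_symbol(self.b)
        if self.a == self.b:
            raise ValueError(f"self-loop edge {self.a}-{self.b}")
        if self.a > self.b:
            self.a, self.b = self.b, self.a
        self.combined = _check_score(self.combined, "combined")
        self.channels = {k: _check_score(v, k) for k, v in self.channels.items()}

    @property
    def pair(self) -> tuple[str, str]:
        return (self.a, self.b)

    def other(self, node: str) -> str:
        if node == self.a:
            return self.b
        if node == self.b:
            return self.a
        raise KeyError(node)


class ScoredNetwork:
    """A simple undirected graph with scored edges and possibly isolated nodes."""

    def __init__(
        self,
        name: str,
        nodes: Iterable[str] = (),
        edges: Iterable[ScoredEdge] = (),
        meta: dict | None = None,
    ) -> None:
        if not name:
            raise ValueError("network name must be non-empty")
        self.name = name
        self.meta: dict = meta or {}
        self._adj: dict[str, dict[str, ScoredEdge]] = {}
        for node in nodes:
            self.add_node(node)
        for edge in edges:
            self.add_edge(edge)

    # -- construction ------------------------------------------------------

    def add_node(self, node: str) -> str:
        node = normalize_symbol(node)
        self._adj.setdefault(node, {})
        return node

    def add_edge(self, edge: ScoredEdge) -> None:
        if self.has_edge(edge.a, edge.b):
            raise ValueError(f"duplicate edge {edge.a}-{edge.b} in network {self.name!r}")
        self.add_node(edge.a)
        self.add_node(edge.b)
        self._adj[edge.a][edge.b] = edge
        self._adj[edge.b][edge.a] = edge

    # -- queries -----------------------------------------------------------

    @property
    def nodes(self) -> list[str]:
        return sorted(self._adj)

    @property
    def node_set(self) -> set[str]:
        return set(self._adj)

    @property
    def edges(self) -> list[ScoredEdge]:
        return sorted(
            (e for node, nbrs in self._adj.items() for nb, e in nbrs.items() if node == e.a),
            key=lambda e: e.pair,
        )

    @property
    def n_nodes(self) -> int:
        return len(self._adj)

    @property
    def n_edges(self) -> int:
        return sum(len(nbrs) for nbrs in self._adj.values()) // 2

    def has_node(self, node: str) -> bool:
        return normalize_symbol(node) in self._adj

    def has_edge(self, a: str, b: str) -> bool:
        a, b = normalize_symbol(a), normalize_symbol(b)
        return a in self._adj and b in self._adj[a]

    def get_edge(self, a: str, b: str) -> ScoredEdge:
        a, b = normalize_symbol(a), normalize_symbol(b)
        try:
            return self._adj[a][b]
        except KeyError:
            raise KeyError(f"no edge {a}-{b} in network {self.name!r}") from None

    def neighbors(self, node: str) -> list[str]:
        node = normalize_symbol(node)
        if node not in self._adj:
            raise KeyError(f"unknown node {node!r} in network {self.name!r}")
        return sorted(self._adj[node])

    def incident_edges(self, node: str) -> list[ScoredEdge]:
        node = normalize_symbol(node)
        if node not in self._adj:
            raise KeyError(f"unknown node {node!r} in network {self.name!r}")
        return [self._adj[node][nb] for nb in sorted(self._adj[node])]

    def degree(self, node: str) -> int:
        node = normalize_symbol(node)
        if node not in self._adj:
            raise KeyError(f"unknown node {node!r} in network {self.name!r}")
        return len(self._adj[node])

    def degrees(self) -> dict[str, int]:
        return {n: len(nbrs) for n, nbrs in self._adj.items()}

    def subgraph(self, members: Iterable[str], name: str | None = None) -> "ScoredNetwork":
        """Induced subgraph on ``members`` (all edges among them retained)."""
        members = {normalize_symbol(m) for m in members}
        unknown = members - self.node_set
        if unknown:
            raise KeyError(f"unknown nodes in subgraph request: {sorted(unknown)}")
        sub = ScoredNetwork(name or f"{self.name}-sub", nodes=members)
        for e in self.edges:
            if e.a in members and e.b in members:
                sub.add_edge(ScoredEdge(e.a, e.b, e.combined, dict(e.channels)))
        return sub

    def __iter__(self) -> Iterator[str]:
        return iter(self.nodes)

    def __repr__(self) -> str:
        return f"ScoredNetwork({self.name!r}, n_nodes={self.n_nodes}, n_edges={self.n_edges})"


def edge_count(net: ScoredNetwork, convention: str = "undirected") -> int:
    """Edge count under a reporting convention.

    STRING exports list each interaction twice (once per direction); network
    figures therefore sometimes report ``2 * |edges|``. ``undirected`` counts
    each unordered pair once, ``directed_pairs`` twice.
    """
    if convention == "undirected":
        return net.n_edges
    if convention == "directed_pairs":
        return 2 * net.n_edges
    raise ValueError(f"unknown edge count convention: {convention!r}")


# ---------------------------------------------------------------------------
# Edge-table I/O
# ---------------------------------------------------------------------------

_ENDPOINT_ALIASES = {"protein1": 0, "protein2": 1, "node1": 0, "node2": 1, "a": 0, "b": 1}
_COMBINED_ALIASES = ("combined_score", "combined", "cs", "score")
_CHANNEL_ALIASES = {
    "coexpression": "coexpression",
    "coexp": "coexpression",
    "experimental": "experimental",
    "experimentally_determined_interaction": "experimental",
    "exp": "experimental",
    "textmining": "textmining",
    "text_mining": "textmining",
    "text": "textmining",
}


def _to_millis(value, score_scale: str, what: str) -> int:
    if score_scale == "millis":
        v = int(value)
    elif score_scale == "unit":
        x = float(value)
        if x < 0 or x > 1:
            raise ValueError(f"{what} score outside [0, 1] under score_scale=unit: {value}")
        v = min(int(round(x * 1000)), SCORE_MAX)
    else:
        raise ValueError(f"unknown score_scale: {score_scale!r}")
    return _check_score(v, what)


def read_edge_table(
    path: str | Path,
    score_scale: str = "millis",
    name: str | None = None,
    node_file: str | Path | None = None,
) -> ScoredNetwork:
    """Read a STRING-style scored edge table into a :class:`ScoredNetwork`.

    The table must have two endpoint columns (``protein1``/``protein2``) and
    a combined-score column; evidence-channel columns are optional. Both the
    TSV dialect and the space-separated STRING export flavour are accepted.
    Directed duplicate rows ``(a,b)``/``(b,a)`` are merged into one
    undirected edge when their scores agree and rejected as corrupt
    otherwise; self-loop rows are dropped with a warning.

    Parameters
    ----------
    score_scale
        ``millis`` for 0-999 integers (canonical), ``unit`` for 0-1
        decimals, which are multiplied by 1000 and capped at 999.
    node_file
        Optional text file with one symbol per line declaring nodes that may
        be isolated (genes in a list with no interaction in the network).
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        first = fh.readline()
    if not first.strip():
        raise ValueError(f"{path}: empty edge table")
    sep = "\t" if "\t" in first else r"\s+"
    df = pd.read_csv(path, sep=sep, engine="python")
    cols = {str(c).strip().lower(): c for c in df.columns}

    endpoint_cols: list = [None, None]
    for key, idx in _ENDPOINT_ALIASES.items():
        if key in cols and endpoint_cols[idx] is None:
            endpoint_cols[idx] = cols[key]
    if endpoint_cols[0] is None or endpoint_cols[1] is None:
        endpoint_cols = list(df.columns[:2])

    combined_col = next((cols[k] for k in _COMBINED_ALIASES if k in cols), None)
    if combined_col is None:
        raise ValueError(f"{path}: no combined-score column found (expected one of {_COMBINED_ALIASES})")
    channel_cols = {
        canon: cols[key] for key, canon in _CHANNEL_ALIASES.items() if key in cols
    }

    net = ScoredNetwork(name or path.stem)
    pending: dict[tuple[str, str], ScoredEdge] = {}
    for i, row in df.iterrows():
        lineno = i + 2  # header is line 1
        a_raw, b_raw = str(row[endpoint_cols[0]]), str(row[endpoint_cols[1]])
        a, b = normalize_symbol(a_raw), normalize_symbol(b_raw)
        if a == b:
            logger.warning("%s: self-loop row at line %d (%s) rejected", path, lineno, a)
            continue
        combined = _to_millis(row[combined_col], score_scale, "combined")
        channels = {
            canon: _to_millis(row[col], score_scale, canon)
            for canon, col in channel_cols.items()
            if not pd.isna(row[col])
        }
        edge = ScoredEdge(a, b, combined, channels)
        prev = pending.get(edge.pair)
        if prev is not None:
            if prev.combined != edge.combined or prev.channels != edge.channels:
                raise ValueError(
                    f"{path}: conflicting duplicate scores for pair {edge.a}-{edge.b} "
                    f"(line {lineno}): {prev.combined} vs {edge.combined}"
                )
            continue
        pending[edge.pair] = edge
    for edge in pending.values():
        net.add_edge(edge)
    if node_file is not None:
        for raw in Path(node_file).read_text(encoding="utf-8").splitlines():
            if raw.strip() and not raw.startswith("#"):
                net.add_node(raw)
    if net.n_nodes < 1:
        raise ValueError(f"{path}: network has no nodes")
    return net


def write_edge_table(net: ScoredNetwork, path: str | Path) -> None:
    """Write a network as a TSV edge table in the canonical dialect.

    Header is ``protein1 protein2 coexpression experimental textmining
    combined_score`` (tab-separated); missing channel scores are written
    as 0. Round-trips through :func:`read_edge_table`.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("protein1\tprotein2\t" + "\t".join(CHANNELS) + "\tcombined_score\n")
        for e in net.edges:
            ch = "\t".join(str(e.channels.get(c, 0)) for c in CHANNELS)
            fh.write(f"{e.a}\t{e.b}\t{ch}\t{e.combined}\n")


def write_node_list(net: ScoredNetwork, path: str | Path) -> None:
    """Write the node set, one symbol per line (companion to the edge table)."""
    Path(path).write_text("\n".join(net.nodes) + "\n", encoding="utf-8")
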