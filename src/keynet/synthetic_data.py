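"""Synthetic inputs: fixture gene lists, planted-hub networks, annotations.

Everything the pipeline consumes can be generated here, fully seeded, so
every stage is exercisable without database downloads.

The packaged fixture reproduces the membership structure of three curated
gene lists for auditory processes in the spiral ganglion — perception of
sound (PoS), acoustic stimulation (AcouStim) and tinnitus (Tin): 81 unique
symbols distributed over six non-empty Venn regions (the PoS+AcouStim-only
region is empty). Membership is exact; the per-gene relevance scores of the
original keyword searches are not available, so scores are placeholders
drawn uniformly from the observed range [0.8, 30.9] under a fixed seed.

Synthetic networks mimic the two structural features the selection
procedure relies on: a small number of hubs whose degree far exceeds the
background (degree separation), and an edge combined-score distribution
concentrated in the top confidence class with a depleted class just below
it (a bimodal "valley" profile). Edge scores are drawn independently of
topology so degree-based hub selection and score-based interactor selection
are independent axes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .enrichment import AnnotationSet, Term
from .netcore import ScoredEdge, ScoredGeneList, ScoredNetwork

#: Venn regions of the packaged three-list fixture (81 unique symbols).
#: Keys are membership tuples over ("PoS", "AcouStim", "Tin").
FIXTURE_REGIONS: dict[tuple[str, ...], tuple[str, ...]] = {
    ("PoS", "AcouStim", "Tin"): (
        "BDNF", "CACNA1D", "P2RX2", "RET", "OTOF", "TH", "CDH23", "SLC26A5", "KCNQ4",
    ),
    ("PoS", "Tin"): (
        "CA2", "MBP", "GDNF", "TBC1D24", "WHRN", "SLC17A8", "MAP1B", "GRM7", "MYO7A",
        "KCNJ10", "PTPN11", "SNAP25", "SETD2", "NRTN", "MAP2K1", "BTD", "MAFB", "GJA1",
    ),
    ("AcouStim", "Tin"): (
        "CALB2", "MAP2", "NOS2", "MALAT1", "EGF", "NTS", "JUN", "NRG1", "SYP",
        "NR3C1", "CREB1", "GFAP",
    ),
    ("PoS",): (
        "CPA6", "MPDZ", "GRM8", "CHAT", "ASIC2", "MT-CO3", "LMNB1", "NOG", "DES",
    ),
    ("AcouStim",): (
        "CERNA3", "NTRK2", "NOS1", "CYP19A1", "CNTF", "SOD2-OT1", "TMX2-CTNND1",
        "PVALB", "SMAD5-AS1", "CALB1", "MAPK10", "OPRM1",
    ),
    ("Tin",): (
        "MIR210", "GPHN", "NTF3", "PCAT1", "PANX1", "HIF1A", "NTRK1", "FGF2", "ID1",
        "CAMK2G", "ANXA5", "VEGFA", "CACNA1G", "NGFR", "GFRA1", "USF1", "NGF",
        "NTRK3", "VIM", "NUDT6", "S100B",
    ),
}

FIXTURE_LIST_NAMES = ("PoS", "AcouStim", "Tin")

#: Relevance-score range observed across the curated lists.
FIXTURE_SCORE_RANGE = (0.8, 30.9)


def make_fixture_lists(seed: int = 13) -> list[ScoredGeneList]:
    """The three packaged gene lists (PoS: 36, AcouStim: 33, Tin: 60 symbols).

    Membership follows :data:`FIXTURE_REGIONS` exactly; relevance scores are
    placeholder draws from ``FIXTURE_SCORE_RANGE`` under ``seed``.
    """
    rng = np.random.default_rng(seed)
    lo, hi = FIXTURE_SCORE_RANGE
    symbols: dict[str, list[str]] = {name: [] for name in FIXTURE_LIST_NAMES}
    for members, genes in FIXTURE_REGIONS.items():
        for g in genes:
            for name in members:
                symbols[name].append(g)
    scores = {g: round(float(rng.uniform(lo, hi)), 1)
              for region in FIXTURE_REGIONS.values() for g in region}
    return [
        ScoredGeneList(name, [(g, scores[g]) for g in symbols[name]])
        for name in FIXTURE_LIST_NAMES
    ]


# ---------------------------------------------------------------------------
# Planted-hub scored networks
# ---------------------------------------------------------------------------

@dataclass
class HubNetworkSpec:
    """Parameters of a planted-hub scored network.

    Defaults mirror a small curated PPI network: ~28 proteins with a sparse
    Erdős–Rényi background (p = 0.12, mean background degree ≈ 3) and two
    hubs wired up to degree 22, comfortably above the background so degree
    ranking recovers them; the combined-score mixture puts 55% of edges in
    the medium range [400, 760) and 45% in the top class [880, 999], leaving
    the class just below the top empty in expectation.
    """

    n_nodes: int = 28
    n_hubs: int = 2
    hub_degree_target: int = 22
    background_edge_prob: float = 0.12
    cs_mixture: tuple[float, float, tuple[int, int], tuple[int, int]] = (
        0.55, 0.45, (400, 760), (880, 999),
    )
    seed: int = 0
    name: str = "synthetic"

    def __post_init__(self) -> None:
        if not (0 < self.n_hubs < self.n_nodes):
            raise ValueError("need 0 < n_hubs < n_nodes")
        if self.hub_degree_target > self.n_nodes - 1:
            raise ValueError("hub_degree_target exceeds n_nodes - 1")
        if not (0.0 < self.background_edge_prob < 1.0) and self.background_edge_prob != 1.0:
            raise ValueError("background_edge_prob must lie in (0, 1]")
        w_low, w_high, low_rng, high_rng = self.cs_mixture
        if abs(w_low + w_high - 1.0) > 1e-9:
            raise ValueError("cs mixture weights must sum to 1")
        for lo, hi in (low_rng, high_rng):
            if not (0 <= lo <= hi <= 999):
                raise ValueError("cs mixture ranges must lie within [0, 999]")


def _draw_scores(rng: np.random.Generator, mixture) -> tuple[int, dict[str, int]]:
    w_low, _, low_rng, high_rng = mixture
    lo, hi = low_rng if rng.random() < w_low else high_rng
    combined = int(rng.integers(lo, hi + 1))
    channels = {
        name: int(rng.integers(0, combined + 1))
        for name in ("coexpression", "experimental", "textmining")
    }
    # the combined score integrates the channels, so the strongest channel
    # is pinned to it and none may exceed it
    pinned = rng.choice(list(channels))
    channels[pinned] = combined
    return combined, channels


def generate_hub_network(spec: HubNetworkSpec) -> ScoredNetwork:
    """A seeded scored network with planted high-degree hubs.

    Background edges are Erdős–Rényi at ``background_edge_prob``; each hub
    is then wired to uniformly chosen non-neighbors until it reaches
    ``hub_degree_target``. Edge scores come from the two-component uniform
    mixture of the spec. The planted hub names are recorded in
    ``net.meta["planted_hubs"]``.
    """
    rng = np.random.default_rng(spec.seed)
    names = [f"GENE{i:03d}" for i in range(spec.n_nodes)]
    hubs = sorted(rng.choice(names, size=spec.n_hubs, replace=False).tolist())

    adj: dict[str, set[str]] = {v: set() for v in names}
    for i, u in enumerate(names):
        for v in names[i + 1:]:
            if rng.random() < spec.background_edge_prob:
                adj[u].add(v)
                adj[v].add(u)
    for h in hubs:
        candidates = [v for v in names if v != h and v not in adj[h]]
        need = spec.hub_degree_target - len(adj[h])
        if need > len(candidates):
            raise ValueError(f"hub degree target {spec.hub_degree_target} unattainable for {h}")
        if need > 0:
            for v in rng.choice(candidates, size=need, replace=False):
                adj[h].add(v)
                adj[v].add(h)

    net = ScoredNetwork(spec.name, nodes=names, meta={"planted_hubs": hubs, "seed": spec.seed})
    for u in names:
        for v in sorted(adj[u]):
            if u < v:
                combined, channels = _draw_scores(rng, spec.cs_mixture)
                net.add_edge(ScoredEdge(u, v, combined, channels))
    return net


# ---------------------------------------------------------------------------
# Synthetic annotations
# ---------------------------------------------------------------------------

def generate_annotation(
    genes: list[str] | set[str],
    n_terms: int = 20,
    term_size_range: tuple[int, int] = (3, 10),
    seed: int = 0,
    planted_query: set[str] | list[str] | None = None,
) -> AnnotationSet:
    """A random flat annotation over ``genes``, optionally with a planted term.

    Random terms draw their gene sets uniformly; categories alternate
    between CC and BP. When ``planted_query`` is given, one extra term
    exactly equal to that subset is added, so an enrichment of the same
    query must rank it first (its overlap is maximal at minimal term size).
    """
    rng = np.random.default_rng(seed)
    pool = sorted({g.strip().upper() for g in genes})
    lo, hi = term_size_range
    if hi > len(pool):
        raise ValueError("term sizes exceed the gene pool")
    terms: dict[str, Term] = {}
    for i in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = frozenset(rng.choice(pool, size=size, replace=False).tolist())
        category = "CC" if i % 2 == 0 else "BP"
        tid = f"TERM{i:04d}"
        terms[tid] = Term(tid, f"random term {i}", category, members)
    if planted_query is not None:
        planted = frozenset(g.strip().upper() for g in planted_query)
        if not planted <= set(pool):
            raise ValueError("planted query must be a subset of the gene pool")
        terms["PLANTED"] = Term("PLANTED", "planted term", "BP", planted)
    # every pool gene appears in the background even if no random term drew it
    terms["BACKGROUND"] = Term("BACKGROUND", "background universe", "other", frozenset(pool))
    return AnnotationSet(terms)
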