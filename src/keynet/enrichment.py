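"""Gene-set over-representation statistics (DAVID-style charts).

Given a query gene set and a flat term annotation, computes for every term
with at least one overlapping gene the one-sided hypergeometric tail
probability P(X >= k) with X ~ Hypergeom(N, K, n), the fold enrichment
(k/n)/(K/N), the overlap percentage, and a multiple-testing adjusted
p-value. The EASE variant — the conservative score DAVID reports — replaces
k by k-1 in the tail, so singleton overlaps are never significant.

Annotations are taken as given (no ontology-graph propagation); the
background defaults to every gene appearing in the annotation and can be
overridden with an explicit population size when a larger genome-wide
background is intended.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .netcore import normalize_symbol

CATEGORIES = ("CC", "BP", "other")


@dataclass(frozen=True)
class Term:
    term_id: str
    name: str
    category: str
    genes: frozenset[str]


@dataclass
class AnnotationSet:
    """A flat gene-set annotation: term id -> (name, category, gene set)."""

    terms: dict[str, Term]
    background_size: int | None = None

    def __post_init__(self) -> None:
        for t in self.terms.values():
            if not t.genes:
                raise ValueError(f"term {t.term_id} has an empty gene set")
            if t.category not in CATEGORIES:
                raise ValueError(f"term {t.term_id} has unknown category {t.category!r}")
        universe = self.universe
        n_bg = self.background_size if self.background_size is not None else len(universe)
        if any(len(t.genes) > n_bg for t in self.terms.values()):
            raise ValueError("background_size smaller than the largest term")

    @property
    def universe(self) -> set[str]:
        out: set[str] = set()
        for t in self.terms.values():
            out |= t.genes
        return out

    @property
    def effective_background(self) -> int:
        return self.background_size if self.background_size is not None else len(self.universe)


@dataclass(frozen=True)
class EnrichmentRecord:
    term_id: str
    name: str
    category: str
    k: int           # overlap count
    n: int           # annotated query size
    K: int           # term size
    N: int           # background size
    percent: int     # round(100 * k / n)
    fold_enrichment: float
    p_raw: float
    p_adjusted: float
    overlap: tuple[str, ...] = field(default=())


# ---------------------------------------------------------------------------
# GMT I/O
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path, background_size: int | None = None) -> AnnotationSet:
    """Read a GMT file (``term<TAB>description<TAB>gene...`` per line).

    If the description field is ``CC`` or ``BP`` (optionally ``CC|text``),
    it is taken as the term category; otherwise the category is ``other``
    and the description becomes the term name.
    """
    terms: dict[str, Term] = {}
    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        parts = raw.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}: malformed GMT line {lineno}")
        term_id, desc = parts[0].strip(), parts[1].strip()
        genes = frozenset(normalize_symbol(g) for g in parts[2:] if g.strip())
        head, _, rest = desc.partition("|")
        category = head if head in ("CC", "BP") else "other"
        name = rest or (desc if category == "other" else term_id)
        terms[term_id] = Term(term_id, name or term_id, category, genes)
    if not terms:
        raise ValueError(f"{path}: empty annotation")
    return AnnotationSet(terms, background_size=background_size)


def write_gmt(annot: AnnotationSet, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        for term_id in sorted(annot.terms):
            t = annot.terms[term_id]
            desc = t.category if t.category in ("CC", "BP") else t.name
            if t.category in ("CC", "BP") and t.name != term_id:
                desc = f"{t.category}|{t.name}"
            fh.write("\t".join([t.term_id, desc, *sorted(t.genes)]) + "\n")


# ---------------------------------------------------------------------------
# Over-representation
# ---------------------------------------------------------------------------

def _tail_p(k: int, N: int, K: int, n: int, method: str) -> float:
    """One-sided upper tail P(X >= k); EASE uses k-1 successes."""
    if method == "hypergeometric":
        kk = k
    elif method == "ease":
        kk = k - 1
    else:
        raise ValueError(f"unknown method: {method!r}")
    # sf(kk - 1) = P(X >= kk)
    return float(min(1.0, hypergeom.sf(kk - 1, N, K, n)))


def enrich(
    query: set[str] | list[str],
    annot: AnnotationSet,
    method: str = "hypergeometric",
    adjust: str = "bh",
) -> list[EnrichmentRecord]:
    """Over-representation of ``query`` in every annotation term.

    Only annotated query genes count toward ``n``; terms with zero overlap
    are omitted. Records are sorted by raw p ascending, ties broken by
    larger overlap then term id.
    """
    qset = {normalize_symbol(g) for g in query}
    universe = annot.universe
    annotated = qset & universe
    if not annotated:
        raise ValueError("query has no genes in the annotation background")
    N = annot.effective_background
    n = len(annotated)

    raw: list[tuple[Term, int, tuple[str, ...]]] = []
    for term_id in sorted(annot.terms):
        t = annot.terms[term_id]
        overlap = tuple(sorted(annotated & t.genes))
        if overlap:
            raw.append((t, len(overlap), overlap))
    if not raw:
        return []

    pvals = [_tail_p(k, N, len(t.genes), n, method) for t, k, _ in raw]
    if adjust == "bh":
        p_adj = multipletests(pvals, method="fdr_bh")[1]
    elif adjust == "bonferroni":
        p_adj = multipletests(pvals, method="bonferroni")[1]
    elif adjust == "none":
        p_adj = pvals
    else:
        raise ValueError(f"unknown adjust: {adjust!r}")

    records = [
        EnrichmentRecord(
            term_id=t.term_id,
            name=t.name,
            category=t.category,
            k=k,
            n=n,
            K=len(t.genes),
            N=N,
            percent=round(100.0 * k / n),
            fold_enrichment=(k / n) / (len(t.genes) / N),
            p_raw=p,
            p_adjusted=float(pa),
            overlap=overlap,
        )
        for (t, k, overlap), p, pa in zip(raw, pvals, p_adj)
    ]
    records.sort(key=lambda r: (r.p_raw, -r.k, r.term_id))
    return records


def top_terms(records: list[EnrichmentRecord], category: str, count: int = 5) -> list[EnrichmentRecord]:
    """The ``count`` most significant records of one category.

    Ordered by ascending raw p; ties broken by larger overlap count, then
    term id. Fewer records than requested are returned as-is.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    subset = sorted(
        (r for r in records if r.category == category),
        key=lambda r: (r.p_raw, -r.k, r.term_id),
    )
    return subset[:count]


def significant_count(records: list[EnrichmentRecord], alpha: float = 0.01, on: str = "raw") -> int:
    """Number of charted terms below ``alpha`` (DAVID-style chart counting uses raw p)."""
    key = (lambda r: r.p_raw) if on == "raw" else (lambda r: r.p_adjusted)
    return sum(1 for r in records if key(r) < alpha)


def enrichment_frame(records: list[EnrichmentRecord]) -> pd.DataFrame:
    rows = [
        {
            "term": r.term_id,
            "name": r.name,
            "category": r.category,
            "k": r.k,
            "n": r.n,
            "K": r.K,
            "N": r.N,
            "percent": r.percent,
            "fold_enrichment": round(r.fold_enrichment, 4),
            "p_raw": f"{r.p_raw:.6g}",
            "p_adjusted": f"{r.p_adjusted:.6g}",
            "genes": ",".join(r.overlap),
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=["term", "name", "category", "k", "n", "K", "N", "percent",
                 "fold_enrichment", "p_raw", "p_adjusted", "genes"],
    )


def write_enrichment_report(records: list[EnrichmentRecord], path: str | Path) -> None:
    enrichment_frame(records).to_csv(path, sep="\t", index=False, lineterminator="\n")
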