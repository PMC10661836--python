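"""Binned relative-frequency distributions of node degrees and edge scores.

Degree distributions are built on the max-normalised degree: each node's
degree is divided by a normalisation constant (by default the maximum
observed degree) and the unit interval (0, 1] is split into equal half-open
classes, class 1 starting at 0 exclusive. Combined-score distributions bin
raw scores into fixed-width classes starting at the medium-confidence floor
of 400; with the default width of 120 the top class spans 880-999.

The relative-frequency denominator is deliberately decoupled from the
number of items binned: published reports normalise degree frequencies to a
protein count and score frequencies to a directed-pair interaction count,
neither of which need equal the binned-item count. The default degree policy
(``all_nodes``) makes the relative frequencies sum to 1 on networks without
isolated nodes; a custom denominator reproduces other conventions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

from .netcore import ScoredNetwork, edge_count


@dataclass
class FrequencyTable:
    """A binned frequency table with an explicit normaliser.

    ``class_edges[i]`` is the ``(lower, upper)`` bound pair of class ``i+1``;
    degree classes are half-open ``(lo, hi]`` on the normalised scale, score
    classes are ``[lo, hi)`` with a closed top class.
    """

    kind: str
    class_edges: list[tuple[float, float]]
    counts: list[int]
    rel_freq: list[float]
    normalizer: int

    @property
    def n_classes(self) -> int:
        return len(self.counts)

    @property
    def total_binned(self) -> int:
        return sum(self.counts)


def degree_class(normalized_degree: float, n_classes: int) -> int:
    """1-based class of a normalised degree in (0, 1]; classes are (lo, hi]."""
    if not (0.0 < normalized_degree <= 1.0):
        raise ValueError(f"normalized degree outside (0, 1]: {normalized_degree}")
    return min(math.ceil(normalized_degree * n_classes), n_classes)


def degree_distribution(
    net: ScoredNetwork,
    n_classes: int = 5,
    normalizer_policy: str = "all_nodes",
    normalizer: int | None = None,
    degree_norm: int | None = None,
) -> FrequencyTable:
    """Relative frequency of max-normalised node degrees.

    Parameters
    ----------
    degree_norm
        Constant the degrees are divided by; defaults to the maximum
        observed degree (so the top class is always occupied). Isolated
        nodes (normalised degree 0) fall outside (0, 1] and are not binned.
    normalizer_policy, normalizer
        Denominator for the relative frequencies: ``all_nodes`` (node
        count), ``nonisolated_nodes``, or ``custom`` with an explicit
        ``normalizer``.
    """
    degs = list(net.degrees().values())
    max_deg = max(degs, default=0)
    if max_deg == 0:
        raise ValueError(f"network {net.name!r} has no edges")
    norm_const = degree_norm if degree_norm is not None else max_deg
    if norm_const <= 0:
        raise ValueError("degree_norm must be positive")

    counts = [0] * n_classes
    for d in degs:
        if d == 0:
            continue
        x = d / norm_const
        if x > 1.0:
            raise ValueError(
                f"degree {d} exceeds normalization constant {norm_const}"
            )
        counts[degree_class(x, n_classes) - 1] += 1

    if normalizer_policy == "all_nodes":
        denom = net.n_nodes
    elif normalizer_policy == "nonisolated_nodes":
        denom = sum(1 for d in degs if d > 0)
    elif normalizer_policy == "custom":
        if normalizer is None:
            raise ValueError("normalizer_policy='custom' requires a normalizer")
        denom = int(normalizer)
    else:
        raise ValueError(f"unknown normalizer_policy: {normalizer_policy!r}")
    if denom <= 0:
        raise ValueError("frequency normalizer must be positive")

    edges = [((i) / n_classes, (i + 1) / n_classes) for i in range(n_classes)]
    return FrequencyTable(
        kind="degree",
        class_edges=edges,
        counts=counts,
        rel_freq=[c / denom for c in counts],
        normalizer=denom,
    )


def cs_class(cs: int, class_width: int = 120, range_start: int = 400, n_classes: int = 5) -> int:
    """1-based class of a combined score; the top class is closed at 999."""
    if cs < range_start:
        raise ValueError(f"combined score {cs} below range start {range_start}")
    k = (cs - range_start) // class_width + 1
    return min(k, n_classes)


def cs_distribution(
    net: ScoredNetwork,
    class_width: int = 120,
    range_start: int = 400,
    n_classes: int = 5,
    normalizer: int | None = None,
) -> FrequencyTable:
    """Relative frequency of edge combined scores in fixed-width classes.

    Each undirected edge contributes its combined score once. The
    relative-frequency denominator defaults to the directed-pair
    interaction count (2E), the convention STRING-derived reports use;
    pass ``normalizer=net.n_edges`` for frequencies that sum to 1.
    """
    edges = net.edges
    if not edges:
        raise ValueError(f"network {net.name!r} has no edges")
    counts = [0] * n_classes
    for e in edges:
        if e.combined < range_start:
            raise ValueError(
                f"edge {e.a}-{e.b} has combined score {e.combined} below range start {range_start}"
            )
        counts[cs_class(e.combined, class_width, range_start, n_classes) - 1] += 1
    denom = int(normalizer) if normalizer is not None else edge_count(net, "directed_pairs")
    if denom <= 0:
        raise ValueError("frequency normalizer must be positive")
    bounds = [
        (range_start + i * class_width,
         999 if i == n_classes - 1 else range_start + (i + 1) * class_width)
        for i in range(n_classes)
    ]
    return FrequencyTable(
        kind="combined_score",
        class_edges=[(float(lo), float(hi)) for lo, hi in bounds],
        counts=counts,
        rel_freq=[c / denom for c in counts],
        normalizer=denom,
    )


def write_frequency_table(table: FrequencyTable, path: str | Path) -> None:
    """TSV: class, lower, upper, count, rel_freq (plus the normaliser used)."""
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# kind={table.kind}\tnormalizer={table.normalizer}\n")
        fh.write("class\tlower\tupper\tcount\trel_freq\n")
        for i, ((lo, hi), c, f) in enumerate(
            zip(table.class_edges, table.counts, table.rel_freq), start=1
        ):
            fh.write(f"{i}\t{lo:g}\t{hi:g}\t{c}\t{f:.6g}\n")


def plot_distributions(degree_table: FrequencyTable, cs_table: FrequencyTable, path: str | Path) -> None:
    """Optional two-panel bar plot (degree classes left, score classes right)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(8, 3.2))
    for ax, table, title in (
        (axes[0], degree_table, "Degree (max-normalised)"),
        (axes[1], cs_table, "Combined score"),
    ):
        ax.bar(range(1, table.n_classes + 1), table.rel_freq, color="steelblue")
        ax.set_xlabel("class")
        ax.set_ylabel("relative frequency")
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
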