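"""Venn partition analysis of two or three gene lists.

Partitions the union of the input lists into the disjoint regions of the
Venn diagram (exclusive and shared memberships) and renders membership
tables. Symbols are compared after the standard case normalisation, so
lists drawn from different tools join correctly.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import pandas as pd

from .netcore import ScoredGeneList


def region_label(names: tuple[str, ...]) -> str:
    """Label of a Venn region: ``"A only"`` or ``"A+B"`` / ``"A+B+C"``."""
    if len(names) == 1:
        return f"{names[0]} only"
    return "+".join(names)


@dataclass
class VennPartition:
    """Disjoint Venn regions of 2-3 gene lists.

    ``groups`` maps every region label (including empty regions) to its
    symbol set; ``list_names`` preserves the input order the labels use.
    """

    list_names: list[str]
    groups: dict[str, set[str]]
    total_unique: int

    def size(self, label: str) -> int:
        return len(self.groups[label])

    def region_of(self, symbol: str) -> str:
        from .netcore import normalize_symbol

        sym = normalize_symbol(symbol)
        for label, members in self.groups.items():
            if sym in members:
                return label
        raise KeyError(sym)


def venn_partition(lists: list[ScoredGeneList]) -> VennPartition:
    """Partition 2-3 gene lists into disjoint Venn regions.

    Every region of the diagram is present in the output, empty ones with
    size 0, so region sizes can be tabulated uniformly.
    """
    if len(lists) < 2:
        raise ValueError("venn_partition requires at least 2 gene lists")
    if len(lists) > 3:
        raise ValueError("venn_partition supports at most 3 gene lists")
    names = [gl.name for gl in lists]
    if len(set(names)) != len(names):
        raise ValueError(f"gene lists must have distinct names, got {names}")

    membership: dict[str, set[str]] = {}
    for gl in lists:
        for sym in gl.symbol_set:
            membership.setdefault(sym, set()).add(gl.name)

    groups: dict[str, set[str]] = {}
    for r in range(len(names), 0, -1):
        for combo in combinations(names, r):
            groups[region_label(combo)] = set()
    for sym, present in membership.items():
        combo = tuple(n for n in names if n in present)
        groups[region_label(combo)].add(sym)

    return VennPartition(list_names=names, groups=groups, total_unique=len(membership))


def membership_table(partition: VennPartition) -> pd.DataFrame:
    """One row per symbol: boolean membership per list plus the region label."""
    rows = []
    for label, members in partition.groups.items():
        for sym in sorted(members):
            in_list = {
                name: (name in label.replace(" only", "").split("+"))
                for name in partition.list_names
            }
            rows.append({"symbol": sym, **in_list, "region": label})
    frame = pd.DataFrame(rows, columns=["symbol", *partition.list_names, "region"])
    return frame.sort_values("symbol", ignore_index=True)


def write_region_report(partition: VennPartition, path: str | Path) -> None:
    """TSV: region, size, comma-joined symbols (deterministic order)."""
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("region\tsize\tsymbols\n")
        for label, members in partition.groups.items():
            fh.write(f"{label}\t{len(members)}\t{','.join(sorted(members))}\n")
        fh.write(f"total_unique\t{partition.total_unique}\t\n")


def write_membership_table(partition: VennPartition, path: str | Path) -> None:
    membership_table(partition).to_csv(path, sep="\t", index=False, lineterminator="\n")
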