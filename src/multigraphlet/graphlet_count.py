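"""Hash-based counting of 2- and 3-node graphlets in labeled multidigraphs.

A 2-node graphlet is identified by the 8-bit code of its edge; a 3-node
graphlet by the 24-bit concatenation of its three pairwise codes (zeros for
an absent closing edge).  Enumeration walks adjacency lists — every ordered
path (a, b, c) centered at b — so the work is proportional to the sum of
squared degrees.  Keys are canonicalized so isomorphic graphlets share one
table entry, and raw enumeration tallies are divided by the enumeration
multiplicity (2 per open path, 6 per triangle) to yield instance counts.

Only the most specific multi-label occurrence is counted: a pair's full
consolidated code is the key contribution; label subsets do not add to the
counts of more generic graphlets.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, Tuple

from .edge_encoding import (
    ZERO_CODE,
    canonical_2node,
    canonical_3node,
    split_3node_key,
    symmetric_code,
)
from .network_build import LabeledMultiDigraph

__all__ = [
    "GraphletCountTable",
    "count_2node",
    "count_3node",
    "count_graphlets",
    "total_instances",
    "write_count_table",
    "read_count_table",
]


@dataclass
class GraphletCountTable:
    """Canonical graphlet key → instance count for one network."""

    counts: Dict[str, int] = field(default_factory=dict)
    label: str = ""
    min_count: int = 1

    def __getitem__(self, key: str) -> int:
        return self.counts[key]

    def get(self, key: str, default: int = 0) -> int:
        return self.counts.get(key, default)

    def __len__(self) -> int:
        return len(self.counts)

    def __contains__(self, key: str) -> bool:
        return key in self.counts

    def items(self) -> Iterator[Tuple[str, int]]:
        return iter(sorted(self.counts.items()))

    def merged_with(self, other: "GraphletCountTable") -> "GraphletCountTable":
        """Union of two tables with disjoint key sets (e.g. sizes 2 and 3)."""
        overlap = set(self.counts) & set(other.counts)
        if overlap:
            raise ValueError(f"tables share keys: {sorted(overlap)[:3]}")
        merged = dict(self.counts)
        merged.update(other.counts)
        return GraphletCountTable(
            merged, self.label or other.label, max(self.min_count, other.min_count)
        )

    def thresholded(self, min_count: int) -> "GraphletCountTable":
        return GraphletCountTable(
            {k: c for k, c in self.counts.items() if c >= min_count},
            self.label,
            min_count,
        )


def count_2node(graph: LabeledMultiDigraph, label: str = "") -> GraphletCountTable:
    """Count 2-node graphlets: one increment per connected unordered pair."""
    tally: Counter = Counter()
    for _a, _b, code in graph.pairs():
        tally[canonical_2node(code)] += 1
    return GraphletCountTable(dict(tally), label)


def count_3node(
    graph: LabeledMultiDigraph,
    min_count: int = 1,
    raw_tallies: bool = False,
    label: str = "",
) -> GraphletCountTable:
    """Count 3-node graphlets by enumerating ordered 2-paths.

    For every ordered path (a, b, c) with both edges present, the 24-bit
    key ``e(a,b) + e(b,c) + e(c,a)`` is canonicalized and tallied (the
    closing segment is all-zero when c and a are unconnected).  Tallies are
    divided by the enumeration multiplicity — 6 for triangles, 2 for open
    paths — unless ``raw_tallies`` is set.  Keys with instance count below
    ``min_count`` are removed.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    tally: Counter = Counter()
    adj = {node: graph.neighbors(node) for node in graph.nodes}
    for b, nbrs in adj.items():
        items = list(nbrs.items())
        for a, e_ba in items:
            e_ab = symmetric_code(e_ba)
            for c, e_bc in items:
                if c == a:
                    continue
                e_ca = adj[c].get(a, ZERO_CODE)
                key = canonical_3node(e_ab, e_bc, e_ca)
                tally[key] += 1
    counts: Dict[str, int] = {}
    for key, t in tally.items():
        if raw_tallies:
            counts[key] = t
        else:
            segs = split_3node_key(key)
            mult = 6 if all(s != ZERO_CODE for s in segs) else 2
            if t % mult:
                raise AssertionError(
                    f"tally {t} for {key} not divisible by multiplicity {mult}"
                )
            counts[key] = t // mult
    if min_count > 1:
        counts = {k: c for k, c in counts.items() if c >= min_count}
    return GraphletCountTable(counts, label, min_count)


def count_graphlets(
    graph: LabeledMultiDigraph,
    min_count: int = 1,
    raw_tallies: bool = False,
    label: str = "",
) -> GraphletCountTable:
    """Joint table of 2- and 3-node graphlet counts (disjoint key lengths)."""
    two = count_2node(graph, label)
    if min_count > 1:
        two = two.thresholded(min_count)
    three = count_3node(graph, min_count=min_count, raw_tallies=raw_tallies,
                        label=label)
    return two.merged_with(three)


def total_instances(table: GraphletCountTable) -> int:
    """Sum of counts: connected pairs (size 2) or connected triples (size 3)."""
    return sum(table.counts.values())


def write_count_table(table: GraphletCountTable, path: str | Path) -> None:
    """TSV ``key  size  count`` in lexicographic key order within size."""
    with open(path, "w", encoding="utf-8") as fh:
        for key, count in sorted(
            table.counts.items(), key=lambda kv: (len(kv[0]), kv[0])
        ):
            size = 2 if len(key) == 8 else 3
            fh.write(f"{key}\t{size}\t{count}\n")


def read_count_table(path: str | Path, label: str = "") -> GraphletCountTable:
    counts: Dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            key, _size, count = line.rstrip("\n").split("\t")
            counts[key] = int(count)
    return GraphletCountTable(counts, label)
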