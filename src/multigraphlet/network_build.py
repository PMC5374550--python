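"""Build labeled multidigraphs from interaction files and expression data.

The integrated network is read from extended SIF (tab-separated
``source  interaction-type  target`` triples).  All relations between an
unordered protein pair are consolidated into one 8-bit :mod:`edge code
<multigraphlet.edge_encoding>`, stored bidirectionally: each endpoint's
adjacency list holds the code from its own point of view, so either list
alone carries the complete relation set.

Condition-specific subnetworks are induced from a gene × sample expression
matrix: a gene is active in a condition when its aggregated expression over
that condition's replicates exceeds a noise threshold ``r`` (default 10.0
on the RMA scale), and the subnetwork keeps exactly the edges with both
endpoints active.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Mapping, Set, Tuple

import pandas as pd

from .edge_encoding import (
    DROPPED_TYPES,
    INTERACTION_TYPES,
    REVERSE_LABELS,
    ZERO_CODE,
    decode_edge,
    encode_edge,
    symmetric_code,
)

logger = logging.getLogger(__name__)

__all__ = [
    "LabeledMultiDigraph",
    "ExpressionMatrix",
    "TissueNetwork",
    "read_extended_sif",
    "build_graph",
    "graph_to_triples",
    "active_genes",
    "induce_subgraph",
    "classify_interaction_counts",
    "write_network",
    "read_network",
    "write_sif",
    "read_expression",
    "write_expression",
]

#: identifier prefixes marking chemical compounds (skipped rows)
DEFAULT_COMPOUND_PREFIXES: Tuple[str, ...] = ("CHEBI:",)

Triple = Tuple[str, str, str]


class LabeledMultiDigraph:
    """Adjacency-list multidigraph with one consolidated 8-bit code per pair.

    Invariants: no self-edges; for every stored entry ``(a, b, code)`` the
    mirror ``(b, a, symmetric_code(code))`` is stored too; at most one entry
    per ordered pair.
    """

    __slots__ = ("_adj",)

    def __init__(self) -> None:
        self._adj: Dict[str, Dict[str, str]] = {}

    # -- construction -----------------------------------------------------
    def add_node(self, node: str) -> None:
        self._adj.setdefault(node, {})

    def add_pair(self, a: str, b: str, code_ab: str) -> None:
        """Store the edge a–b with ``code_ab`` encoded from a's point of view."""
        if a == b:
            raise ValueError(f"self-edge on {a!r} is not allowed")
        if code_ab == ZERO_CODE:
            raise ValueError("the all-zero code cannot be stored as an edge")
        if b in self._adj.get(a, ()):
            raise ValueError(f"pair {a!r}–{b!r} already has an edge")
        self.add_node(a)
        self.add_node(b)
        self._adj[a][b] = code_ab
        self._adj[b][a] = symmetric_code(code_ab)

    def remove_pair(self, a: str, b: str) -> None:
        del self._adj[a][b]
        del self._adj[b][a]

    # -- queries ----------------------------------------------------------
    @property
    def nodes(self) -> List[str]:
        return list(self._adj)

    def __contains__(self, node: str) -> bool:
        return node in self._adj

    def neighbors(self, node: str) -> Dict[str, str]:
        """Mapping neighbor → code encoded from ``node``'s point of view."""
        return self._adj[node]

    def code(self, a: str, b: str) -> str | None:
        """Code of the edge a → b, or None when the pair is unconnected."""
        return self._adj.get(a, {}).get(b)

    def degree(self, node: str) -> int:
        return len(self._adj[node])

    @property
    def n_nodes(self) -> int:
        return len(self._adj)

    @property
    def n_pairs(self) -> int:
        """Number of connected unordered pairs."""
        return sum(len(nbrs) for nbrs in self._adj.values()) // 2

    @property
    def n_directed_entries(self) -> int:
        """Number of stored adjacency entries (2 per connected pair)."""
        return sum(len(nbrs) for nbrs in self._adj.values())

    def pairs(self) -> Iterator[Tuple[str, str, str]]:
        """Each connected pair once, as ``(a, b, code_ab)`` with a < b."""
        for a, nbrs in self._adj.items():
            for b, code in nbrs.items():
                if a < b:
                    yield a, b, code

    def ordered_edges(self) -> Iterator[Tuple[str, str, str]]:
        """Every stored entry, both directions."""
        for a, nbrs in self._adj.items():
            for b, code in nbrs.items():
                yield a, b, code

    # -- auditing / utilities ---------------------------------------------
    def check_symmetry(self) -> None:
        """Raise if any entry lacks its symmetric mirror or is a self-edge."""
        for a, b, code in self.ordered_edges():
            if a == b:
                raise AssertionError(f"self-edge stored on {a!r}")
            mirror = self._adj.get(b, {}).get(a)
            if mirror != symmetric_code(code):
                raise AssertionError(
                    f"asymmetric storage for {a!r}–{b!r}: {code} vs {mirror}"
                )

    def degree_vectors(self) -> Dict[str, Counter]:
        """Per node, the multiset of adjacency codes (the typed degree vector)."""
        return {a: Counter(nbrs.values()) for a, nbrs in self._adj.items()}

    def copy(self) -> "LabeledMultiDigraph":
        g = LabeledMultiDigraph()
        g._adj = {a: dict(nbrs) for a, nbrs in self._adj.items()}
        return g

    def relabel(self, mapping: Mapping[str, str]) -> "LabeledMultiDigraph":
        g = LabeledMultiDigraph()
        g._adj = {
            mapping[a]: {mapping[b]: code for b, code in nbrs.items()}
            for a, nbrs in self._adj.items()
        }
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LabeledMultiDigraph):
            return NotImplemented
        return self._adj == other._adj

    def __repr__(self) -> str:
        return (
            f"<LabeledMultiDigraph {self.n_nodes} nodes, "
            f"{self.n_pairs} connected pairs>"
        )


@dataclass
class ExpressionMatrix:
    """Gene × sample expression values plus a sample → condition map."""

    values: pd.DataFrame  # rows genes, columns samples
    sample_conditions: Dict[str, str]

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene identifiers: {list(dupes)[:5]}")
        missing = [s for s in self.values.columns if s not in self.sample_conditions]
        if missing:
            raise ValueError(f"samples without a condition label: {missing[:5]}")

    @property
    def genes(self) -> List[str]:
        return list(self.values.index)

    @property
    def conditions(self) -> List[str]:
        seen: Dict[str, None] = {}
        for s in self.values.columns:
            seen.setdefault(self.sample_conditions[s], None)
        return list(seen)

    def samples_of(self, condition: str) -> List[str]:
        cols = [
            s for s in self.values.columns if self.sample_conditions[s] == condition
        ]
        if not cols:
            raise KeyError(
                f"unknown condition {condition!r}; available: {self.conditions}"
            )
        return cols


@dataclass
class TissueNetwork:
    """A condition-specific subnetwork induced on the active genes."""

    condition: str
    graph: LabeledMultiDigraph
    n_genes_requested: int = 0
    n_genes_missing: int = 0


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_extended_sif(
    path: str | Path,
    *,
    compound_prefixes: Iterable[str] = DEFAULT_COMPOUND_PREFIXES,
    drop_types: Iterable[str] = DROPPED_TYPES,
) -> List[Triple]:
    """Read protein–protein triples from an extended SIF file.

    Rows involving chemical-compound identifiers (matched by prefix) are
    skipped, as are rows with an excluded interaction type.  Columns beyond
    the third are ignored; duplicate triples are deduplicated; malformed or
    unrecognized rows are skipped with a warning.  The synthesized reverse
    labels must not appear in input and raise ``ValueError``.
    """
    prefixes = tuple(compound_prefixes)
    dropped = frozenset(drop_types)
    triples: List[Triple] = []
    seen: Set[Triple] = set()
    n_compound = n_dropped = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                logger.warning("%s:%d: fewer than 3 columns, skipped", path, lineno)
                continue
            source, itype, target = cols[0], cols[1], cols[2]
            if itype in REVERSE_LABELS:
                raise ValueError(
                    f"{path}:{lineno}: reverse label {itype!r} is not valid input"
                )
            if itype not in INTERACTION_TYPES:
                logger.warning(
                    "%s:%d: unrecognized interaction type %r, skipped",
                    path, lineno, itype,
                )
                continue
            if source.startswith(prefixes) or target.startswith(prefixes):
                n_compound += 1
                continue
            if itype in dropped:
                n_dropped += 1
                continue
            triple = (source, itype, target)
            if triple not in seen:
                seen.add(triple)
                triples.append(triple)
    if n_compound:
        logger.info("%s: skipped %d compound rows", path, n_compound)
    if n_dropped:
        logger.info("%s: skipped %d rows of excluded types", path, n_dropped)
    return triples


def build_graph(
    triples: Iterable[Triple], isolated_nodes: Iterable[str] = ()
) -> LabeledMultiDigraph:
    """Consolidate triples into a labeled multidigraph, one code per pair."""
    by_pair: Dict[Tuple[str, str], List[Tuple[str, str]]] = defaultdict(list)
    n_self = 0
    for source, itype, target in triples:
        if source == target:
            n_self += 1
            continue
        a, b = (source, target) if source < target else (target, source)
        info = INTERACTION_TYPES.get(itype)
        if info is None:
            raise ValueError(f"unknown interaction type {itype!r}")
        if info.dropped:
            raise ValueError(f"excluded interaction type {itype!r} reached build")
        if not info.directed:
            direction = "undirected"
        else:
            direction = "forward" if (source, target) == (a, b) else "reverse"
        by_pair[(a, b)].append((itype, direction))
    if n_self:
        logger.warning("discarded %d self-loop triples", n_self)
    g = LabeledMultiDigraph()
    for (a, b), interactions in by_pair.items():
        g.add_pair(a, b, encode_edge(interactions))
    for node in isolated_nodes:
        g.add_node(node)
    return g


def graph_to_triples(graph: LabeledMultiDigraph) -> List[Triple]:
    """Decode every consolidated edge back into interaction triples."""
    triples: List[Triple] = []
    for a, b, code in sorted(graph.pairs()):
        for name, direction in decode_edge(code):
            if direction == "reverse":
                triples.append((b, name, a))
            else:
                triples.append((a, name, b))
    return triples


def write_sif(graph: LabeledMultiDigraph, path: str | Path) -> None:
    """Write the graph as plain SIF triples (decoding each multi-label edge)."""
    with open(path, "w", encoding="utf-8") as fh:
        for source, itype, target in graph_to_triples(graph):
            fh.write(f"{source}\t{itype}\t{target}\n")


def write_network(graph: LabeledMultiDigraph, path: str | Path) -> None:
    """Write one canonical direction per pair: ``source  target  code8``."""
    with open(path, "w", encoding="utf-8") as fh:
        for a, b, code in sorted(graph.pairs()):
            fh.write(f"{a}\t{b}\t{code}\n")
        # isolated nodes, one per line with empty partner columns
        connected = {n for n in graph.nodes if graph.degree(n) > 0}
        for node in sorted(set(graph.nodes) - connected):
            fh.write(f"{node}\t\t\n")


def read_network(path: str | Path) -> LabeledMultiDigraph:
    g = LabeledMultiDigraph()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            a, b, code = line.split("\t")
            if not b:
                g.add_node(a)
            else:
                g.add_pair(a, b, code)
    return g


def read_expression(
    expr_path: str | Path, conditions_path: str | Path
) -> ExpressionMatrix:
    """Read a gene × sample TSV plus a two-column sample → condition TSV."""
    values = pd.read_csv(expr_path, sep="\t", index_col=0)
    cond = pd.read_csv(
        conditions_path, sep="\t", header=None, names=["sample", "condition"]
    )
    return ExpressionMatrix(values, dict(zip(cond["sample"], cond["condition"])))


def write_expression(
    matrix: ExpressionMatrix, expr_path: str | Path, conditions_path: str | Path
) -> None:
    matrix.values.to_csv(expr_path, sep="\t")
    with open(conditions_path, "w", encoding="utf-8") as fh:
        for sample in matrix.values.columns:
            fh.write(f"{sample}\t{matrix.sample_conditions[sample]}\n")


# ---------------------------------------------------------------------------
# condition-specific networks
# ---------------------------------------------------------------------------

_AGGREGATORS = {"mean", "median", "min"}


def active_genes(
    matrix: ExpressionMatrix,
    condition: str,
    r: float = 10.0,
    agg: str = "mean",
) -> Set[str]:
    """Genes whose aggregated expression over the condition's replicates is > r.

    The threshold is strict; ``agg`` selects how replicate samples are
    summarized (mean by default, optionally median or min).
    """
    if r < 0:
        raise ValueError("threshold r must be nonnegative")
    if agg not in _AGGREGATORS:
        raise ValueError(f"agg must be one of {sorted(_AGGREGATORS)}")
    cols = matrix.samples_of(condition)
    sub = matrix.values[cols]
    summary = getattr(sub, agg)(axis=1)
    return set(summary.index[summary > r])


def induce_subgraph(
    graph: LabeledMultiDigraph, genes: Iterable[str], condition: str = "subset"
) -> TissueNetwork:
    """Subnetwork on ``genes``: keep a node iff listed, an edge iff both ends kept."""
    wanted = set(genes)
    kept = wanted & set(graph.nodes)
    missing = len(wanted) - len(kept)
    if missing:
        logger.info(
            "%s: %d requested genes absent from the network", condition, missing
        )
    sub = LabeledMultiDigraph()
    for node in kept:
        sub.add_node(node)
    for a, b, code in graph.pairs():
        if a in kept and b in kept:
            sub.add_pair(a, b, code)
    if not kept:
        logger.warning("%s: empty intersection with the network", condition)
    return TissueNetwork(condition, sub, len(wanted), missing)


def classify_interaction_counts(counts: Mapping[str, int]) -> Dict[str, int]:
    """Split per-type pair counts into undirected / directed / dropped totals.

    Bookkeeping over a type-count table (e.g. the per-type pair counts a
    provider reports): undirected and directed totals cover only the types
    retained in the integrated network.
    """
    totals = {"undirected": 0, "directed": 0, "dropped": 0}
    for name, n in counts.items():
        info = INTERACTION_TYPES.get(name)
        if info is None:
            raise ValueError(f"unknown interaction type {name!r}")
        if info.dropped:
            totals["dropped"] += n
        elif info.directed:
            totals["directed"] += n
        else:
            totals["undirected"] += n
    return totals
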