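"""Seeded generators for synthetic networks and expression matrices.

Every pipeline stage is testable without downloads: the generators emit
labeled multidigraphs with a configurable multi-label edge composition
(skewed toward undirected physical interactions, as in curated integrated
networks), optionally with graphlet instances planted on fresh node
triples, plus RMA-scale expression matrices whose active/inactive status
per gene and condition is known exactly by construction.

All outputs are bit-reproducible from (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .edge_encoding import ZERO_CODE, canonical_key, split_3node_key, symmetric_code
from .network_build import ExpressionMatrix, LabeledMultiDigraph

__all__ = [
    "SynthSpec",
    "default_spec",
    "gen_multidigraph",
    "plant_graphlets",
    "gen_expression",
    "DEFAULT_EDGE_COUNTS",
]

#: Default multi-label edge composition: expected edge counts per code on the
#: default 200-node graph.  Undirected physical interaction dominates, a few
#: directed and mixed codes recur at intermediate rates, and one reciprocal
#: catalysis code is rare — a skew like the one real integrated networks show.
DEFAULT_EDGE_COUNTS: Dict[str, float] = {
    "10000000": 260.0,  # interacts-with
    "01000000": 120.0,  # in-complex-with
    "00100000": 60.0,   # catalysis-precedes (forward)
    "00010000": 40.0,   # controls-expression-of
    "00001000": 40.0,   # controls-state-change-of
    "11000000": 25.0,   # physical + complex
    "01001001": 15.0,   # complex + reciprocal state change
    "00101100": 6.0,    # reciprocal catalysis + state change
}


@dataclass
class SynthSpec:
    """Parameters for the synthetic network + expression generators.

    ``edge_probs`` gives the per-pair probability of each code; the
    alternative ``edge_counts`` gives expected edge counts, converted by
    dividing by the number of unordered pairs.  Each pair receives at most
    one code.  ``planted`` lists ``(canonical_3node_key, copies)`` to place
    on fresh triples.  Expression values stay outside the open interval
    (r − margin, r + margin), so activity under the strict threshold r is
    unambiguous.
    """

    n_nodes: int = 200
    edge_probs: Dict[str, float] | None = None
    edge_counts: Dict[str, float] | None = None
    planted: List[Tuple[str, int]] = field(default_factory=list)
    orientation_flip: bool = True
    # expression block
    n_genes: int = 200
    conditions: Sequence[str] = ("cond_a", "cond_b")
    n_samples_per_condition: int = 3
    active_fraction: float = 0.6
    r: float = 10.0
    margin: float = 0.5
    spread: float = 4.0
    low: float = 2.0
    seed: int = 0

    def pair_probs(self) -> Dict[str, float]:
        n_pairs = self.n_nodes * (self.n_nodes - 1) // 2
        if (self.edge_probs is None) == (self.edge_counts is None):
            raise ValueError("give exactly one of edge_probs or edge_counts")
        if self.edge_probs is not None:
            probs = dict(self.edge_probs)
        else:
            probs = {c: v / n_pairs for c, v in self.edge_counts.items()}
        for code, p in probs.items():
            if code == ZERO_CODE:
                raise ValueError("the all-zero code cannot be placed as an edge")
            if not 0.0 <= p <= 1.0:
                raise ValueError(
                    f"infeasible spec: per-pair probability {p:.3g} for {code} "
                    "is outside [0, 1]"
                )
        if sum(probs.values()) > 1.0 + 1e-12:
            raise ValueError("infeasible spec: per-pair probabilities sum above 1")
        return probs

    def validate_expression(self) -> None:
        if self.margin <= 0:
            raise ValueError("margin must be positive for unambiguous activity")
        if not 0.0 <= self.active_fraction <= 1.0:
            raise ValueError("active_fraction must be in [0, 1]")
        if self.low >= self.r - self.margin:
            raise ValueError("low must sit below r - margin")


def default_spec(seed: int = 0, **overrides) -> SynthSpec:
    """A SynthSpec with the default edge composition (see DEFAULT_EDGE_COUNTS)."""
    kw = dict(edge_counts=dict(DEFAULT_EDGE_COUNTS), seed=seed)
    kw.update(overrides)
    return SynthSpec(**kw)


def _node_names(n: int) -> List[str]:
    width = max(4, len(str(n - 1)))
    return [f"G{i:0{width}d}" for i in range(n)]


def gen_multidigraph(
    spec: SynthSpec, rng: np.random.Generator | None = None
) -> Tuple[LabeledMultiDigraph, List[Tuple[str, str, str]]]:
    """Sample a labeled multidigraph; returns the graph and a placement log.

    Each unordered pair independently receives at most one code, drawn
    from the spec's per-pair probabilities.  For asymmetric codes the
    stored orientation is flipped with probability 1/2 (when
    ``orientation_flip``) so directed relations point both ways across the
    node ordering.
    """
    probs = spec.pair_probs()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    codes = sorted(probs)
    cum = np.cumsum([probs[c] for c in codes])
    names = _node_names(spec.n_nodes)
    g = LabeledMultiDigraph()
    for name in names:
        g.add_node(name)
    log: List[Tuple[str, str, str]] = []
    for i in range(spec.n_nodes):
        for j in range(i + 1, spec.n_nodes):
            u = rng.random()
            k = int(np.searchsorted(cum, u, side="right"))
            if k >= len(codes):
                continue
            code = codes[k]
            if spec.orientation_flip and code != symmetric_code(code):
                if rng.random() < 0.5:
                    code = symmetric_code(code)
            g.add_pair(names[i], names[j], code)
            log.append((names[i], names[j], code))
    return g, log


def plant_graphlets(
    graph: LabeledMultiDigraph,
    key: str,
    copies: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> Tuple[LabeledMultiDigraph, List[Tuple[str, str, str]]]:
    """Place ``copies`` instances of a canonical 3-node key on fresh triples.

    Triples are node-disjoint across copies and internally unconnected in
    the input graph, so counting the result finds at least ``copies``
    instances of the key (any excess comes from background collisions).
    Returns a new graph and the list of triples used.
    """
    try:
        ok = len(key) == 24 and canonical_key(key) == key
    except ValueError:
        ok = False
    if not ok:
        raise ValueError(f"not a canonical 3-node key: {key!r}")
    if copies < 0:
        raise ValueError("copies must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    g = graph.copy()
    if copies == 0:
        return g, []
    e_ab, e_bc, e_ca = split_3node_key(key)
    nodes = sorted(g.nodes)
    order = list(rng.permutation(len(nodes)))
    used: Set[str] = set()
    planted: List[Tuple[str, str, str]] = []

    def fresh(a: str, b: str, c: str) -> bool:
        if used & {a, b, c}:
            return False
        return all(g.code(x, y) is None for x, y in ((a, b), (b, c), (c, a)))

    pool = [nodes[i] for i in order]
    idx = 0
    while len(planted) < copies:
        # scan for the next triple of mutually unconnected, unused nodes
        found = None
        for p in range(idx, len(pool) - 2):
            a = pool[p]
            if a in used:
                continue
            for q in range(p + 1, len(pool) - 1):
                b = pool[q]
                if b in used:
                    continue
                for s in range(q + 1, len(pool)):
                    c = pool[s]
                    if c in used:
                        continue
                    if fresh(a, b, c):
                        found = (a, b, c)
                        break
                if found:
                    break
            if found:
                break
        if found is None:
            raise ValueError(
                f"insufficient fresh triples: placed {len(planted)} of {copies}"
            )
        a, b, c = found
        for (x, y), code in (((a, b), e_ab), ((b, c), e_bc), ((c, a), e_ca)):
            if code != ZERO_CODE:
                g.add_pair(x, y, code)
        used.update((a, b, c))
        planted.append((a, b, c))
    return g, planted


def gen_expression(
    spec: SynthSpec, rng: np.random.Generator | None = None
) -> Tuple[ExpressionMatrix, Dict[str, Set[str]]]:
    """Sample an expression matrix plus the exact active-gene truth table.

    Active genes draw every replicate value uniformly from
    (r + margin, r + margin + spread); inactive genes from
    (low, r − margin).  Activity is assigned per condition independently.
    """
    spec.validate_expression()
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    # gene identifiers share the node naming scheme so that expression rows
    # line up with network nodes when n_genes matches n_nodes
    genes = _node_names(spec.n_genes)
    n_active = round(spec.active_fraction * spec.n_genes)
    columns: List[str] = []
    sample_conditions: Dict[str, str] = {}
    blocks: List[np.ndarray] = []
    truth: Dict[str, Set[str]] = {}
    for cond in spec.conditions:
        active_idx = rng.choice(spec.n_genes, size=n_active, replace=False)
        active = np.zeros(spec.n_genes, dtype=bool)
        active[active_idx] = True
        truth[cond] = {genes[i] for i in np.flatnonzero(active)}
        block = np.empty((spec.n_genes, spec.n_samples_per_condition))
        lo_a, hi_a = spec.r + spec.margin, spec.r + spec.margin + spec.spread
        lo_i, hi_i = spec.low, spec.r - spec.margin
        for k in range(spec.n_samples_per_condition):
            vals = np.where(
                active,
                rng.uniform(lo_a, hi_a, size=spec.n_genes),
                rng.uniform(lo_i, hi_i, size=spec.n_genes),
            )
            block[:, k] = vals
            sample = f"{cond}_s{k}"
            columns.append(sample)
            sample_conditions[sample] = cond
        blocks.append(block)
    values = pd.DataFrame(np.hstack(blocks), index=genes, columns=columns)
    return ExpressionMatrix(values, sample_conditions), truth
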