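"""Bit-vector encoding of multi-label directed edges and canonical graphlet keys.

Integrated protein networks carry several relation types between the same
pair of proteins: physical binding, complex membership, metabolic ordering
and regulatory control.  All relations connecting an ordered protein pair
(a, b) are consolidated into a single 8-bit vector, rendered as an
8-character ``'0'``/``'1'`` string with bit 1 leftmost:

======  ===========================  ==============================
 bit     label                        meaning for the pair (a, b)
======  ===========================  ==============================
 1       interacts-with               undirected physical interaction
 2       in-complex-with              undirected complex co-membership
 3       catalysis-precedes           directed, a before b
 4       controls-expression-of       directed, a regulates b
 5       controls-state-change-of     directed, a modifies b
 6       catalysis-succeeds           directed, b before a
 7       expression-controlled-by     directed, b regulates a
 8       state-changed-by             directed, b modifies a
======  ===========================  ==============================

The reverse labels on bits 6-8 never appear in input files; they are
synthesized so that both endpoints of an edge can store the complete
relation set from their own point of view (the two encodings are related
by :func:`symmetric_code`).

A 2-node graphlet is identified by one such code; a 3-node graphlet by the
24-character concatenation ``e(a,b) + e(b,c) + e(c,a)`` where an absent
closing edge is written as eight zeros.  Isomorphic graphlets are collapsed
onto a canonical key: the lexicographically smallest bit string over all
node orderings (2 for pairs, 6 for triples).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations
from typing import Dict, Iterable, List, Tuple

__all__ = [
    "InteractionType",
    "INTERACTION_TYPES",
    "DROPPED_TYPES",
    "REVERSE_LABELS",
    "ZERO_CODE",
    "Direction",
    "encode_edge",
    "decode_edge",
    "symmetric_code",
    "canonical_2node",
    "canonical_3node",
    "canonical_key",
    "is_canonical",
    "split_3node_key",
    "count_distinct_2node_types",
    "all_nonzero_codes",
]

ZERO_CODE = "00000000"

Direction = str  # "undirected" | "forward" | "reverse" (relative to the ordered pair)


@dataclass(frozen=True)
class InteractionType:
    """One of the seven relation names accepted from interaction files."""

    name: str
    directed: bool
    dropped: bool = False  # parsed but excluded from the integrated network


INTERACTION_TYPES: Dict[str, InteractionType] = {
    t.name: t
    for t in (
        InteractionType("interacts-with", directed=False),
        InteractionType("in-complex-with", directed=False),
        InteractionType("controls-phosphorylation-of", directed=True, dropped=True),
        InteractionType("catalysis-precedes", directed=True),
        InteractionType("controls-expression-of", directed=True),
        InteractionType("controls-transport-of", directed=True, dropped=True),
        InteractionType("controls-state-change-of", directed=True),
    )
}

DROPPED_TYPES = frozenset(t.name for t in INTERACTION_TYPES.values() if t.dropped)

#: Synthesized labels for bits 6-8; rejected when found in input files.
REVERSE_LABELS = ("catalysis-succeeds", "expression-controlled-by", "state-changed-by")

_UNDIRECTED_BIT = {"interacts-with": 0, "in-complex-with": 1}
_FORWARD_BIT = {
    "catalysis-precedes": 2,
    "controls-expression-of": 3,
    "controls-state-change-of": 4,
}
# reverse orientation shifts the forward block (bits 3-5) onto bits 6-8
_REVERSE_OFFSET = 3

_DIRECTIONS = ("undirected", "forward", "reverse")


def _validate_code(code: str) -> None:
    if not isinstance(code, str) or len(code) != 8 or set(code) - {"0", "1"}:
        raise ValueError(f"not a valid 8-bit edge code: {code!r}")


def encode_edge(interactions: Iterable[Tuple[str, Direction]]) -> str:
    """Encode the relations on an ordered pair (a, b) as an 8-bit code.

    Parameters
    ----------
    interactions
        ``(type_name, direction)`` items, where *direction* is
        ``"undirected"`` for the two undirected types, ``"forward"`` for a
        directed relation oriented a → b and ``"reverse"`` for b → a.

    Returns
    -------
    str
        Nonzero 8-character code, bit 1 leftmost.
    """
    bits = [0] * 8
    n = 0
    for name, direction in interactions:
        n += 1
        if direction not in _DIRECTIONS:
            raise ValueError(f"unknown direction {direction!r} for {name!r}")
        if name in _UNDIRECTED_BIT:
            bits[_UNDIRECTED_BIT[name]] = 1
        elif name in _FORWARD_BIT:
            if direction == "undirected":
                raise ValueError(f"directed type {name!r} needs an orientation")
            pos = _FORWARD_BIT[name]
            if direction == "reverse":
                pos += _REVERSE_OFFSET
            bits[pos] = 1
        elif name in REVERSE_LABELS:
            raise ValueError(
                f"reverse label {name!r} is synthesized internally and is not "
                "accepted as input"
            )
        elif name in DROPPED_TYPES:
            raise ValueError(f"interaction type {name!r} is excluded and has no bit")
        else:
            raise ValueError(f"unknown interaction type {name!r}")
    if n == 0:
        raise ValueError("no interactions to encode")
    return "".join(map(str, bits))


def decode_edge(code: str) -> List[Tuple[str, Direction]]:
    """Inverse of :func:`encode_edge`; returns ``(type_name, direction)`` items."""
    _validate_code(code)
    out: List[Tuple[str, Direction]] = []
    for name, pos in _UNDIRECTED_BIT.items():
        if code[pos] == "1":
            out.append((name, "undirected"))
    for name, pos in _FORWARD_BIT.items():
        if code[pos] == "1":
            out.append((name, "forward"))
        if code[pos + _REVERSE_OFFSET] == "1":
            out.append((name, "reverse"))
    return sorted(out)


@lru_cache(maxsize=512)
def symmetric_code(code: str) -> str:
    """Re-encode an edge from the other endpoint's point of view.

    Bits 1-2 (undirected) are unchanged; the a → b block (bits 3-5) and the
    b → a block (bits 6-8) swap places.  An involution.
    """
    _validate_code(code)
    return code[:2] + code[5:8] + code[2:5]


@lru_cache(maxsize=512)
def canonical_2node(code: str) -> str:
    """Canonical key of a 2-node graphlet: min of the two endpoint encodings."""
    _validate_code(code)
    if code == ZERO_CODE:
        raise ValueError("the all-zero code does not describe a 2-node graphlet")
    return min(code, symmetric_code(code))


@lru_cache(maxsize=1 << 18)
def canonical_3node(e_ab: str, e_bc: str, e_ca: str) -> str:
    """Canonical key of a 3-node graphlet given its three pairwise codes.

    The key for a node ordering (x, y, z) is ``e(x,y) + e(y,z) + e(z,x)``;
    the canonical key is the lexicographic minimum over the six orderings,
    re-orienting each pairwise code with :func:`symmetric_code` as needed.
    At most one of the three codes may be all-zero (connectivity).
    """
    for c in (e_ab, e_bc, e_ca):
        _validate_code(c)
    if sum(c != ZERO_CODE for c in (e_ab, e_bc, e_ca)) < 2:
        raise ValueError("disconnected triple: fewer than two nonzero codes")
    pair: Dict[Tuple[int, int], str] = {}
    for (i, j), c in (((0, 1), e_ab), ((1, 2), e_bc), ((2, 0), e_ca)):
        pair[(i, j)] = c
        pair[(j, i)] = symmetric_code(c)
    return min(
        pair[(x, y)] + pair[(y, z)] + pair[(z, x)]
        for x, y, z in permutations((0, 1, 2))
    )


def split_3node_key(key: str) -> Tuple[str, str, str]:
    """Split a 24-character 3-node key into its three 8-bit segments."""
    if len(key) != 24:
        raise ValueError(f"not a 24-bit 3-node key: {key!r}")
    return key[0:8], key[8:16], key[16:24]


def canonical_key(key: str) -> str:
    """Canonicalize a key of either size (idempotent on canonical input)."""
    if len(key) == 8:
        return canonical_2node(key)
    return canonical_3node(*split_3node_key(key))


def is_canonical(key: str) -> bool:
    return canonical_key(key) == key


def all_nonzero_codes() -> List[str]:
    """All 255 nonzero 8-bit codes, ascending."""
    return [format(v, "08b") for v in range(1, 256)]


def count_distinct_2node_types(codes: Iterable[str] | None = None) -> int:
    """Number of isomorphism classes among the given codes (default: all 255)."""
    if codes is None:
        codes = all_nonzero_codes()
    return len({canonical_2node(c) for c in codes})
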