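"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive: explicit enumeration over node
permutations, all unordered pairs, and all node triples.  These functions
never call the package's counting or canonicalization code paths.
"""

from itertools import combinations, permutations

ZERO = "00000000"


def sym(code: str) -> str:
    """Block-swap re-encoding: undirected bits fixed, forward/reverse swapped."""
    return code[:2] + code[5:8] + code[2:5]


def canonical2_oracle(code: str) -> str:
    return min(code, sym(code))


def canonical3_oracle(e_ab: str, e_bc: str, e_ca: str) -> str:
    """Minimum 24-bit string over the six explicit node orderings."""
    edge = {
        ("a", "b"): e_ab, ("b", "a"): sym(e_ab),
        ("b", "c"): e_bc, ("c", "b"): sym(e_bc),
        ("c", "a"): e_ca, ("a", "c"): sym(e_ca),
    }
    keys = []
    for x, y, z in permutations("abc"):
        keys.append(edge[(x, y)] + edge[(y, z)] + edge[(z, x)])
    return min(keys)


def count2_oracle(graph) -> dict:
    """Tally canonical 2-node keys over every unordered node pair."""
    out: dict = {}
    for a, b in combinations(sorted(graph.nodes), 2):
        code = graph.code(a, b)
        if code is None:
            continue
        key = canonical2_oracle(code)
        out[key] = out.get(key, 0) + 1
    return out


def count3_oracle(graph) -> dict:
    """Tally canonical 3-node keys over every connected node triple."""
    out: dict = {}
    for a, b, c in combinations(sorted(graph.nodes), 3):
        e_ab = graph.code(a, b) or ZERO
        e_bc = graph.code(b, c) or ZERO
        e_ca = graph.code(c, a) or ZERO
        if sum(e != ZERO for e in (e_ab, e_bc, e_ca)) < 2:
            continue
        key = canonical3_oracle(e_ab, e_bc, e_ca)
        out[key] = out.get(key, 0) + 1
    return out


def random_code(rng) -> str:
    """A uniformly random nonzero 8-bit code."""
    return format(int(rng.integers(1, 256)), "08b")


def random_graph(rng, n_nodes: int, p_edge: float = 0.25):
    """A random labeled multidigraph with uniformly random nonzero codes."""
    from multigraphlet.network_build import LabeledMultiDigraph

    names = [f"N{i:03d}" for i in range(n_nodes)]
    g = LabeledMultiDigraph()
    for name in names:
        g.add_node(name)
    for i, j in combinations(range(n_nodes), 2):
        if rng.random() < p_edge:
            g.add_pair(names[i], names[j], random_code(rng))
    return g
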