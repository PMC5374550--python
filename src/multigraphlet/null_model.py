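"""Label-preserving edge shuffling and graphlet z-scores.

Randomized networks are generated by repeatedly choosing two edges that
carry the identical multi-label code, say a→b and c→d, and rewiring them to
a→d and c→b with the same code.  A swap is applied only when the four
endpoints are distinct and neither new pair is already connected, so the
randomization conserves every node's typed in/out degree vector, never
introduces self-edges, and never merges labels onto an existing pair.

Significance of a real count c_g is measured against the randomized
ensemble as z_g = (c_g − μ_g) / σ_g, where μ_g and σ_g are the ensemble
mean and standard deviation of the count of graphlet g.  A graphlet that
never occurs in the ensemble (σ_g = 0, c_g > 0) receives a +inf sentinel.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, NamedTuple, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .graphlet_count import GraphletCountTable
from .network_build import LabeledMultiDigraph

__all__ = [
    "ShuffleResult",
    "NullEnsembleStats",
    "SignatureVector",
    "shuffle_edges",
    "ensemble_stats",
    "zscores",
    "normality_check",
    "ensemble_count_matrix",
]


class ShuffleResult(NamedTuple):
    graph: LabeledMultiDigraph
    swaps: int
    attempts: int


@dataclass
class NullEnsembleStats:
    """Per-key ensemble mean and sample standard deviation of counts."""

    mean: Dict[str, float]
    std: Dict[str, float]
    n_networks: int

    def get(self, key: str) -> Tuple[float, float]:
        """(μ, σ) for a key; absence from the ensemble means (0, 0)."""
        return self.mean.get(key, 0.0), self.std.get(key, 0.0)


@dataclass
class SignatureVector:
    """Graphlet key → z-score for one network; ±inf sentinels allowed."""

    label: str
    z: Dict[str, float] = field(default_factory=dict)

    def finite_keys(self) -> Set[str]:
        return {k for k, v in self.z.items() if math.isfinite(v)}

    def __getitem__(self, key: str) -> float:
        return self.z[key]


def shuffle_edges(
    graph: LabeledMultiDigraph,
    seed: int | None = None,
    n_successful_swaps: int | None = None,
    attempt_factor: int = 100,
    rng: np.random.Generator | None = None,
) -> ShuffleResult:
    """Randomize a graph by code-preserving edge swaps.

    ``n_successful_swaps`` defaults to 10 × (connected pairs); up to
    ``attempt_factor`` × that many attempts are made before giving up with
    a warning.  Deterministic given the seed.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    g = graph.copy()
    target = 10 * g.n_pairs if n_successful_swaps is None else n_successful_swaps

    # ordered-edge pools per code; pool sizes are invariant under swaps
    by_code: Dict[str, List[List[str]]] = {}
    pos: Dict[Tuple[str, str], Tuple[str, int]] = {}
    for u, v, code in g.ordered_edges():
        lst = by_code.setdefault(code, [])
        pos[(u, v)] = (code, len(lst))
        lst.append([u, v])
    codes = sorted(by_code)
    # a swap needs two *distinct* pairs sharing a code; for a symmetric code
    # one pair contributes both ordered entries of its pool
    def _distinct_pairs(code: str) -> int:
        return len({frozenset(e) for e in by_code[code]})

    if not codes or max(_distinct_pairs(c) for c in codes) < 2:
        if target > 0:
            warnings.warn(
                "no code class has two distinct pairs; graph returned unchanged"
            )
        return ShuffleResult(g, 0, 0)
    sizes = np.array([len(by_code[c]) for c in codes])
    cum = np.cumsum(sizes)
    total = int(cum[-1])

    def _move(old: Tuple[str, str], new: Tuple[str, str]) -> None:
        code, idx = pos.pop(old)
        by_code[code][idx] = list(new)
        pos[new] = (code, idx)

    swaps = attempts = 0
    max_attempts = attempt_factor * max(target, 1)
    while swaps < target and attempts < max_attempts:
        attempts += 1
        flat = int(rng.integers(total))
        ci = int(np.searchsorted(cum, flat, side="right"))
        code = codes[ci]
        lst = by_code[code]
        i = flat - (int(cum[ci - 1]) if ci else 0)
        j = int(rng.integers(len(lst)))
        if i == j:
            continue
        a, b = lst[i]
        c, d = lst[j]
        if len({a, b, c, d}) < 4:
            continue
        if g.code(a, d) is not None or g.code(c, b) is not None:
            continue
        g.remove_pair(a, b)
        g.remove_pair(c, d)
        g.add_pair(a, d, code)
        g.add_pair(c, b, code)
        _move((a, b), (a, d))
        _move((b, a), (d, a))
        _move((c, d), (c, b))
        _move((d, c), (b, c))
        swaps += 1
    if swaps < target:
        warnings.warn(
            f"reached {swaps}/{target} successful swaps after {attempts} attempts"
        )
    return ShuffleResult(g, swaps, attempts)


def ensemble_stats(
    count_tables: Sequence[GraphletCountTable],
    keys: Sequence[str] | None = None,
) -> NullEnsembleStats:
    """Per-key mean and sample (n−1) standard deviation over an ensemble.

    A key absent from a randomized table contributes a count of 0.  By
    default the key universe is the union over the ensemble; pass ``keys``
    to extend it (e.g. with the real networks' keys).
    """
    if len(count_tables) < 2:
        raise ValueError("an ensemble needs at least 2 count tables")
    universe: Set[str] = set(keys or ())
    for t in count_tables:
        universe.update(t.counts)
    mean: Dict[str, float] = {}
    std: Dict[str, float] = {}
    for key in universe:
        vals = np.array([t.get(key, 0) for t in count_tables], dtype=float)
        mean[key] = float(vals.mean())
        std[key] = float(vals.std(ddof=1))
    return NullEnsembleStats(mean, std, len(count_tables))


def zscores(
    real: GraphletCountTable,
    null: NullEnsembleStats,
    label: str | None = None,
) -> SignatureVector:
    """z_g = (c_g − μ_g) / σ_g per key of the real table.

    With σ_g = 0 the score degenerates to ±inf (sign of c_g − μ_g) or 0
    when the real count equals the ensemble mean exactly.
    """
    z: Dict[str, float] = {}
    for key, c in real.counts.items():
        mu, sigma = null.get(key)
        if sigma > 0:
            z[key] = (c - mu) / sigma
        elif c > mu:
            z[key] = math.inf
        elif c < mu:
            z[key] = -math.inf
        else:
            z[key] = 0.0
    return SignatureVector(label if label is not None else real.label, z)


def ensemble_count_matrix(
    count_tables: Sequence[GraphletCountTable],
    keys: Sequence[str] | None = None,
) -> Dict[str, np.ndarray]:
    """Per-key vector of ensemble counts (absence → 0), for diagnostics."""
    universe: Set[str] = set(keys or ())
    for t in count_tables:
        universe.update(t.counts)
    return {
        key: np.array([t.get(key, 0) for t in count_tables], dtype=float)
        for key in universe
    }


def normality_check(
    ensemble_counts: Mapping[str, Sequence[float]],
    min_size: int = 8,
) -> pd.DataFrame:
    """Shapiro–Wilk normality test of each key's ensemble count distribution.

    Purely diagnostic: the z-score computation is never gated on the
    outcome.  Keys with a constant ensemble (or fewer than ``min_size``
    values) are flagged undefined with NaN statistics.
    """
    rows = []
    for key in sorted(ensemble_counts):
        vals = np.asarray(ensemble_counts[key], dtype=float)
        if len(vals) < min_size or np.ptp(vals) == 0.0:
            rows.append((key, math.nan, math.nan, False))
            continue
        stat, p = sps.shapiro(vals)
        rows.append((key, float(stat), float(p), True))
    return pd.DataFrame(rows, columns=["key", "statistic", "pvalue", "defined"])
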