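"""Cross-network graphlet signature analysis.

Each condition-specific network is summarized by its vector of graphlet
z-scores.  Stacking the vectors over networks gives a signature matrix
(rows = networks, columns = canonical graphlet keys) restricted to keys
with a finite z-score in every network — graphlets never seen in the
randomized ensembles carry an infinite sentinel and are excluded — and
with an instance count reaching the report threshold in at least one
network.  The matrix supports dimensionality reduction (PCA), hierarchical
clustering under the 1 − Pearson-correlation distance, and differential
comparison of two conditions.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from .edge_encoding import (
    ZERO_CODE,
    canonical_3node,
    canonical_key,
    symmetric_code,
)
from .graphlet_count import GraphletCountTable
from .network_build import LabeledMultiDigraph
from .null_model import SignatureVector

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterResult",
    "DifferentialReport",
    "assemble_matrix",
    "pca_explained_variance",
    "hcluster",
    "to_newick",
    "differential",
    "inducing_proteins",
]


def assemble_matrix(
    vectors: Sequence[SignatureVector],
    tables: Sequence[GraphletCountTable],
    min_count: int = 10,
) -> pd.DataFrame:
    """Stack signature vectors into a networks × keys z-score matrix.

    Columns keep the keys that are finite wherever they occur (any
    infinite sentinel excludes the key) and whose instance count reaches
    ``min_count`` in at least one network.  A key absent from some
    network's vector is filled with 0 (logged).  Rows and columns are
    sorted lexicographically.
    """
    vlabels = sorted(v.label for v in vectors)
    tlabels = sorted(t.label for t in tables)
    if vlabels != tlabels:
        raise ValueError(
            f"vector/table labels differ: {sorted(set(vlabels) ^ set(tlabels))}"
        )
    if len(set(vlabels)) != len(vlabels):
        raise ValueError(f"duplicate network labels in {vlabels}")
    all_keys: Set[str] = set()
    for v in vectors:
        all_keys.update(v.z)
    infinite = {
        k for v in vectors for k, z in v.z.items() if not math.isfinite(z)
    }
    reaching = {
        k for t in tables for k, c in t.counts.items() if c >= min_count
    }
    cols = sorted((all_keys - infinite) & reaching)
    rows = sorted(v.label for v in vectors)
    by_label = {v.label: v for v in vectors}
    n_filled = 0
    data = np.zeros((len(rows), len(cols)))
    for i, label in enumerate(rows):
        z = by_label[label].z
        for j, key in enumerate(cols):
            if key in z:
                data[i, j] = z[key]
            else:
                n_filled += 1
    if n_filled:
        logger.info("filled %d absent finite z entries with 0", n_filled)
    return pd.DataFrame(data, index=rows, columns=cols)


def pca_explained_variance(matrix: pd.DataFrame, k: int) -> float:
    """Cumulative fraction of variance captured by the first k components."""
    n, p = matrix.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 networks")
    if not 1 <= k <= min(n - 1, p):
        raise ValueError(f"k must be in [1, {min(n - 1, p)}], got {k}")
    X = matrix.to_numpy(dtype=float)
    if np.allclose(X.var(axis=0), 0.0):
        warnings.warn("matrix has no variance; explained fraction defined as 1")
        return 1.0
    pca = PCA(n_components=min(n - 1, p)).fit(X)
    return float(np.cumsum(pca.explained_variance_ratio_)[k - 1])


@dataclass
class ClusterResult:
    """Agglomerative clustering of signature rows.

    ``linkage`` is a scipy linkage matrix over the 1 − Pearson correlation
    distance with average linkage; ``labels`` are the leaf network labels
    in the (lexicographic) order passed to the linkage.
    """

    linkage: np.ndarray
    labels: List[str]

    def cut(self, n_clusters: int) -> Dict[str, int]:
        assign = hierarchy.fcluster(self.linkage, n_clusters, criterion="maxclust")
        return dict(zip(self.labels, map(int, assign)))


def hcluster(matrix: pd.DataFrame) -> ClusterResult:
    """Cluster networks by signature correlation (average linkage)."""
    if matrix.shape[0] < 2:
        raise ValueError("clustering needs at least 2 networks")
    flat = [
        str(label)
        for label, var in matrix.var(axis=1, ddof=0).items()
        if var == 0.0
    ]
    if flat:
        raise ValueError(f"zero-variance signature rows: {flat}")
    ordered = matrix.sort_index()
    dist = pdist(ordered.to_numpy(dtype=float), metric="correlation")
    Z = hierarchy.linkage(dist, method="average")
    return ClusterResult(Z, list(ordered.index))


def to_newick(result: ClusterResult) -> str:
    """Serialize the dendrogram as Newick with branch lengths from merge heights."""
    tree = hierarchy.to_tree(result.linkage)

    def render(node, parent_dist: float) -> str:
        length = parent_dist - node.dist
        if node.is_leaf():
            return f"{result.labels[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({render(tree.left, tree.dist)},{render(tree.right, tree.dist)});"


@dataclass
class DifferentialReport:
    """Per-key comparison of two networks' signatures and counts.

    ``shared`` ranks keys with a finite z-score in both networks by
    |z1 − z2| (descending); ``exclusive_1`` / ``exclusive_2`` list each
    network's remaining keys — those the other network lacks entirely and
    those carrying an infinite sentinel, i.e. graphlets never produced by
    that network's randomized ensemble.  The z-ratio column is populated
    only when both z-scores are positive (a ratio across zero is not
    meaningful).
    """

    label1: str
    label2: str
    shared: pd.DataFrame
    exclusive_1: pd.DataFrame
    exclusive_2: pd.DataFrame
    inducing: Dict[str, Tuple[Set[str], Set[str]]] = field(default_factory=dict)

    def by_count_fold(self) -> pd.DataFrame:
        return self.shared.sort_values(
            ["count_fold", "key"], ascending=[False, True]
        ).reset_index(drop=True)


def differential(
    vec1: SignatureVector,
    vec2: SignatureVector,
    table1: GraphletCountTable,
    table2: GraphletCountTable,
    graph1: LabeledMultiDigraph | None = None,
    graph2: LabeledMultiDigraph | None = None,
    inducing_top: int = 10,
) -> DifferentialReport:
    """Identify graphlets that recur differentially between two conditions.

    Keys scored in both networks are ranked by the absolute z-score
    difference; the count fold c1/c2 (inf when c2 = 0) is reported
    alongside.  When the graphs are supplied, the proteins inducing each of
    the top ``inducing_top`` shared keys are extracted for both networks.
    """
    shared_keys = sorted(
        k
        for k in set(vec1.z) & set(vec2.z)
        if math.isfinite(vec1.z[k]) and math.isfinite(vec2.z[k])
    )
    rows = []
    for key in shared_keys:
        z1, z2 = vec1.z[key], vec2.z[key]
        c1, c2 = table1.get(key), table2.get(key)
        delta = z1 - z2
        ratio = z1 / z2 if z1 > 0 and z2 > 0 else math.nan
        fold = c1 / c2 if c2 else (math.inf if c1 else math.nan)
        rows.append((key, z1, z2, delta, abs(delta), ratio, c1, c2, fold))
    shared = pd.DataFrame(
        rows,
        columns=[
            "key", "z1", "z2", "delta_z", "abs_delta_z",
            "z_ratio", "count1", "count2", "count_fold",
        ],
    )
    shared = shared.sort_values(
        ["abs_delta_z", "key"], ascending=[False, True]
    ).reset_index(drop=True)

    def _exclusive(vec: SignatureVector, table: GraphletCountTable) -> pd.DataFrame:
        # everything scored in this network but not comparably scored in both:
        # keys the other network lacks, plus keys carrying a +/-inf sentinel
        keys = sorted(set(vec.z) - set(shared_keys))
        return pd.DataFrame(
            [(k, vec.z[k], table.get(k)) for k in keys],
            columns=["key", "z", "count"],
        )

    report = DifferentialReport(
        vec1.label,
        vec2.label,
        shared,
        _exclusive(vec1, table1),
        _exclusive(vec2, table2),
    )
    if graph1 is not None and graph2 is not None:
        for key in shared["key"].head(inducing_top):
            report.inducing[key] = (
                inducing_proteins(graph1, key),
                inducing_proteins(graph2, key),
            )
    return report


def inducing_proteins(graph: LabeledMultiDigraph, key: str) -> Set[str]:
    """Union of node sets over all instances of a canonical graphlet key."""
    if canonical_key(key) != key:
        raise ValueError(f"key is not canonical: {key!r}")
    nodes: Set[str] = set()
    if len(key) == 8:
        for a, b, code in graph.pairs():
            if min(code, symmetric_code(code)) == key:
                nodes.update((a, b))
        return nodes
    adj = {node: graph.neighbors(node) for node in graph.nodes}
    for b, nbrs in adj.items():
        items = list(nbrs.items())
        for a, e_ba in items:
            e_ab = symmetric_code(e_ba)
            for c, e_bc in items:
                if c == a:
                    continue
                e_ca = adj[c].get(a, ZERO_CODE)
                if canonical_3node(e_ab, e_bc, e_ca) == key:
                    nodes.update((a, b, c))
    return nodes
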