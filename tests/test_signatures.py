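"""Signature matrices, PCA, correlation clustering and differential graphlets."""

import math

import numpy as np
import pandas as pd
import pytest

from multigraphlet.graphlet_count import GraphletCountTable, count_graphlets
from multigraphlet.network_build import build_graph
from multigraphlet.null_model import SignatureVector
from multigraphlet.signatures import (
    assemble_matrix,
    differential,
    hcluster,
    inducing_proteins,
    pca_explained_variance,
    to_newick,
)
from multigraphlet.synthgen import plant_graphlets
from multigraphlet.edge_encoding import canonical_3node
from oracles import random_graph


def _vec(label, **z):
    return SignatureVector(label, z)


def _table(label, **counts):
    return GraphletCountTable(counts, label)


class TestAssembleMatrix:
    def test_single_network_row(self):
        m = assemble_matrix([_vec("n1", a=1.0, b=2.0)],
                            [_table("n1", a=12, b=15)], min_count=10)
        assert list(m.index) == ["n1"]
        assert m.loc["n1", "a"] == 1.0 and m.loc["n1", "b"] == 2.0

    def test_sentinel_key_excluded(self):
        m = assemble_matrix(
            [_vec("n1", a=1.0, b=math.inf), _vec("n2", a=2.0, b=1.0)],
            [_table("n1", a=12, b=30), _table("n2", a=12, b=30)],
            min_count=10,
        )
        assert list(m.columns) == ["a"]

    def test_min_count_requires_one_network_only(self):
        m = assemble_matrix(
            [_vec("n1", a=1.0), _vec("n2", a=2.0)],
            [_table("n1", a=3), _table("n2", a=12)],
            min_count=10,
        )
        assert list(m.columns) == ["a"]

    def test_absent_finite_entry_filled_with_zero(self):
        m = assemble_matrix(
            [_vec("n1", a=1.0, b=4.0), _vec("n2", a=2.0)],
            [_table("n1", a=12, b=12), _table("n2", a=12)],
            min_count=10,
        )
        assert m.loc["n2", "b"] == 0.0

    def test_label_mismatch_names_offenders(self):
        with pytest.raises(ValueError, match="n2"):
            assemble_matrix([_vec("n1", a=1.0)], [_table("n2", a=12)])

    def test_column_logic_matches_set_oracle(self, rng):
        keys = [f"k{i}" for i in range(30)]
        vectors, tables = [], []
        for label in ("n1", "n2", "n3", "n4", "n5"):
            z = {}
            counts = {}
            for k in keys:
                if rng.random() < 0.8:
                    z[k] = (math.inf if rng.random() < 0.1
                            else float(rng.normal()))
                    counts[k] = int(rng.integers(1, 30))
            vectors.append(SignatureVector(label, z))
            tables.append(GraphletCountTable(counts, label))
        m = assemble_matrix(vectors, tables, min_count=10)
        # brute-force set logic
        union = set().union(*(v.z for v in vectors))
        bad = {k for v in vectors for k, z in v.z.items() if math.isinf(z)}
        reach = {k for t in tables for k, c in t.counts.items() if c >= 10}
        assert list(m.columns) == sorted((union - bad) & reach)
        for v in vectors:
            for k in m.columns:
                assert m.loc[v.label, k] == v.z.get(k, 0.0)


class TestPCA:
    def test_rank_one_matrix(self):
        base = np.arange(6, dtype=float)
        m = pd.DataFrame(np.outer([1.0, 2.0, 3.0], base),
                         index=list("abc"), columns=range(6))
        assert pca_explained_variance(m, 1) == pytest.approx(1.0)

    def test_isotropic_noise_spreads_variance(self):
        rng = np.random.default_rng(5)
        m = pd.DataFrame(rng.normal(size=(500, 10)))
        frac = pca_explained_variance(m, 3)
        assert frac == pytest.approx(0.3, abs=0.08)

    def test_planted_three_factor_model(self):
        rng = np.random.default_rng(6)
        loadings = rng.normal(size=(30, 3))
        factors = rng.normal(size=(3, 50))
        m = pd.DataFrame(loadings @ factors + 0.01 * rng.normal(size=(30, 50)))
        assert pca_explained_variance(m, 3) >= 0.95

    def test_fractions_non_decreasing_and_complete(self):
        rng = np.random.default_rng(7)
        m = pd.DataFrame(rng.normal(size=(8, 5)))
        fracs = [pca_explained_variance(m, k) for k in range(1, 6)]
        assert all(b >= a for a, b in zip(fracs, fracs[1:]))
        assert fracs[-1] == pytest.approx(1.0)

    def test_constant_matrix_defined_as_one(self):
        m = pd.DataFrame(np.ones((4, 3)))
        with pytest.warns(UserWarning, match="no variance"):
            assert pca_explained_variance(m, 1) == 1.0

    def test_k_out_of_range(self):
        m = pd.DataFrame(np.eye(3))
        with pytest.raises(ValueError, match="k must be"):
            pca_explained_variance(m, 3)


class TestHCluster:
    def test_identical_rows_merge_first(self):
        rng = np.random.default_rng(8)
        base = rng.normal(size=10)
        m = pd.DataFrame([base, base, -base], index=["a", "b", "c"])
        result = hcluster(m)
        # first linkage row merges the two identical signatures at height 0
        i, j, height, _ = result.linkage[0]
        assert {result.labels[int(i)], result.labels[int(j)]} == {"a", "b"}
        assert height == pytest.approx(0.0, abs=1e-12)

    def test_two_planted_blocks_recovered_at_two_cluster_cut(self):
        rng = np.random.default_rng(9)
        u, v = rng.normal(size=40), rng.normal(size=40)
        rows = {
            "a1": u + 0.05 * rng.normal(size=40),
            "a2": u + 0.05 * rng.normal(size=40),
            "b1": v + 0.05 * rng.normal(size=40),
            "b2": v + 0.05 * rng.normal(size=40),
        }
        result = hcluster(pd.DataFrame(rows).T)
        cut = result.cut(2)
        assert cut["a1"] == cut["a2"] != cut["b1"]
        assert cut["b1"] == cut["b2"]

    def test_two_row_merge_height_is_one_minus_correlation(self):
        rng = np.random.default_rng(10)
        x, y = rng.normal(size=20), rng.normal(size=20)
        m = pd.DataFrame([x, y], index=["a", "b"])
        result = hcluster(m)
        expected = 1 - np.corrcoef(x, y)[0, 1]
        assert result.linkage[0][2] == pytest.approx(expected)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(11)
        m = pd.DataFrame(rng.normal(size=(5, 12)),
                         index=["a", "b", "c", "d", "e"])
        r1 = hcluster(m)
        r2 = hcluster(m.iloc[::-1])
        assert np.allclose(r1.linkage, r2.linkage)
        assert r1.labels == r2.labels

    def test_zero_variance_row_rejected_by_name(self):
        m = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]],
                         index=["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            hcluster(m)

    def test_newick_serialization(self):
        rng = np.random.default_rng(12)
        m = pd.DataFrame(rng.normal(size=(4, 8)),
                         index=["a", "b", "c", "d"])
        text = to_newick(hcluster(m))
        assert text.endswith(";")
        for label in "abcd":
            assert label in text


class TestDifferential:
    def test_large_z_gap_ranks_first(self):
        v1 = _vec("normal", big=43.40, flat=5.0)
        v2 = _vec("disease", big=-0.08, flat=5.0)
        t1 = _table("normal", big=40, flat=20)
        t2 = _table("disease", big=10, flat=20)
        report = differential(v1, v2, t1, t2)
        assert report.shared.iloc[0]["key"] == "big"
        assert report.shared.iloc[0]["delta_z"] == pytest.approx(43.48)

    def test_identical_vectors_null_report(self):
        v = _vec("n1", a=1.0, b=2.0)
        t = _table("n1", a=5, b=5)
        report = differential(v, _vec("n2", a=1.0, b=2.0), t,
                              _table("n2", a=5, b=5))
        assert (report.shared["delta_z"] == 0).all()
        assert report.exclusive_1.empty and report.exclusive_2.empty

    def test_planted_count_fold_tops_fold_ranking(self):
        v1 = _vec("n1", a=1.0, b=1.0, c=1.0)
        v2 = _vec("n2", a=1.0, b=1.0, c=1.0)
        t1 = _table("n1", a=40, b=10, c=10)
        t2 = _table("n2", a=10, b=10, c=10)
        report = differential(v1, v2, t1, t2)
        by_fold = report.by_count_fold()
        assert by_fold.iloc[0]["key"] == "a"
        assert by_fold.iloc[0]["count_fold"] == pytest.approx(4.0)

    def test_exclusive_sections(self):
        v1 = _vec("n1", shared=1.0, only1=9.0)
        v2 = _vec("n2", shared=1.5, only2=3.0)
        report = differential(v1, v2, _table("n1", shared=5, only1=12),
                              _table("n2", shared=5, only2=7))
        assert list(report.exclusive_1["key"]) == ["only1"]
        assert list(report.exclusive_2["key"]) == ["only2"]

    def test_antisymmetry(self):
        rng = np.random.default_rng(13)
        keys = [f"k{i}" for i in range(12)]
        z1 = {k: float(rng.normal()) for k in keys}
        z2 = {k: float(rng.normal()) for k in keys}
        counts = {k: int(rng.integers(1, 40)) for k in keys}
        fwd = differential(SignatureVector("a", z1), SignatureVector("b", z2),
                           GraphletCountTable(counts, "a"),
                           GraphletCountTable(counts, "b"))
        rev = differential(SignatureVector("b", z2), SignatureVector("a", z1),
                           GraphletCountTable(counts, "b"),
                           GraphletCountTable(counts, "a"))
        assert list(fwd.shared["key"]) == list(rev.shared["key"])
        assert np.allclose(fwd.shared["delta_z"], -rev.shared["delta_z"])

    def test_sentinel_keys_routed_to_exclusive_sections(self):
        v1 = _vec("n1", fin=1.0, never_in_null=math.inf)
        v2 = _vec("n2", fin=2.0, never_in_null=1.0)
        report = differential(v1, v2, _table("n1", fin=5, never_in_null=30),
                              _table("n2", fin=5, never_in_null=3))
        assert list(report.shared["key"]) == ["fin"]
        assert "never_in_null" in set(report.exclusive_1["key"])
        assert "never_in_null" in set(report.exclusive_2["key"])

    def test_zratio_only_for_positive_pairs(self):
        report = differential(_vec("a", k=-1.0), _vec("b", k=2.0),
                              _table("a", k=5), _table("b", k=5))
        assert math.isnan(report.shared.iloc[0]["z_ratio"])


class TestInducingProteins:
    def test_triangle_key_induces_all_nodes(self, triangle_graph):
        key = canonical_3node("10000000", "10000000", "10000000")
        assert inducing_proteins(triangle_graph, key) == {"X", "Y", "Z"}

    def test_absent_key_empty_set(self, triangle_graph):
        key = canonical_3node("01000000", "01000000", "01000000")
        assert inducing_proteins(triangle_graph, key) == set()

    def test_non_canonical_key_rejected(self, triangle_graph):
        with pytest.raises(ValueError, match="not canonical"):
            inducing_proteins(triangle_graph, "01100010")

    def test_two_node_key(self, worked_graph):
        assert inducing_proteins(worked_graph, "01010100") == {"PA", "PB"}

    def test_planted_instances_recovered_exactly(self, rng):
        g = random_graph(rng, 40, 0.0)  # edgeless background
        key = canonical_3node("01000000", "00100000", "01001001")
        planted, log = plant_graphlets(g, key, 6, seed=99)
        expected = {n for triple in log for n in triple}
        assert inducing_proteins(planted, key) == expected
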