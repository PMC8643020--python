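import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from scregmark.datatypes import (
    ExpressionMatrix,
    GeneSet,
    RegulationRecord,
    RegulationTable,
    ValidationError,
)
from scregmark import regnet as rn


def _expr(values, genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cells = [f"c{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(genes, cells, values, {c: "S" for c in cells})


class TestImputation:
    def test_average_complexity_cell_gets_gene_mean(self):
        # gene mean 2; the zero sits in a cell of exactly average complexity
        values = np.array([[4.0, 0.0, 2.0], [1.0, 2.0, 3.0], [5.0, 6.0, 0.0]])
        out = rn.impute_expression(_expr(values))
        g_mean = values[0].mean()  # 2.0
        complexity = (values > 0).sum(axis=0)
        expected = g_mean * complexity[1] / complexity.mean()
        assert out.values[0, 1] == pytest.approx(expected)

    def test_nonzero_entries_unchanged(self, rng):
        values = rng.poisson(2.0, size=(6, 8)).astype(float)
        out = rn.impute_expression(_expr(values))
        mask = values > 0
        assert np.array_equal(out.values[mask], values[mask])

    def test_matches_hand_formula_on_4x3(self):
        values = np.array(
            [[1.0, 0.0, 2.0], [0.0, 3.0, 1.0], [2.0, 2.0, 0.0], [4.0, 0.0, 1.0]]
        )
        out = rn.impute_expression(_expr(values))
        g_mean = values.mean(axis=1)
        c = (values > 0).sum(axis=0).astype(float)
        expected = values.copy()
        for i in range(4):
            for j in range(3):
                if values[i, j] == 0:
                    expected[i, j] = g_mean[i] * c[j] / c.mean()
        assert np.allclose(out.values, expected)

    def test_no_zeros_left_for_expressed_genes(self, rng):
        values = rng.poisson(1.0, size=(10, 12)).astype(float)
        values[0] = 0.0  # fully silent gene stays zero
        out = rn.impute_expression(_expr(values))
        expressed = values.sum(axis=1) > 0
        assert np.all(out.values[expressed] > 0)
        assert np.all(out.values[0] == 0)

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValidationError):
            rn.impute_expression(_expr(np.zeros((3, 3))))


def _table(pairs, tfs):
    return RegulationTable(
        [RegulationRecord(a, b, b in tfs, "t") for a, b in pairs]
    )


class TestRestrictPairs:
    def test_decision_rules(self):
        table = _table([("A", "g1"), ("A", "g2"), ("A", "B"), ("B", "g3")], {"A", "B"})
        out = rn.restrict_pairs(
            table,
            GeneSet("cons", {"g1", "g3"}),
            measured={"A", "B", "g1", "g2", "g3"},
        )
        assert {(r.tf, r.target) for r in out.records} == {
            ("A", "g1"),
            ("A", "B"),
            ("B", "g3"),
        }

    def test_matches_brute_force(self, rng):
        tfs = [f"T{i}" for i in range(6)]
        genes = [f"g{i}" for i in range(20)]
        pairs = {
            (tfs[rng.integers(6)], (tfs + genes)[rng.integers(26)]) for _ in range(60)
        }
        pairs = [(a, b) for a, b in pairs if a != b]
        consensus = {g for g in genes if rng.random() < 0.5}
        measured = {x for x in tfs + genes if rng.random() < 0.8}
        table = _table(pairs, set(tfs))
        expected = set()
        for a, b in pairs:
            if a not in measured or b not in measured:
                continue
            if b in tfs or b in consensus:
                expected.add((a, b))
        try:
            out = rn.restrict_pairs(table, GeneSet("c", consensus or {"x"}), measured)
            assert {(r.tf, r.target) for r in out.records} == expected
        except ValidationError:
            assert not expected

    def test_empty_result_raises_with_counts(self):
        table = _table([("A", "g1")], {"A"})
        with pytest.raises(ValidationError, match="1 input pairs"):
            rn.restrict_pairs(table, GeneSet("c", {"zz"}), measured={"A", "g1"})


class TestEdgeSimilarity:
    def test_three_four_five_distance_and_minmax(self):
        # rows: tf at (0,0), targets at (3,4) and (1.2,1.6) and (0,0)-like
        values = np.array([[0.0, 0.0], [3.0, 4.0], [1.2, 1.6], [2.4, 3.2]])
        expr = _expr(values, genes=["t", "a", "b", "c"])
        table = _table([("t", "a"), ("t", "b"), ("t", "c")], set())
        out = rn.edge_similarity(expr, table, cutoff=0.0)
        # distances {5, 2, 4} -> min-max similarities {0, 1, 1/3}
        sims = dict(zip(out["target"], out["similarity"]))
        assert sims["a"] == pytest.approx(0.0)
        assert sims["b"] == pytest.approx(1.0)
        assert sims["c"] == pytest.approx(1.0 / 3.0)

    def test_distances_2_4_6_map_to_1_half_0(self):
        values = np.array([[0.0], [2.0], [4.0], [6.0]])
        expr = _expr(values, genes=["t", "a", "b", "c"])
        table = _table([("t", "a"), ("t", "b"), ("t", "c")], set())
        out = rn.edge_similarity(expr, table, cutoff=0.0)
        sims = dict(zip(out["target"], out["similarity"]))
        assert (sims["a"], sims["b"], sims["c"]) == (1.0, 0.5, 0.0)

    def test_cutoff_monotone(self, rng):
        values = rng.random((10, 20)) * 5
        expr = _expr(values)
        pairs = [(f"g{i}", f"g{j}") for i in range(3) for j in range(3, 9)]
        table = _table(pairs, set())
        lo = rn.edge_similarity(expr, table, cutoff=0.3)
        hi = rn.edge_similarity(expr, table, cutoff=0.6)
        kept_lo = set(zip(lo["tf"], lo["target"]))
        kept_hi = set(zip(hi["tf"], hi["target"]))
        assert kept_hi <= kept_lo

    def test_degenerate_distances_all_one(self):
        values = np.array([[1.0], [2.0], [3.0]])
        expr = _expr(values, genes=["t", "a", "b"])
        table = _table([("t", "a"), ("b", "a")], set())
        out = rn.edge_similarity(expr, table, cutoff=0.6)
        assert (out["similarity"] == 1.0).all()


def _edges_frame(tf_tf, tf_gene):
    rows = [(a, b, "TF-TF", 1.0) for a, b in tf_tf]
    rows += [(a, b, "TF-gene", 1.0) for a, b in tf_gene]
    return pd.DataFrame(rows, columns=["tf", "target", "kind", "similarity"])


def _brute_force_ffls(edges):
    """O(V^3) reference enumeration."""
    has = {(a, b) for a, b in zip(edges["tf"], edges["target"])}
    tf_tf = {(a, b) for a, b, k in zip(edges["tf"], edges["target"], edges["kind"]) if k == "TF-TF"}
    nodes = sorted(set(edges["tf"]) | set(edges["target"]))
    out = set()
    for m in nodes:
        for n in nodes:
            for g in nodes:
                if m != n and g not in (m, n):
                    if (m, n) in tf_tf and (m, g) in has and (n, g) in has:
                        out.add((m, n, g))
    return out


class TestFflEnumeration:
    def test_single_ffl(self):
        edges = _edges_frame([("A", "B")], [("A", "g"), ("B", "g")])
        assert [(t.M, t.N, t.G) for t in rn.enumerate_ffls(edges)] == [("A", "B", "g")]

    def test_mutual_tf_pair_gives_two_ffls(self):
        edges = _edges_frame([("A", "B"), ("B", "A")], [("A", "g"), ("B", "g")])
        got = [(t.M, t.N, t.G) for t in rn.enumerate_ffls(edges)]
        assert got == [("A", "B", "g"), ("B", "A", "g")]

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force_on_random_digraphs(self, seed):
        rng = np.random.default_rng(seed)
        n_tfs, n_genes = 8, 12
        tfs = [f"T{i}" for i in range(n_tfs)]
        genes = [f"g{i}" for i in range(n_genes)]
        tf_tf = {
            (tfs[rng.integers(n_tfs)], tfs[rng.integers(n_tfs)]) for _ in range(12)
        }
        tf_tf = {(a, b) for a, b in tf_tf if a != b}
        tf_gene = {
            (tfs[rng.integers(n_tfs)], genes[rng.integers(n_genes)])
            for _ in range(25)
        }
        edges = _edges_frame(sorted(tf_tf), sorted(tf_gene))
        got = {(t.M, t.N, t.G) for t in rn.enumerate_ffls(edges)}
        assert got == _brute_force_ffls(edges)


class TestSpecificNetwork:
    def test_non_ffl_edge_dropped(self):
        edges = _edges_frame([("A", "B")], [("A", "g"), ("B", "g"), ("A", "h")])
        net = rn.build_specific_network(edges, rn.enumerate_ffls(edges))
        assert set(zip(net.edges["tf"], net.edges["target"])) == {
            ("A", "B"),
            ("A", "g"),
            ("B", "g"),
        }

    def test_pure_ffl_network_unchanged(self):
        edges = _edges_frame([("A", "B")], [("A", "g"), ("B", "g")])
        net = rn.build_specific_network(edges, rn.enumerate_ffls(edges))
        assert len(net.edges) == 3

    def test_planted_ffls_survive_decoys(self, rng):
        tf_tf, tf_gene = [], []
        planted_edges = set()
        for i in range(3):
            m, n_, g = f"M{i}", f"N{i}", f"g{i}"
            tf_tf.append((m, n_))
            tf_gene += [(m, g), (n_, g)]
            planted_edges |= {(m, n_), (m, g), (n_, g)}
        for j in range(10):  # decoy edges never complete a triangle
            tf_gene.append((f"M{j % 3}", f"decoy{j}"))
        edges = _edges_frame(tf_tf, tf_gene)
        net = rn.build_specific_network(edges, rn.enumerate_ffls(edges))
        assert set(zip(net.edges["tf"], net.edges["target"])) == planted_edges

    def test_rerun_reproduces_ffl_set(self, rng):
        tfs = [f"T{i}" for i in range(6)]
        genes = [f"g{i}" for i in range(8)]
        tf_tf = sorted({(tfs[rng.integers(6)], tfs[rng.integers(6)]) for _ in range(8)})
        tf_tf = [(a, b) for a, b in tf_tf if a != b]
        tf_gene = sorted(
            {(tfs[rng.integers(6)], genes[rng.integers(8)]) for _ in range(14)}
        )
        edges = _edges_frame(tf_tf, tf_gene)
        ffls = rn.enumerate_ffls(edges)
        if not ffls:
            pytest.skip("random instance without FFLs")
        net = rn.build_specific_network(edges, ffls)
        assert rn.enumerate_ffls(net.edges) == ffls
        # output edges are a subset of input edges
        inp = set(zip(edges["tf"], edges["target"]))
        assert set(zip(net.edges["tf"], net.edges["target"])) <= inp

    def test_no_ffls_is_an_error(self):
        edges = _edges_frame([("A", "B")], [("A", "g")])
        with pytest.raises(ValidationError, match="similarity cutoff"):
            rn.build_specific_network(edges, [])
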