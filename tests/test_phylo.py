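import math

import numpy as np
import pytest
from skbio import DistanceMatrix
from skbio.tree import TreeNode
from skbio.tree import nj as skbio_nj

from fcptools import phylo
from fcptools.msa import MSA
from fcptools.phylo import (
    assign_lhcf_groups,
    bootstrap_support,
    jukes_cantor,
    neighbor_joining,
    p_distance,
    pdistance_matrix,
)


class TestPDistance:
    def test_identical_rows_zero(self):
        msa = MSA([("a", "MKVL"), ("b", "MKVL")])
        assert p_distance(msa, "a", "b") == 0.0

    def test_one_difference_in_four(self):
        msa = MSA([("a", "AAAA"), ("b", "AAAT")])
        assert p_distance(msa, "a", "b") == 0.25

    def test_pairwise_deletion_over_shared_columns(self):
        msa = MSA([("a", "A-CD"), ("b", "AXCD")])
        assert p_distance(msa, "a", "b") == 0.0

    def test_no_shared_column_errors(self):
        msa = MSA([("a", "AA--"), ("b", "--CC")])
        with pytest.raises(ValueError):
            p_distance(msa, "a", "b")

    def test_matrix_matches_scalar(self, rng):
        rows = []
        for i in range(5):
            row = "".join(
                "-" if rng.random() < 0.1 else "ACDEFGHIKLMNPQRSTVWY"[
                    int(rng.integers(0, 20))
                ]
                for _ in range(60)
            )
            rows.append((f"s{i}", row))
        msa = MSA(rows)
        dm = pdistance_matrix(msa)
        for i in range(5):
            for j in range(i + 1, 5):
                assert dm[f"s{i}", f"s{j}"] == pytest.approx(
                    p_distance(msa, f"s{i}", f"s{j}")
                )


class TestJukesCantor:
    def test_boundaries(self):
        assert jukes_cantor(0.0) == 0.0
        with pytest.raises(ValueError):
            jukes_cantor(0.95)
        with pytest.raises(ValueError):
            jukes_cantor(-0.1)

    def test_half_distance_closed_form(self):
        assert jukes_cantor(0.5) == pytest.approx(
            0.95 * math.log(19.0 / 9.0), abs=1e-12
        )

    def test_matches_high_precision_evaluation(self):
        """Agreement to 1e-12 with an independent arbitrary-precision
        evaluation of -(19/20) ln(1 - 20p/19)."""
        import sympy

        p_sym = sympy.Symbol("p")
        expr = -sympy.Rational(19, 20) * sympy.log(
            1 - sympy.Rational(20, 19) * p_sym
        )
        for p in np.linspace(0.0, 0.94, 48):
            expected = float(expr.subs(p_sym, sympy.Float(p, 50)).evalf(50))
            assert jukes_cantor(float(p)) == pytest.approx(expected, abs=1e-12)

    def test_correction_exceeds_p_and_increases(self):
        grid = np.linspace(0.01, 0.9, 30)
        d = [jukes_cantor(float(p)) for p in grid]
        assert all(di >= pi for di, pi in zip(d, grid))
        assert all(d[i] < d[i + 1] for i in range(len(d) - 1))


def _bipartitions(tree):
    tips = frozenset(t.name for t in tree.tips())
    ref = min(tips)
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = tips - side
        if 1 < len(side) < len(tips) - 1:
            parts.add(side)
    return parts


class TestNeighborJoining:
    def test_additive_four_taxon_recovery(self):
        # distances from the tree ((A:1,B:2):1,(C:3,D:4))
        d = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        tree = neighbor_joining(DistanceMatrix(d, ["A", "B", "C", "D"]))
        assert _bipartitions(tree) == {frozenset({"C", "D"})}
        # additive input is reproduced exactly by path lengths
        rec = tree.tip_tip_distances()
        for i, a in enumerate("ABCD"):
            for b in "ABCD"[i + 1 :]:
                assert rec[a, b] == pytest.approx(d["ABCD".index(a),
                                                    "ABCD".index(b)])

    def test_three_taxa_closed_form(self):
        d = np.array([[0, 2, 4], [2, 0, 5], [4, 5, 0]], float)
        tree = neighbor_joining(DistanceMatrix(d, ["A", "B", "C"]))
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["A"] == pytest.approx((2 + 4 - 5) / 2)
        assert lengths["B"] == pytest.approx((2 + 5 - 4) / 2)
        assert lengths["C"] == pytest.approx((4 + 5 - 2) / 2)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(np.zeros((2, 2)), ["A", "B"]))

    def test_equal_distances_tie_break_deterministic(self):
        d = np.ones((4, 4)) - np.eye(4)
        ids = ["A", "B", "C", "D"]
        t1 = str(neighbor_joining(DistanceMatrix(d, ids)))
        t2 = str(neighbor_joining(DistanceMatrix(d, ids)))
        assert t1 == t2

    def test_agrees_with_independent_nj_on_additive_matrix(self):
        """Cross-check against scikit-bio's neighbor joining."""
        rng = np.random.default_rng(5)
        for _ in range(10):
            n = int(rng.integers(5, 8))
            ids = [f"t{i}" for i in range(n)]
            # random additive matrix from a random tree
            nodes = [TreeNode(name=i, length=float(rng.uniform(0.1, 1.0)))
                     for i in ids]
            while len(nodes) > 1:
                i, j = sorted(rng.choice(len(nodes), 2, replace=False))
                parent = TreeNode(children=[nodes[i], nodes[j]],
                                  length=float(rng.uniform(0.1, 1.0)))
                nodes = [nodes[k] for k in range(len(nodes))
                         if k not in (i, j)] + [parent]
            gen = nodes[0]
            dm_t = gen.tip_tip_distances()
            dm = DistanceMatrix(dm_t.data, list(dm_t.ids))
            ours = neighbor_joining(dm)
            theirs = skbio_nj(dm)
            assert _bipartitions(ours) == _bipartitions(theirs)


def _mutate(seq, positions, rng):
    chars = list(seq)
    for p in positions:
        chars[p] = "ACDEFGHIKLMNPQRSTVWY"[int(rng.integers(0, 20))]
    return "".join(chars)


class TestBootstrap:
    def _signal_msa(self):
        rng = np.random.default_rng(11)
        base = "".join(
            "ACDEFGHIKLMNPQRSTVWY"[int(rng.integers(0, 20))] for _ in range(80)
        )
        twin = _mutate(base, range(0, 10), rng)
        far1 = _mutate(base, range(20, 45), rng)
        far2 = _mutate(far1, range(0, 8), rng)
        far3 = _mutate(far1, range(60, 72), rng)
        return MSA([("s1", twin), ("s2", twin), ("o1", far1),
                    ("o2", far2), ("o3", far3)])

    def test_identical_sisters_get_full_support(self):
        tree = bootstrap_support(self._signal_msa(), n_reps=30, seed=3)
        for node in tree.non_tips(include_self=False):
            names = {t.name for t in node.tips()}
            if names == {"s1", "s2"} or names == {"o1", "o2", "o3"}:
                assert node.support == 100.0

    def test_supports_within_range_and_reproducible(self):
        msa = self._signal_msa()
        t1 = bootstrap_support(msa, n_reps=20, seed=9)
        t2 = bootstrap_support(msa, n_reps=20, seed=9)
        s1 = sorted(
            n.support for n in t1.non_tips(include_self=False)
            if hasattr(n, "support")
        )
        s2 = sorted(
            n.support for n in t2.non_tips(include_self=False)
            if hasattr(n, "support")
        )
        assert s1 == s2
        assert all(0 <= s <= 100 for s in s1)

    def test_degenerate_inputs_rejected(self):
        flat = MSA([(f"s{i}", "MKVLMKVL") for i in range(5)])
        with pytest.raises(ValueError, match="signal"):
            bootstrap_support(flat, n_reps=5, seed=0)
        small = MSA([("a", "MKVL"), ("b", "MKVA"), ("c", "MKLL")])
        with pytest.raises(ValueError):
            bootstrap_support(small, n_reps=5, seed=0)


def _supported_tree(newick, supports):
    import io

    tree = TreeNode.read(io.StringIO(newick))
    k = 0
    for node in tree.non_tips(include_self=False):
        node.support = supports[k]
        k += 1
    return tree


class TestLhcfGroups:
    def test_pure_clades_labelled_b_c_d(self):
        tree = _supported_tree(
            "((h1,h2,h3),(d1,d2,d3),(w1,w2,w3));", [90, 85, 80]
        )
        cls = {f"h{i}": "haptophyte" for i in range(1, 4)}
        cls |= {f"d{i}": "diatom" for i in range(1, 4)}
        cls |= {f"w{i}": "seaweed" for i in range(1, 4)}
        labels = assign_lhcf_groups(tree, cls)
        assert all(labels[f"h{i}"] == "B" for i in range(1, 4))
        assert all(labels[f"d{i}"] == "C" for i in range(1, 4))
        assert all(labels[f"w{i}"] == "D" for i in range(1, 4))

    def test_haptophyte_majority_with_diatom_is_group_a(self):
        leaves = [f"h{i}" for i in range(1, 8)] + ["d1", "d2"]
        tree = _supported_tree(
            "((h1,h2,h3,h4,h5,h6,h7,d1,d2),(w1,w2,w3));", [95, 90]
        )
        cls = {leaf: "haptophyte" for leaf in leaves[:7]}
        cls |= {"d1": "diatom", "d2": "diatom"}
        cls |= {f"w{i}": "seaweed" for i in range(1, 4)}
        labels = assign_lhcf_groups(tree, cls)
        assert all(labels[leaf] == "A" for leaf in leaves)
        assert labels["w1"] == "D"

    def test_low_support_clade_left_unassigned(self):
        tree = _supported_tree("((h1,h2,h3),(d1,d2,d3));", [30, 95])
        cls = {f"h{i}": "haptophyte" for i in range(1, 4)}
        cls |= {f"d{i}": "diatom" for i in range(1, 4)}
        labels = assign_lhcf_groups(tree, cls, min_support=50)
        assert all(labels[f"h{i}"] == "unassigned" for i in range(1, 4))
        assert all(labels[f"d{i}"] == "C" for i in range(1, 4))

    def test_unclassified_leaf_errors(self):
        tree = _supported_tree("((h1,h2,h3),(d1,d2,d3));", [90, 90])
        with pytest.raises(ValueError, match="d3"):
            assign_lhcf_groups(
                tree,
                {"h1": "haptophyte", "h2": "haptophyte", "h3": "haptophyte",
                 "d1": "diatom", "d2": "diatom"},
            )


def test_newick_round_trip(tmp_path):
    d = np.array([[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
                 float)
    tree = neighbor_joining(DistanceMatrix(d, ["A", "B", "C", "D"]))
    path = tmp_path / "t.nwk"
    phylo.write_newick(tree, path, supports=False)
    back = phylo.read_newick(path)
    assert _bipartitions(back) == _bipartitions(tree)
    assert {t.name for t in back.tips()} == {"A", "B", "C", "D"}
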