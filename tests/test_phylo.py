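"""Tree parsing, covariance construction and branching-time extraction."""

import io
import subprocess

import numpy as np
import pytest

import richrates as rr
from richrates.phylo import (
    BranchingTimes,
    TreeError,
    TreeParseError,
    UltrametricityError,
)

from oracles import vcv_path_intersection

NEXUS_WRAPPER = """#NEXUS
[ comment to be ignored ]
BEGIN TAXA; DIMENSIONS NTAX=3; TAXLABELS A B C; END;
BEGIN TREES;
    TRANSLATE 1 A, 2 B, 3 C;
    TREE one = ((1:1,2:1):1,3:2);
END;
"""


class TestParsing:
    def test_minimal_two_tip_tree(self):
        t = rr.read_tree("(A:1,B:1);")
        assert t.n_tips == 2
        assert sorted(t.tip_labels) == ["A", "B"]
        assert np.allclose(t.tip_depths(), 1.0)
        assert t.is_ultrametric()

    def test_three_tip_structure(self, three_tip_tree):
        t = three_tip_tree
        assert t.n_tips == 3
        assert t.depth == pytest.approx(2.0)
        internal = [d for d, lab in zip(t.node_depths(), t.labels) if lab is None]
        assert sorted(internal) == pytest.approx([0.0, 1.0])

    def test_nexus_translate_matches_newick(self, three_tip_tree):
        t = rr.read_tree(io.StringIO(NEXUS_WRAPPER), format="nexus")
        assert sorted(t.tip_labels) == sorted(three_tip_tree.tip_labels)
        ref = three_tip_tree.vcv().reorder(t.tip_labels)
        assert np.allclose(t.vcv().matrix, ref.matrix)

    def test_multiple_trees_listed_and_selectable(self):
        src = "(A:1,B:1);\n((A:1,B:1):1,C:2);\n"
        trees = rr.read_trees(src)
        assert [t.n_tips for t in trees] == [2, 3]
        assert rr.read_tree(src, index=1).n_tips == 3

    def test_malformed_source_raises_parse_error(self):
        with pytest.raises(TreeParseError):
            rr.read_tree("((A:1,B:1):1,C:2")

    def test_duplicate_tip_labels_rejected(self):
        with pytest.raises(TreeError, match="duplicate"):
            rr.read_tree("(A:1,A:1);")

    def test_polytomy_accepted(self):
        t = rr.read_tree("(A:2,B:2,C:2);")
        assert t.n_tips == 3

    def test_newick_round_trip(self, three_tip_tree):
        again = rr.read_tree(three_tip_tree.write_newick())
        assert np.allclose(
            again.vcv().reorder(three_tip_tree.tip_labels).matrix,
            three_tip_tree.vcv().matrix,
        )

    def test_drop_tips(self, backbone_tree):
        pruned = backbone_tree.drop_tips(["Aneides"])
        assert pruned.n_tips == 14
        assert "Aneides" not in pruned.tip_labels
        assert pruned.depth == pytest.approx(61.0)
        with pytest.raises(KeyError):
            backbone_tree.drop_tips(["NotACladeName"])


class TestVCV:
    def test_star_tree_is_scaled_identity(self, star4_tree):
        C = star4_tree.vcv()
        assert np.allclose(C.matrix, 2.0 * np.eye(4))

    def test_three_tip_hand_derived(self, three_tip_tree):
        C = three_tip_tree.vcv().reorder(["A", "B", "C"])
        assert np.allclose(C.matrix, [[2, 1, 0], [1, 2, 0], [0, 0, 2]])

    @pytest.mark.parametrize("seed,n_tips", [(1, 5), (2, 6), (3, 7), (4, 8)])
    def test_matches_path_intersection_oracle(self, seed, n_tips):
        tree = rr.simulate_yule(n_tips, 1.0, seed)
        assert np.allclose(tree.vcv().matrix, vcv_path_intersection(tree), atol=1e-12)

    def test_invariants_on_random_tree(self):
        tree = rr.simulate_yule(12, 0.7, 99)
        C = tree.vcv()
        m = C.matrix
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), tree.tip_depths())
        mins = np.minimum.outer(np.diag(m), np.diag(m))
        assert np.all(m <= mins + 1e-12)
        assert np.linalg.eigvalsh(m).min() > -1e-9

    def test_matches_ape_vcv(self, three_tip_tree):
        out = subprocess.run(
            ["Rscript", "-e",
             'library(ape); tr <- read.tree(text="((A:1,B:1):1,C:2);");'
             'v <- vcv(tr); cat(v[c("A","B","C"), c("A","B","C")])'],
            capture_output=True, text=True, check=True,
        )
        ape = np.array([float(v) for v in out.stdout.split()]).reshape(3, 3, order="F")
        ours = three_tip_tree.vcv().reorder(["A", "B", "C"]).matrix
        assert np.allclose(ours, ape, atol=1e-8)


class TestLambdaTransform:
    def test_identity_at_one(self, three_tip_tree):
        C = three_tip_tree.vcv()
        assert np.allclose(C.lambda_transform(1.0).matrix, C.matrix)

    def test_star_collapse_at_zero(self, three_tip_tree):
        C = three_tip_tree.vcv()
        assert np.allclose(C.lambda_transform(0.0).matrix, np.diag(np.diag(C.matrix)))

    def test_half_on_two_by_two(self):
        C = rr.PhyloCovariance(np.array([[2.0, 1.0], [1.0, 2.0]]), ("A", "B"))
        assert np.allclose(C.lambda_transform(0.5).matrix, [[2, 0.5], [0.5, 2]])

    @pytest.mark.parametrize("lam", [-0.1, 1.5])
    def test_out_of_bounds_rejected(self, three_tip_tree, lam):
        with pytest.raises(ValueError):
            three_tip_tree.vcv().lambda_transform(lam)

    def test_entrywise_linear_in_lambda(self, backbone_tree):
        C = backbone_tree.vcv()
        a, b = C.lambda_transform(0.3).matrix, C.lambda_transform(0.6).matrix
        off = ~np.eye(C.n, dtype=bool)
        assert np.allclose(b[off], 2.0 * a[off])


class TestBranchingTimes:
    def test_three_tip_depths_and_intervals(self, three_tip_tree):
        bt = three_tip_tree.branching_times()
        assert np.allclose(bt.depths, [2.0, 1.0])
        assert np.allclose(bt.intervals, [1.0, 1.0])  # g_2, g_3
        assert bt.intervals.sum() == pytest.approx(bt.root_age)

    def test_balanced_four_tip(self):
        t = rr.read_tree("((A:1,B:1):2,(C:1,D:1):2);")
        bt = t.branching_times()
        assert np.allclose(bt.depths, [3.0, 1.0, 1.0])

    def test_two_tip_tree_valid_but_insufficient_for_gamma(self):
        bt = rr.read_tree("(A:1.5,B:1.5);").branching_times()
        assert np.allclose(bt.depths, [1.5])
        with pytest.raises(ValueError, match=">= 3"):
            rr.gamma_stat(bt)

    def test_non_ultrametric_names_offending_tip(self):
        t = rr.read_tree("((A:1,B:1):1,C:5);")
        with pytest.raises(UltrametricityError, match="'C'"):
            t.branching_times()

    def test_polytomy_contributes_coincident_depths(self):
        bt = rr.read_tree("(A:2,B:2,C:2);").branching_times()
        assert np.allclose(bt.depths, [2.0, 2.0])
        assert np.allclose(bt.intervals, [0.0, 2.0])

    def test_invariant_to_rotation_and_relabelling(self):
        a = rr.read_tree("((A:1,B:1):1,C:2);").branching_times()
        b = rr.read_tree("(Z:2,(Y:1,X:1):1);").branching_times()
        assert np.allclose(a.intervals, b.intervals)

    def test_from_intervals_round_trip(self):
        bt = BranchingTimes.from_intervals([0.5, 0.25, 0.25])
        assert np.allclose(bt.depths, [1.0, 0.5, 0.25])
        assert bt.n_tips == 4
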