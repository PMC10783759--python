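import itertools

import numpy as np
import pytest

from autophy.tree import (
    PatristicDistanceMatrix,
    TreeValidationError,
    patristic_matrix,
    read_tree,
    tree_from_string,
    write_clustered_tree,
)

from conftest import TOY4, random_binary_tree
from _oracles import patristic_oracle


class TestReadAndValidate:
    def test_parses_four_leaf_tree(self, toy4):
        assert set(toy4.leaf_labels) == {"A", "B", "C", "D"}
        assert len(toy4.dendropy_tree.seed_node.child_nodes()) == 2

    def test_two_leaf_tree_accepted_for_distances(self):
        t = tree_from_string("(A:1,B:2);")
        assert t.n_leaves == 2
        assert patristic_matrix(t).distance("A", "B") == pytest.approx(3.0)

    def test_duplicate_leaf_labels_named_in_error(self):
        with pytest.raises(TreeValidationError, match="(?i)duplicate.*A"):
            tree_from_string("(A:1,A:2);")

    def test_missing_branch_length_is_hard_error(self):
        with pytest.raises(TreeValidationError, match="branch length"):
            tree_from_string("((A:1,B):3,(C:4,D:5):6);")

    def test_negative_branch_length_rejected(self):
        with pytest.raises(TreeValidationError, match="negative"):
            tree_from_string("((A:1,B:-2):3,(C:4,D:5):6);")

    def test_zero_branch_length_allowed(self):
        t = tree_from_string("((A:0,B:2):3,(C:4,D:5):0);")
        assert t.n_leaves == 4

    def test_unrooted_trifurcation_rejected_without_midpoint_flag(self):
        with pytest.raises(TreeValidationError, match="unrooted"):
            tree_from_string("(A:1,B:2,C:3);")

    def test_midpoint_rooting_flag_accepts_unrooted(self):
        t = tree_from_string("(A:1,B:2,C:6);", midpoint_root=True)
        assert set(t.leaf_labels) == {"A", "B", "C"}
        assert len(t.dendropy_tree.seed_node.child_nodes()) == 2

    def test_quoted_labels_unquoted_and_comments_stripped(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("(('sp one':1,B:2)[a comment]:3,(C:4,D:5):6);\n")
        t = read_tree(p)
        assert "sp one" in t.leaf_labels

    def test_nexus_translate_table_resolved(self, tmp_path):
        p = tmp_path / "t.nex"
        p.write_text(
            "#NEXUS\nBEGIN TAXA;\nDIMENSIONS NTAX=4;\n"
            "TAXLABELS alpha beta gamma delta;\nEND;\n"
            "BEGIN TREES;\nTRANSLATE 1 alpha, 2 beta, 3 gamma, 4 delta;\n"
            "TREE t = ((1:1,2:2):3,(3:4,4:5):6);\nEND;\n"
        )
        t = read_tree(p, format="auto")
        assert set(t.leaf_labels) == {"alpha", "beta", "gamma", "delta"}


class TestPatristicMatrix:
    def test_toy_tree_distances(self, toy4):
        pdm = patristic_matrix(toy4)
        assert pdm.distance("A", "C") == pytest.approx(14.0)
        assert pdm.distance("B", "D") == pytest.approx(16.0)
        assert pdm.distance("C", "D") == pytest.approx(9.0)

    def test_symmetric_zero_diagonal(self, toy4):
        v = patristic_matrix(toy4).values
        assert np.allclose(v, v.T)
        assert np.all(np.diag(v) == 0)

    def test_row_order_is_stable_leaf_postorder(self, toy4):
        pdm = patristic_matrix(toy4)
        assert pdm.labels == toy4.leaf_labels

    def test_matches_path_enumeration_oracle_on_random_trees(self):
        rng = np.random.default_rng(7)
        worst = 0.0
        for _ in range(100):
            t = random_binary_tree(int(rng.integers(4, 21)), rng)
            pdm = patristic_matrix(t)
            oracle = patristic_oracle(t.dendropy_tree)
            for (a, b), d in oracle.items():
                worst = max(worst, abs(pdm.distance(a, b) - d))
        assert worst < 1e-9

    def test_four_point_condition_on_random_trees(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            t = random_binary_tree(int(rng.integers(5, 13)), rng)
            pdm = patristic_matrix(t)
            v, lab = pdm.values, pdm.labels
            scale = v.max()
            for i, j, k, l in itertools.combinations(range(len(lab)), 4):
                sums = sorted(
                    [v[i, j] + v[k, l], v[i, k] + v[j, l], v[i, l] + v[j, k]]
                )
                assert sums[2] - sums[1] <= 1e-6 * scale

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ValueError):
            PatristicDistanceMatrix(("A", "B"), np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError):
            PatristicDistanceMatrix(("A", "B"), np.array([[0.0, np.nan], [np.nan, 0.0]]))


class TestWriteClusteredTree:
    def test_newick_appends_cluster_labels(self, toy4, tmp_path):
        out = tmp_path / "o.nwk"
        write_clustered_tree(toy4, {"A": 0, "B": 0, "C": 1, "D": 1}, out)
        text = out.read_text()
        assert "A|0" in text and "C|1" in text

    def test_partition_mismatch_reports_symmetric_difference(self, toy4, tmp_path):
        with pytest.raises(ValueError, match="missing.*'D'"):
            write_clustered_tree(
                toy4, {"A": 0, "B": 0, "C": 1, "X": 1}, tmp_path / "o.nwk"
            )
        with pytest.raises(ValueError, match="partition"):
            write_clustered_tree(toy4, {}, tmp_path / "o.nwk")

    def test_round_trip_preserves_topology_and_lengths(self, tmp_path):
        rng = np.random.default_rng(3)
        t = random_binary_tree(9, rng)
        out = tmp_path / "o.nwk"
        part = {lf: 0 for lf in t.leaf_labels}
        write_clustered_tree(t, part, out)
        back = read_tree(out)
        assert back.n_leaves == t.n_leaves
        # same clades (after stripping the |label suffix), same path metric
        stripped = {
            frozenset(x.rsplit("|", 1)[0] for x in clade)
            for clade in back.clade_leafsets()
        }
        assert stripped == set(t.clade_leafsets())
        pdm_a = patristic_matrix(t)
        pdm_b = patristic_matrix(back)
        for a, b in itertools.combinations(t.leaf_labels, 2):
            assert pdm_b.distance(f"{a}|0", f"{b}|0") == pytest.approx(
                pdm_a.distance(a, b), abs=1e-9
            )

    def test_nexus_output_carries_figtree_colors(self, toy4, tmp_path):
        out = tmp_path / "o.nex"
        write_clustered_tree(
            toy4, {"A": 0, "B": 0, "C": 1, "D": 1}, out, format="nexus"
        )
        text = out.read_text()
        assert text.startswith("#NEXUS")
        assert "[&!color=#" in text
        # one distinct color per cluster
        colors = {
            line.split("[&!color=")[1].rstrip("]\n")
            for line in text.splitlines()
            if "[&!color=" in line
        }
        assert len(colors) == 2
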