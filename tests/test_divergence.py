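import itertools
import math

import numpy as np
import pytest

from autophy.divergence import (
    divergence_report,
    log_ratio,
    mean_pairwise_distance,
    subtending_branch_length,
)
from autophy.mcim import maximize_monophyly
from autophy.tree import patristic_matrix, tree_from_string

from conftest import TOY4, random_binary_tree
from _oracles import patristic_oracle


class TestMeanPairwiseDistance:
    def test_cherry_is_its_single_pair_distance(self, toy4):
        pdm = patristic_matrix(toy4)
        assert mean_pairwise_distance(pdm, {"A", "B"}) == pytest.approx(3.0)

    def test_three_tip_average(self, toy4):
        pdm = patristic_matrix(toy4)
        # d(A,B)=3, d(A,C)=14, d(B,C)=15 -> 32/3
        assert mean_pairwise_distance(pdm, {"A", "B", "C"}) == pytest.approx(32 / 3)

    def test_singleton_is_zero_by_convention(self, toy4):
        pdm = patristic_matrix(toy4)
        assert mean_pairwise_distance(pdm, {"A"}) == 0.0

    def test_unknown_label_is_hard_error(self, toy4):
        with pytest.raises(KeyError):
            mean_pairwise_distance(patristic_matrix(toy4), {"A", "Z"})

    def test_matches_double_loop_oracle_on_random_subsets(self):
        rng = np.random.default_rng(17)
        for _ in range(40):
            t = random_binary_tree(int(rng.integers(4, 15)), rng)
            pdm = patristic_matrix(t)
            oracle = patristic_oracle(t.dendropy_tree)
            leaves = list(t.leaf_labels)
            size = int(rng.integers(2, len(leaves) + 1))
            sub = rng.choice(leaves, size=size, replace=False).tolist()
            pairs = list(itertools.combinations(sorted(sub), 2))
            expected = sum(oracle[p] for p in pairs) / len(pairs)
            assert mean_pairwise_distance(pdm, sub) == pytest.approx(
                expected, abs=1e-9
            )


class TestSubtendingBranch:
    def test_cherry_parent_edge(self, toy4):
        assert subtending_branch_length(toy4, {"A", "B"}) == pytest.approx(3.0)

    def test_full_leaf_set_has_no_subtending_branch(self, toy4):
        assert subtending_branch_length(toy4, set(toy4.leaf_labels)) is None

    def test_singleton_uses_its_own_terminal_branch(self, toy4):
        assert subtending_branch_length(toy4, {"C"}) == pytest.approx(4.0)

    def test_non_monophyletic_set_rejected(self, toy4):
        with pytest.raises(ValueError, match="monophyletic"):
            subtending_branch_length(toy4, {"A", "C"})


class TestLogRatio:
    def test_equal_terms_give_zero(self):
        assert log_ratio(3.0, 3.0) == (0.0, None)

    def test_natural_log_identity(self):
        v, reason = log_ratio(math.e * 0.7, 0.7)
        assert v == pytest.approx(1.0)
        assert reason is None

    def test_base_ten_option(self):
        v, _ = log_ratio(10.0, 1.0, base=10)
        assert v == pytest.approx(1.0)

    def test_undefined_reasons(self):
        assert log_ratio(0.0, 1.0) == (None, "zero-mpd")
        assert log_ratio(1.0, None) == (None, "root-cluster")
        assert log_ratio(1.0, 0.0) == (None, "zero-subtending")

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            log_ratio(-1.0, 1.0)

    def test_strictly_decreasing_in_subtending_branch(self):
        values = [log_ratio(2.0, b)[0] for b in (0.5, 1.0, 2.0, 8.0)]
        assert all(x > y for x, y in zip(values, values[1:]))


class TestDivergenceReport:
    def test_two_cherry_partition_fully_defined(self, toy4):
        pdm = patristic_matrix(toy4)
        part = maximize_monophyly(toy4, {"A": 0, "B": 0, "C": 1, "D": 1})
        recs = divergence_report(toy4, pdm, part)
        assert [r.cluster_label for r in recs] == ["0", "1"]
        assert all(r.defined for r in recs)
        assert recs[0].log_ratio == pytest.approx(math.log(3.0 / 3.0))
        assert recs[1].log_ratio == pytest.approx(math.log(9.0 / 6.0))

    def test_root_cluster_flagged_not_dropped(self, toy4):
        pdm = patristic_matrix(toy4)
        part = maximize_monophyly(toy4, {lf: 0 for lf in toy4.leaf_labels})
        recs = divergence_report(toy4, pdm, part)
        assert len(recs) == 1
        assert not recs[0].defined and recs[0].reason == "root-cluster"

    def test_singleton_cluster_flagged(self, toy4):
        pdm = patristic_matrix(toy4)
        part = maximize_monophyly(toy4, {"A": 0, "B": 0, "C": 1, "D": 2})
        recs = {r.cluster_label: r for r in divergence_report(toy4, pdm, part)}
        assert recs["1"].reason == "singleton"
        assert recs["1"].n_tips == 1

    @pytest.mark.parametrize("scale", [0.01, 3.0, 1e4])
    def test_scale_equivariance_leaves_log_ratio_unchanged(self, scale):
        base = tree_from_string(TOY4)
        scaled_newick = "((A:{},B:{}):{},(C:{},D:{}):{});".format(
            *(x * scale for x in (1, 2, 3, 4, 5, 6))
        )
        scaled = tree_from_string(scaled_newick)
        labels = {"A": 0, "B": 0, "C": 1, "D": 1}
        r0 = divergence_report(
            base, patristic_matrix(base), maximize_monophyly(base, labels)
        )
        r1 = divergence_report(
            scaled, patristic_matrix(scaled), maximize_monophyly(scaled, labels)
        )
        for a, b in zip(r0, r1):
            assert b.mpd == pytest.approx(a.mpd * scale, rel=1e-12)
            assert b.subtending_length == pytest.approx(
                a.subtending_length * scale, rel=1e-12
            )
            assert b.log_ratio == pytest.approx(a.log_ratio, abs=1e-9)
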