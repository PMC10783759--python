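"""Annotation concordance via parsimony with a randomization null.

If the clustering recovers real subfamilies, external annotations should
be phylogenetically conserved: mapping a short annotation key (by default
the first three characters of each leaf's annotation string) onto the
tree should need far fewer state changes than chance.  The observed Fitch
parsimony score is compared with the scores of uniformly permuted
leaf→key assignments; the add-one permutation p-value quantifies how
often chance does at least as well.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tree import RootedTree

__all__ = [
    "AnnotationTable",
    "read_annotations",
    "fitch_parsimony",
    "parsimony_randomization",
    "PermutationTestResult",
]


@dataclass(frozen=True)
class AnnotationTable:
    """Leaf label → annotation string, with a derived categorical key per
    leaf (annotation prefix of length ``key_length``)."""

    annotations: dict[str, str]
    key_length: int = 3

    def __post_init__(self):
        if self.key_length < 1:
            raise ValueError("key length must be >= 1")
        for leaf, ann in self.annotations.items():
            if not ann:
                raise ValueError(f"empty annotation for leaf {leaf!r}")

    def keys_for(
        self, tree: RootedTree, *, drop_unannotated: bool = False
    ) -> dict[str, str]:
        """Per-leaf categorical states for the given tree.

        Leaves without an annotation are a hard error unless
        ``drop_unannotated`` is set, in which case they are omitted (the
        scoring functions then prune the tree to the covered leaves).
        """
        missing = [lf for lf in tree.leaf_labels if lf not in self.annotations]
        if missing and not drop_unannotated:
            raise ValueError(
                f"{len(missing)} leaves lack annotations "
                f"(first few: {missing[:5]}); pass drop_unannotated=True "
                "to restrict scoring to annotated leaves"
            )
        return {
            lf: self.annotations[lf][: self.key_length]
            for lf in tree.leaf_labels
            if lf in self.annotations
        }


def read_annotations(path: str | os.PathLike, key_length: int = 3) -> AnnotationTable:
    """Read a two-column TSV (leaf_label, annotation); header optional."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError("annotation table needs two tab-separated columns")
    if str(df.iloc[0, 0]).lower() in ("leaf", "leaf_label", "label", "tip"):
        df = df.iloc[1:]
    mapping = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
    return AnnotationTable(annotations=mapping, key_length=key_length)


def _restrict(tree: RootedTree, states: dict[str, str]) -> RootedTree:
    keep = set(states)
    if keep == set(tree.leaf_labels):
        return tree
    pruned = tree.dendropy_tree.extract_tree_with_taxa_labels(labels=keep)
    return RootedTree(pruned)


def fitch_parsimony(tree: RootedTree, states: dict[str, str]) -> int:
    """Minimum number of state changes explaining the leaf states.

    Computed by a unit-cost dynamic program over observed states (the
    small-parsimony recurrence), which reduces to Fitch's
    intersection/union rule on bifurcating trees and stays exactly minimal
    at polytomies.
    """
    missing = set(tree.leaf_labels) - set(states)
    if missing:
        raise ValueError(
            f"missing state for leaves: {sorted(missing)[:5]}"
        )
    alphabet = sorted(set(states[lf] for lf in tree.leaf_labels))
    sidx = {s: i for i, s in enumerate(alphabet)}
    m = len(alphabet)
    big = np.iinfo(np.int64).max // 4
    cost: dict[int, np.ndarray] = {}
    for nd in tree.dendropy_tree.postorder_node_iter():
        if nd.is_leaf():
            c = np.full(m, big, dtype=np.int64)
            c[sidx[states[nd.taxon.label]]] = 0
        else:
            c = np.zeros(m, dtype=np.int64)
            for ch in nd.child_nodes():
                child = cost.pop(id(ch))
                # staying in state i is free; switching costs 1
                c += np.minimum(child, child.min() + 1)
        cost[id(nd)] = c
    root = tree.dendropy_tree.seed_node
    return int(cost[id(root)].min())


@dataclass(frozen=True)
class PermutationTestResult:
    observed: int
    null_scores: np.ndarray = field(repr=False)
    p_value: float
    n_perm: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"null_score": self.null_scores})


def parsimony_randomization(
    tree: RootedTree,
    states: dict[str, str],
    n_perm: int = 999,
    seed: int = 42,
    *,
    drop_unannotated: bool = False,
) -> PermutationTestResult:
    """Permutation test of tree–annotation concordance.

    The null distribution is the Fitch score under ``n_perm`` uniform
    random permutations of the leaf→state assignment over all leaves;
    p = (1 + #{null ≤ observed}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if drop_unannotated:
        states = {lf: st for lf, st in states.items() if lf in set(tree.leaf_labels)}
        tree = _restrict(tree, states)
    observed = fitch_parsimony(tree, states)
    leaves = list(tree.leaf_labels)
    values = np.array([states[lf] for lf in leaves], dtype=object)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm, dtype=np.int64)
    for i in range(n_perm):
        perm = rng.permutation(len(leaves))
        null[i] = fitch_parsimony(
            tree, dict(zip(leaves, values[perm]))
        )
    p = (1 + int(np.sum(null <= observed))) / (n_perm + 1)
    return PermutationTestResult(
        observed=observed, null_scores=null, p_value=p, n_perm=n_perm, seed=seed
    )
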