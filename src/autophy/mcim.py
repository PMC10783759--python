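"""Monophyletic cluster maximization (MCIM).

Mixture clusters live in embedding space and need not correspond to clades
of the tree.  This module maps each mixture cluster back onto the tree,
keeps it as-is when it is monophyletic, and otherwise decomposes it into
the maximal clades it contains.  Because the clades of a rooted tree form
a laminar family, that decomposition is unique: the maximal contained
clades are pairwise disjoint and cover the cluster.  Split parts inherit
the parent cluster's integer label with a decimal suffix ("3" → "3.0",
"3.1", …) in extraction order (largest first; equal sizes broken toward
the lexicographically smallest member label).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .tree import RootedTree

__all__ = [
    "ClusterLabel",
    "ClusterPartition",
    "is_monophyletic",
    "decompose_cluster",
    "maximize_monophyly",
]

_LABEL_RE = re.compile(r"^[0-9]+(\.[0-9]+)?$")


@dataclass(frozen=True, order=True)
class ClusterLabel:
    """A cluster label: bare integer for direct mixture clusters, or
    integer.decimal for parts produced by splitting ("3", "3.0", "3.1")."""

    base: int
    suffix: int | None = None

    def __post_init__(self):
        if self.base < 0 or (self.suffix is not None and self.suffix < 0):
            raise ValueError("cluster label components must be non-negative")

    def __str__(self) -> str:
        s = str(self.base) if self.suffix is None else f"{self.base}.{self.suffix}"
        assert _LABEL_RE.match(s)
        return s

    @classmethod
    def parse(cls, text: str) -> "ClusterLabel":
        if not _LABEL_RE.match(text):
            raise ValueError(f"not a cluster label: {text!r}")
        if "." in text:
            b, s = text.split(".")
            return cls(int(b), int(s))
        return cls(int(text))


@dataclass(frozen=True)
class ClusterPartition:
    """Total mapping leaf label → cluster label, with per-cluster
    provenance ("direct" from the mixture, or "split" from MCIM)."""

    assignments: Mapping[str, ClusterLabel]
    provenance: Mapping[ClusterLabel, str]

    def __post_init__(self):
        if not self.assignments:
            raise ValueError("empty partition")
        for lb in set(self.assignments.values()):
            if self.provenance.get(lb) not in ("direct", "split"):
                raise ValueError(f"missing provenance for cluster {lb}")

    def clusters(self) -> dict[ClusterLabel, frozenset[str]]:
        out: dict[ClusterLabel, set[str]] = {}
        for leaf, lb in self.assignments.items():
            out.setdefault(lb, set()).add(leaf)
        return {lb: frozenset(s) for lb, s in sorted(out.items())}

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignments.values()))

    def to_frame(self, leaf_order: Iterable[str] | None = None) -> pd.DataFrame:
        leaves = list(leaf_order) if leaf_order is not None else sorted(self.assignments)
        return pd.DataFrame(
            {
                "leaf_label": leaves,
                "cluster_label": [str(self.assignments[lf]) for lf in leaves],
                "provenance": [
                    self.provenance[self.assignments[lf]] for lf in leaves
                ],
            }
        )


def is_monophyletic(tree: RootedTree, leafset: Iterable[str]) -> bool:
    """True iff the MRCA of ``leafset`` has exactly ``leafset`` below it —
    equivalently, iff the set is one of the tree's clades."""
    ls = tree.check_leaves(leafset)
    return ls in tree.clade_leafsets()


def decompose_cluster(
    tree: RootedTree, leafset: Iterable[str]
) -> list[frozenset[str]]:
    """Maximal clades of the tree contained in ``leafset``.

    Recursive largest-clade extraction and the laminar structure of tree
    clades give the same unique answer: the parts are pairwise disjoint,
    union to ``leafset``, and are returned size-descending (ties toward
    the part holding the lexicographically smallest label).  A monophyletic
    input comes back as a single part.
    """
    ls = tree.check_leaves(leafset)
    parts: list[frozenset[str]] = []
    covered: set[str] = set()
    # postorder: children before parents, so test maximality via the parent
    nodes = {id(nd): below for nd, below in tree._clades}
    for nd, below in tree._clades:
        if not below <= ls:
            continue
        parent = nd.parent_node
        if parent is not None and nodes[id(parent)] <= ls:
            continue  # a larger contained clade exists above
        if below & covered:
            continue  # same leafset reachable through a unifurcation
        parts.append(below)
        covered |= below
    assert covered == ls
    parts.sort(key=lambda p: (-len(p), min(p)))
    return parts


def maximize_monophyly(
    tree: RootedTree, mixture_labels: Mapping[str, int]
) -> ClusterPartition:
    """Resolve mixture clusters into monophyletic final clusters.

    Monophyletic mixture clusters keep their bare integer label; every
    non-monophyletic cluster with base label B is decomposed and its parts
    labeled B.0, B.1, … in extraction order.
    """
    leafset = set(tree.leaf_labels)
    if set(mixture_labels) != leafset:
        raise ValueError("mixture labels must cover exactly the tree's leaves")
    by_cluster: dict[int, set[str]] = {}
    for leaf, lb in mixture_labels.items():
        by_cluster.setdefault(int(lb), set()).add(leaf)
    assignments: dict[str, ClusterLabel] = {}
    provenance: dict[ClusterLabel, str] = {}
    for base in sorted(by_cluster):
        members = by_cluster[base]
        if is_monophyletic(tree, members):
            lb = ClusterLabel(base)
            provenance[lb] = "direct"
            for leaf in members:
                assignments[leaf] = lb
        else:
            for suffix, part in enumerate(decompose_cluster(tree, members)):
                lb = ClusterLabel(base, suffix)
                provenance[lb] = "split"
                for leaf in part:
                    assignments[leaf] = lb
    return ClusterPartition(assignments=assignments, provenance=provenance)
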