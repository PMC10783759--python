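"""Rooted-tree input/output and patristic distances.

A rooted phylogenetic tree with branch lengths is the substrate for every
downstream step: the patristic distance matrix feeds the embedding, and the
rooted clade structure defines monophyly, cluster decomposition and
subtending branches.  Trees are held as :class:`dendropy.Tree` objects
wrapped in a validating :class:`RootedTree`.
"""

from __future__ import annotations

import colorsys
import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

__all__ = [
    "TreeValidationError",
    "RootedTree",
    "PatristicDistanceMatrix",
    "read_tree",
    "tree_from_string",
    "patristic_matrix",
    "write_clustered_tree",
    "cluster_colors",
]


class TreeValidationError(ValueError):
    """Raised when an input tree violates a structural invariant."""


def _sniff_format(path: str) -> str:
    with open(path, "r", encoding="utf-8", errors="replace") as fh:
        head = fh.read(4096).lstrip()
    return "nexus" if head.upper().startswith("#NEXUS") else "newick"


class RootedTree:
    """A validated rooted tree with branch lengths.

    Invariants enforced at construction:

    * leaf labels are unique and non-empty;
    * every non-root edge has a finite, non-negative length (zero allowed —
      it occurs in MCC summary trees; negative is an error);
    * the root is a single bifurcation (or a single leaf pair); a basal
      trifurcation marks an unrooted tree and is rejected unless midpoint
      rooting was requested by the caller;
    * at least ``min_leaves`` leaves (2 for distance work; the clustering
      pipeline itself demands more).
    """

    def __init__(self, tree: dendropy.Tree, *, min_leaves: int = 2):
        self._tree = tree
        self._validate(min_leaves)
        self._leaf_labels: tuple[str, ...] = tuple(
            nd.taxon.label for nd in tree.postorder_node_iter() if nd.is_leaf()
        )
        self._leaf_nodes = {
            nd.taxon.label: nd for nd in tree.leaf_node_iter()
        }
        # leaf set under each node, postorder so children precede parents
        self._clades: list[tuple[dendropy.Node, frozenset[str]]] = []
        below: dict[int, frozenset[str]] = {}
        for nd in tree.postorder_node_iter():
            if nd.is_leaf():
                ls = frozenset([nd.taxon.label])
            else:
                ls = frozenset().union(*(below[id(ch)] for ch in nd.child_nodes()))
            below[id(nd)] = ls
            self._clades.append((nd, ls))
        self._clade_sets = {ls for _, ls in self._clades}

    # -- construction helpers -------------------------------------------------

    def _validate(self, min_leaves: int) -> None:
        tree = self._tree
        leaves = [nd for nd in tree.leaf_node_iter()]
        labels = []
        for nd in leaves:
            if nd.taxon is None or not (nd.taxon.label or "").strip():
                raise TreeValidationError("tree contains an unlabeled leaf")
            labels.append(nd.taxon.label)
        seen: set[str] = set()
        dupes = sorted({lb for lb in labels if lb in seen or seen.add(lb)})
        if dupes:
            raise TreeValidationError(
                f"duplicate leaf labels: {', '.join(dupes)}"
            )
        if len(labels) < min_leaves:
            raise TreeValidationError(
                f"tree has {len(labels)} leaves; at least {min_leaves} required"
            )
        root = tree.seed_node
        nchild = len(root.child_nodes())
        if nchild > 2:
            raise TreeValidationError(
                f"root has {nchild} children: tree appears unrooted; "
                "re-root it (e.g. midpoint rooting) before analysis"
            )
        for nd in tree.preorder_node_iter():
            if nd is root:
                continue
            bl = nd.edge.length
            if bl is None:
                who = nd.taxon.label if nd.is_leaf() and nd.taxon else "an internal node"
                raise TreeValidationError(
                    f"missing branch length on the edge above {who}; "
                    "branch lengths are required on every non-root edge"
                )
            if not np.isfinite(bl):
                raise TreeValidationError("non-finite branch length in tree")
            if bl < 0:
                raise TreeValidationError(f"negative branch length {bl}")

    # -- basic accessors ------------------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def leaf_labels(self) -> tuple[str, ...]:
        """Leaf labels in stable postorder; defines matrix row order."""
        return self._leaf_labels

    @property
    def n_leaves(self) -> int:
        return len(self._leaf_labels)

    def newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    # -- clade machinery ------------------------------------------------------

    def clade_leafsets(self) -> frozenset[frozenset[str]]:
        """The leaf set of every node — the tree's laminar clade family."""
        return frozenset(self._clade_sets)

    def check_leaves(self, leafset: Iterable[str]) -> frozenset[str]:
        ls = frozenset(leafset)
        unknown = ls - set(self._leaf_labels)
        if unknown:
            raise KeyError(
                f"labels not in tree: {', '.join(sorted(unknown))}"
            )
        if not ls:
            raise ValueError("empty leaf set")
        return ls

    def mrca_node(self, leafset: Iterable[str]) -> dendropy.Node:
        """Most recent common ancestor: the smallest clade containing the set.

        Postorder visits every node before its ancestors, so the first node
        whose descendant leaf set contains ``leafset`` is the MRCA.
        """
        ls = self.check_leaves(leafset)
        for nd, below in self._clades:
            if ls <= below:
                return nd
        raise AssertionError("unreachable: root contains every leaf")

    def leafset_below(self, node: dendropy.Node) -> frozenset[str]:
        for nd, below in self._clades:
            if nd is node:
                return below
        raise KeyError("node not in tree")


def read_tree(
    path: str | os.PathLike,
    format: str = "auto",
    *,
    midpoint_root: bool = False,
    min_leaves: int = 2,
) -> RootedTree:
    """Read a rooted tree from a newick or nexus file.

    Quoted labels are unquoted and ``[...]`` comments stripped by the parser;
    nexus TRANSLATE tables are resolved to full labels.  An unrooted input
    (basal trifurcation) is an error unless ``midpoint_root`` is set, in
    which case the tree is midpoint-rooted first.
    """
    path = os.fspath(path)
    if format == "auto":
        format = _sniff_format(path)
    if format not in ("newick", "nexus"):
        raise ValueError(f"unknown tree format {format!r}")
    try:
        dtree = dendropy.Tree.get(
            path=path, schema=format, preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises assorted parse errors
        raise TreeValidationError(f"could not parse {path} as {format}: {exc}") from exc
    return _finalize(dtree, midpoint_root=midpoint_root, min_leaves=min_leaves)


def tree_from_string(
    data: str, format: str = "newick", *, midpoint_root: bool = False,
    min_leaves: int = 2,
) -> RootedTree:
    """Parse a tree from an in-memory newick/nexus string."""
    try:
        dtree = dendropy.Tree.get(
            data=data, schema=format, preserve_underscores=True
        )
    except Exception as exc:
        raise TreeValidationError(f"could not parse {format} tree: {exc}") from exc
    return _finalize(dtree, midpoint_root=midpoint_root, min_leaves=min_leaves)


def _finalize(
    dtree: dendropy.Tree, *, midpoint_root: bool, min_leaves: int
) -> RootedTree:
    if midpoint_root and len(dtree.seed_node.child_nodes()) != 2:
        dtree.reroot_at_midpoint(update_bipartitions=False)
    return RootedTree(dtree, min_leaves=min_leaves)


@dataclass(frozen=True)
class PatristicDistanceMatrix:
    """Symmetric leaf-by-leaf matrix of summed branch-length path distances.

    ``values[i, j]`` is the patristic distance δ(i, j) between
    ``labels[i]`` and ``labels[j]``; row order equals the source tree's
    stable postorder leaf order.
    """

    labels: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match label count")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite distances")
        if np.any(v < 0) or not np.allclose(v, v.T) or np.any(np.diag(v) != 0):
            raise ValueError("not a valid distance matrix")
        object.__setattr__(self, "values", v)
        object.__setattr__(
            self, "_index", {lb: i for i, lb in enumerate(self.labels)}
        )

    @property
    def n(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self._index[label]

    def distance(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def indices(self, labels: Iterable[str]) -> np.ndarray:
        try:
            return np.array([self._index[lb] for lb in labels], dtype=int)
        except KeyError as exc:
            raise KeyError(f"label not in distance matrix: {exc.args[0]!r}") from exc


def patristic_matrix(tree: RootedTree) -> PatristicDistanceMatrix:
    """Patristic distance matrix of a tree: path branch-length sums."""
    if tree.n_leaves < 2:
        raise TreeValidationError("distance matrix needs at least 2 leaves")
    dmat = dendropy.PhylogeneticDistanceMatrix.from_tree(tree.dendropy_tree)
    labels = tree.leaf_labels
    taxa = {t.label: t for t in tree.dendropy_tree.taxon_namespace}
    n = len(labels)
    values = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            d = dmat.patristic_distance(taxa[labels[i]], taxa[labels[j]])
            values[i, j] = values[j, i] = d
    return PatristicDistanceMatrix(labels=labels, values=values)


def cluster_colors(labels: Sequence[str]) -> dict[str, str]:
    """One distinct hex color per cluster label, deterministic in label order."""
    k = len(labels)
    out = {}
    for i, lb in enumerate(labels):
        r, g, b = colorsys.hsv_to_rgb(i / max(k, 1), 0.85, 0.90)
        out[lb] = "#{:02x}{:02x}{:02x}".format(
            round(r * 255), round(g * 255), round(b * 255)
        )
    return out


def _relabeled_clone(tree: RootedTree, partition: Mapping[str, object]) -> dendropy.Tree:
    clone = dendropy.Tree(tree.dendropy_tree)
    clone.taxon_namespace = dendropy.TaxonNamespace()
    for nd in clone.leaf_node_iter():
        name = nd.taxon.label
        nd.taxon = clone.taxon_namespace.new_taxon(f"{name}|{partition[name]}")
    return clone


def write_clustered_tree(
    tree: RootedTree,
    partition: Mapping[str, object],
    path: str | os.PathLike,
    format: str = "newick",
) -> None:
    """Write the tree with cluster labels appended to the leaf names.

    Newick output renames each leaf ``name`` to ``name|<cluster>``.  Nexus
    output additionally carries one FigTree-style ``[&!color=#RRGGBB]``
    comment per taxon, one distinct color per cluster, assigned
    deterministically in sorted cluster-label order.
    """
    if format not in ("newick", "nexus"):
        raise ValueError(f"unknown output format {format!r}")
    leafset = set(tree.leaf_labels)
    covered = set(partition)
    if covered != leafset:
        missing = sorted(leafset - covered)
        extra = sorted(covered - leafset)
        raise ValueError(
            "partition does not match the tree's leaf set; "
            f"missing={missing}, extra={extra}"
        )
    clone = _relabeled_clone(tree, partition)
    if format == "newick":
        clone.write(path=os.fspath(path), schema="newick", suppress_rooting=True)
        return
    # Nexus with per-taxon color comments in the FigTree annotation
    # convention, which dendropy's writer does not emit.
    order = sorted({str(v) for v in partition.values()})
    colors = cluster_colors(order)
    newick_str = clone.as_string(
        schema="newick", suppress_rooting=True
    ).strip()
    buf = io.StringIO()
    buf.write("#NEXUS\n\nBEGIN TAXA;\n")
    buf.write(f"    DIMENSIONS NTAX={tree.n_leaves};\n    TAXLABELS\n")
    for name in tree.leaf_labels:
        lab = f"{name}|{partition[name]}"
        quoted = "'" + lab.replace("'", "''") + "'"
        buf.write(f"        {quoted}[&!color={colors[str(partition[name])]}]\n")
    buf.write("    ;\nEND;\n\nBEGIN TREES;\n")
    buf.write(f"    TREE clustered = [&R] {newick_str}\n")
    buf.write("END;\n")
    with open(os.fspath(path), "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())
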