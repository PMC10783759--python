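"""Synthetic fixtures: planted-partition trees and Gaussian point clouds.

Real protein-family trees that cluster cleanly have tight subtrees
separated by long stem branches.  The planted-partition generator builds
exactly that geometry — c clades of coalescent-style subtrees of height
about ``within_height``, hung off a backbone with stems of length about
``stem_length`` — together with the ground-truth leaf partition, so every
stage of the pipeline and the whole pipeline can be exercised and scored
with no external data.  The point-cloud generator plants separated
isotropic Gaussian components for testing the mixture stage in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np

from .tree import RootedTree

__all__ = ["PlantedTreeSpec", "generate_planted_tree", "generate_mixture_points"]


@dataclass(frozen=True)
class PlantedTreeSpec:
    """Parameters of a planted-partition tree.

    ``leaves_per_clade`` may be a single int (all clades equal) or one int
    per clade; ``None`` draws each clade's size uniformly from 8–15, the
    subfamily sizes the recovery experiments use.  ``stem_length`` over
    ``within_height`` is the planted separation ratio; the default 100×
    gives unambiguous clusters.

    ``clade_shape`` controls the geometry inside each clade:

    * ``"radiation"`` (default): random-merge topology with short
      exponential internal edges (mean ``internal_scale × within_height``)
      and terminal branches ≈ ``within_height`` — tight subtrees whose
      internal branches are short relative to the stems that separate
      clades.
    * ``"star"``: zero-length internal edges, i.e. a hard polytomy
      radiation.  A single star clade is the structureless negative
      control: a tree with no subfamilies at all.
    """

    n_clades: int = 4
    leaves_per_clade: int | Sequence[int] | None = None
    within_height: float = 0.05
    stem_length: float = 5.0
    internal_scale: float = 0.1
    clade_shape: str = "radiation"
    backbone: str = "caterpillar"
    seed: int = 42

    def __post_init__(self):
        if self.n_clades < 1:
            raise ValueError("need at least one clade")
        if self.within_height <= 0 or self.stem_length <= 0:
            raise ValueError("height and stem scales must be positive")
        if self.internal_scale < 0:
            raise ValueError("internal_scale must be non-negative")
        if self.clade_shape not in ("radiation", "star"):
            raise ValueError(f"unknown clade shape {self.clade_shape!r}")
        if self.backbone not in ("caterpillar", "balanced"):
            raise ValueError(f"unknown backbone shape {self.backbone!r}")
        sizes = self.clade_sizes(np.random.default_rng(self.seed))
        if any(s < 1 for s in sizes):
            raise ValueError("every clade needs at least one leaf")

    def clade_sizes(self, rng: np.random.Generator) -> list[int]:
        if self.leaves_per_clade is None:
            return [int(rng.integers(8, 16)) for _ in range(self.n_clades)]
        if isinstance(self.leaves_per_clade, (int, np.integer)):
            return [int(self.leaves_per_clade)] * self.n_clades
        sizes = [int(s) for s in self.leaves_per_clade]
        if len(sizes) != self.n_clades:
            raise ValueError("leaves_per_clade length must equal n_clades")
        return sizes


def _random_clade(
    taxa: dendropy.TaxonNamespace,
    labels: list[str],
    height: float,
    internal_scale: float,
    shape: str,
    rng: np.random.Generator,
) -> dendropy.Node:
    """A radiation-like random-merge subtree over ``labels``.

    Terminal branches are ``height × U(0.8, 1.2)``; internal edges are
    exponential with mean ``internal_scale × height`` ("radiation") or
    exactly zero ("star"), so the subtree's patristic diameter is about
    2·height and its internal branches are short.
    """
    nodes: list[dendropy.Node] = []
    for lb in labels:
        nd = dendropy.Node(taxon=taxa.new_taxon(lb))
        nd.edge.length = float(height * rng.uniform(0.8, 1.2))
        nodes.append(nd)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        parent = dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        if shape == "star":
            parent.edge.length = 0.0
        else:
            parent.edge.length = float(rng.exponential(internal_scale * height))
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    return nodes[0]


def _stem(rng: np.random.Generator, scale: float) -> float:
    return float(scale * rng.uniform(0.8, 1.2))


def _attach_backbone(
    subtrees: list[dendropy.Node],
    shape: str,
    stem: float,
    rng: np.random.Generator,
) -> dendropy.Node:
    if len(subtrees) == 1:
        return subtrees[0]
    if shape == "caterpillar":
        right = subtrees[-1]
        right.edge.length = (right.edge.length or 0.0) + _stem(rng, stem)
        for st in reversed(subtrees[:-1]):
            st.edge.length = (st.edge.length or 0.0) + _stem(rng, stem)
            node = dendropy.Node()
            node.add_child(st)
            node.add_child(right)
            node.edge.length = _stem(rng, stem)
            right = node
        right.edge.length = None
        return right
    mid = len(subtrees) // 2
    left = _attach_backbone(subtrees[:mid], shape, stem, rng)
    right = _attach_backbone(subtrees[mid:], shape, stem, rng)
    node = dendropy.Node()
    for child in (left, right):
        child.edge.length = (child.edge.length or 0.0) + _stem(rng, stem)
        node.add_child(child)
    return node


def generate_planted_tree(
    spec: PlantedTreeSpec,
) -> tuple[RootedTree, dict[str, int]]:
    """Generate a planted-partition tree and its ground-truth partition.

    Leaf labels encode the true clade ("c03_t007").  Deterministic for a
    fixed spec (including its seed): the same spec yields an identical
    newick string.
    """
    rng = np.random.default_rng(spec.seed)
    sizes = spec.clade_sizes(rng)
    taxa = dendropy.TaxonNamespace()
    subtrees = []
    truth: dict[str, int] = {}
    for ci, size in enumerate(sizes):
        labels = [f"c{ci:02d}_t{ti:03d}" for ti in range(size)]
        for lb in labels:
            truth[lb] = ci
        subtrees.append(
            _random_clade(
                taxa, labels, spec.within_height, spec.internal_scale,
                spec.clade_shape, rng,
            )
        )
    root = _attach_backbone(subtrees, spec.backbone, spec.stem_length, rng)
    root.edge.length = None
    dtree = dendropy.Tree(taxon_namespace=taxa)
    dtree.seed_node = root
    if len(root.child_nodes()) == 0:  # single leaf is not a usable tree
        raise ValueError("planted tree must have at least 2 leaves in total")
    return RootedTree(dtree), truth


def generate_mixture_points(
    k: int,
    n_per_component: int,
    d: int = 2,
    separation: float = 10.0,
    sigma: float = 1.0,
    seed: int = 42,
) -> tuple[np.ndarray, np.ndarray]:
    """Labeled draws from k isotropic Gaussians with means ≥ ``separation``
    apart (placed along the first coordinate axis).  Returns (points
    [k·n_per, d], generating labels)."""
    if k < 1 or n_per_component < 1:
        raise ValueError("k and n_per_component must be positive")
    if separation < 0 or sigma <= 0:
        raise ValueError("separation must be >= 0 and sigma > 0")
    rng = np.random.default_rng(seed)
    means = np.zeros((k, d))
    means[:, 0] = np.arange(k) * separation
    X = np.concatenate(
        [rng.normal(means[c], sigma, size=(n_per_component, d)) for c in range(k)]
    )
    labels = np.repeat(np.arange(k), n_per_component)
    return X, labels
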