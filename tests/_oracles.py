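"""Independent brute-force oracles used to check the implementation.

These deliberately avoid the code paths they verify: patristic distances
are summed along explicitly enumerated ancestor paths, maximal contained
clades come from exhaustive pairwise subset comparison, and parsimony
scores from complete enumeration of internal state assignments.
"""

from __future__ import annotations

import itertools

import dendropy


def _ancestors(node):
    path = [node]
    while path[-1].parent_node is not None:
        path.append(path[-1].parent_node)
    return path


def patristic_oracle(dtree: dendropy.Tree) -> dict[tuple[str, str], float]:
    """Pairwise leaf distances by explicit path enumeration: walk both
    leaves' root paths, cut at the lowest shared node, sum edge lengths."""
    leaves = [nd for nd in dtree.leaf_node_iter()]
    out: dict[tuple[str, str], float] = {}
    for a, b in itertools.combinations(leaves, 2):
        pa, pb = _ancestors(a), _ancestors(b)
        sb = {id(n) for n in pb}
        dist = 0.0
        for nd in pa:
            if id(nd) in sb:
                lca = nd
                break
            dist += nd.edge.length or 0.0
        for nd in pb:
            if nd is lca:
                break
            dist += nd.edge.length or 0.0
        key = tuple(sorted((a.taxon.label, b.taxon.label)))
        out[key] = dist
    return out


def all_clades(dtree: dendropy.Tree) -> set[frozenset[str]]:
    clades = set()
    below = {}
    for nd in dtree.postorder_node_iter():
        if nd.is_leaf():
            ls = frozenset([nd.taxon.label])
        else:
            ls = frozenset().union(*(below[id(c)] for c in nd.child_nodes()))
        below[id(nd)] = ls
        clades.add(ls)
    return clades


def maximal_contained_clades(
    dtree: dendropy.Tree, leafset: frozenset[str]
) -> set[frozenset[str]]:
    """Every clade of the tree contained in ``leafset`` that is not a
    proper subset of another contained clade; order-free by construction."""
    contained = [c for c in all_clades(dtree) if c <= leafset]
    return {
        c
        for c in contained
        if not any(c < other for other in contained)
    }


def fitch_bruteforce(dtree: dendropy.Tree, states: dict[str, str]) -> int:
    """Minimum state changes by exhaustive assignment of internal states."""
    alphabet = sorted(set(states.values()))
    internals = [nd for nd in dtree.preorder_node_iter() if not nd.is_leaf()]
    edges = []
    for nd in dtree.preorder_node_iter():
        if nd.parent_node is not None:
            edges.append((nd.parent_node, nd))
    best = None
    for combo in itertools.product(alphabet, repeat=len(internals)):
        assign = {id(nd): st for nd, st in zip(internals, combo)}
        for nd in dtree.leaf_node_iter():
            assign[id(nd)] = states[nd.taxon.label]
        changes = sum(
            1 for p, c in edges if assign[id(p)] != assign[id(c)]
        )
        if best is None or changes < best:
            best = changes
    return best
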