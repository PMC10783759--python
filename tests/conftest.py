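import numpy as np
import dendropy
import pytest

from autophy.tree import RootedTree, tree_from_string

TOY4 = "((A:1,B:2):3,(C:4,D:5):6);"
TOY5 = "(((A:1,B:1):1,C:1):1,(D:1,E:1):1);"


@pytest.fixture
def toy4():
    return tree_from_string(TOY4)


@pytest.fixture
def toy5():
    return tree_from_string(TOY5)


def random_binary_tree(n: int, rng: np.random.Generator,
                       prefix: str = "L") -> RootedTree:
    """A random-topology binary tree with uniform(0.1, 2) branch lengths,
    built by random joins — independent of the package's generator."""
    taxa = dendropy.TaxonNamespace()
    nodes = []
    for i in range(n):
        nd = dendropy.Node(taxon=taxa.new_taxon(f"{prefix}{i:03d}"))
        nd.edge.length = float(rng.uniform(0.1, 2.0))
        nodes.append(nd)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        parent = dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        parent.edge.length = float(rng.uniform(0.1, 2.0))
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    nodes[0].edge.length = None
    dtree = dendropy.Tree(taxon_namespace=taxa)
    dtree.seed_node = nodes[0]
    return RootedTree(dtree)
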