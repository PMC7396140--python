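import itertools

import dendropy
import numpy as np
import pytest

from microko.phylogeny import DistanceMatrix


@pytest.fixture
def two_leaf_tree():
    """A rooted 2-leaf tree with total leaf separation 0.15."""
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node.new_child(taxon=tns.new_taxon("x"), edge_length=0.075)
    tree.seed_node.new_child(taxon=tns.new_taxon("y"), edge_length=0.075)
    return tree


def patristic_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """Exact additive distance matrix of a tree (leaf path lengths)."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return DistanceMatrix(labels, d)


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Robinson-Foulds distance via a shared taxon namespace."""
    from dendropy.calculate import treecompare

    tns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(
        data=t1.as_string(schema="newick"), schema="newick", taxon_namespace=tns
    )
    b = dendropy.Tree.get(
        data=t2.as_string(schema="newick"), schema="newick", taxon_namespace=tns
    )
    for t in (a, b):  # compare as unrooted splits
        t.deroot()
        t.encode_bipartitions()
    return treecompare.symmetric_difference(a, b)
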