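import numpy as np
import pytest

from dyphylo import CharacterMatrix, DistanceMatrix, PhyloTree


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_matrix():
    """3 taxa x 4 characters with one missing cell."""
    return CharacterMatrix(
        ("A", "B", "C"),
        np.array(
            [[0, 1, 0, 1], [0, -1, 1, 1], [1, 0, 1, 0]], dtype=np.int8
        ),
    )


@pytest.fixture
def box_distances():
    """The maximally conflicting 4-taxon 'box': AB=BC=CD=DA=1, AC=BD=2."""
    d = np.array(
        [[0, 1, 2, 1], [1, 0, 1, 2], [2, 1, 0, 1], [1, 2, 1, 0]], dtype=float
    )
    return DistanceMatrix(("A", "B", "C", "D"), d)


@pytest.fixture
def additive_distances():
    """Distances from the tree ((A:1,B:1):1,(C:1,D:1):1)."""
    d = np.array(
        [[0, 2, 3, 3], [2, 0, 3, 3], [3, 3, 0, 2], [3, 3, 2, 0]], dtype=float
    )
    return DistanceMatrix(("A", "B", "C", "D"), d)


@pytest.fixture
def five_taxon_tree():
    return PhyloTree.from_newick(
        "((A:0.2,B:0.35):0.15,((C:0.1,D:0.4):0.2,E:0.5):0.1);"
    )


def random_matrix(rng, n_taxa, n_chars, missing=0.1):
    states = rng.integers(0, 2, size=(n_taxa, n_chars)).astype(np.int8)
    mask = rng.random(states.shape) < missing
    states[mask] = -1
    return CharacterMatrix(
        tuple(f"T{i}" for i in range(n_taxa)), states
    )


def tree_distance_matrix(tree: PhyloTree) -> DistanceMatrix:
    """Path-length (additive) distances between the tips of a tree."""
    leaves = tree.leaves()
    labels = [n.label for n in leaves]
    idx = {id(n): i for i, n in enumerate(leaves)}
    n = len(leaves)
    d = np.zeros((n, n))

    def depth_map(node, acc, depths):
        if node.is_leaf:
            depths[id(node)] = acc
        for c in node.children:
            depth_map(c, acc + c.length, depths)

    # distance via LCA over root-to-tip paths
    paths = {}

    def collect(node, path):
        path = path + [node]
        if node.is_leaf:
            paths[id(node)] = path
        for c in node.children:
            collect(c, path)

    collect(tree.root, [])
    for a in leaves:
        for b in leaves:
            if id(a) >= id(b):
                continue
            pa, pb = paths[id(a)], paths[id(b)]
            shared = 0
            for x, y in zip(pa, pb):
                if x is y:
                    shared += 1
                else:
                    break
            dist = sum(n.length for n in pa[shared:]) + sum(
                n.length for n in pb[shared:]
            )
            d[idx[id(a)], idx[id(b)]] = d[idx[id(b)], idx[id(a)]] = dist
    return DistanceMatrix(tuple(labels), d)
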