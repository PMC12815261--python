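"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest

from ptbt import Phylogeny, assign_node_ids, parse_newick, yule_tree


@pytest.fixture
def balanced4():
    """((A,B),(C,D)) with unit branch lengths and assigned clade ids."""
    return assign_node_ids(parse_newick("((A:1,B:1):1,(C:1,D:1):1);"))


@pytest.fixture
def polytomy3():
    return assign_node_ids(parse_newick("(A:1,B:1,C:1);"))


def random_multifurcating(n, seed, max_children=4):
    """Random tree with polytomies: repeatedly merge 2..max_children groups."""
    rng = np.random.default_rng(seed)
    children = [[] for _ in range(n)]
    lengths = [float(rng.uniform(0.1, 2.0)) for _ in range(n)]
    names = [f"L{i + 1:05d}" for i in range(n)]
    items = list(range(n))
    while len(items) > 1:
        k = int(rng.integers(2, min(max_children, len(items)) + 1))
        picks = sorted(rng.choice(len(items), size=k, replace=False))
        group = [items[i] for i in picks]
        for i in reversed(picks):
            items.pop(i)
        v = len(names)
        children.append(list(group))
        lengths.append(float(rng.uniform(0.1, 2.0)))
        names.append(None)
        items.insert(int(rng.integers(len(items) + 1)), v)
    root = items[0]
    parent = np.full(len(names), -1, dtype=np.int64)
    for v, kids in enumerate(children):
        for c in kids:
            parent[c] = v
    bl = np.array(lengths)
    bl[root] = np.nan
    tree = Phylogeny(children, parent, bl, names)
    return assign_node_ids(tree)


def random_tree(n, seed, multifurcating=False):
    if multifurcating:
        return random_multifurcating(n, seed)
    return yule_tree(n, seed=seed)


def gram_schmidt_basis(tree):
    """Independent dense oracle for the Haar-like wavelet basis.

    Gram-Schmidt on [constant vector] + [subtree indicators of children
    c, c-1, ..., 2 of each internal node, nodes in preorder].  Returns a
    dict mapping (node_index, contrast_k) -> unit vector; contrast_k
    matches the fast path's convention (pooled children 0..k-1 vs child
    k).  Vectors are defined up to sign.
    """
    n = tree.n_leaves
    leafsets = tree.subtree_leaf_sets()
    raw, labels = [np.ones(n)], [None]
    for v in tree.preorder():
        kids = tree.children[v]
        for k in range(len(kids) - 1, 0, -1):
            ind = np.zeros(n)
            ind[leafsets[kids[k]]] = 1.0
            raw.append(ind)
            labels.append((v, k))
    ortho = []
    for vec in raw:
        u = vec.astype(float).copy()
        for b in ortho:
            u -= (u @ b) * b
        u /= np.linalg.norm(u)
        ortho.append(u)
    return {lab: ortho[i] for i, lab in enumerate(labels) if lab is not None}
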