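"""Independent oracles shared by the test suite: brute-force topology
enumeration with least-squares branch fitting, for checking neighbor joining
against an exhaustive search."""

import itertools

import numpy as np

from centroscan.phylo import Node, PhyloTree


def enumerate_topologies(labels):
    """All unrooted binary topologies over the labels, built by inserting
    each new leaf on every edge (3 topologies for 4 taxa, 15 for 5)."""
    base = PhyloTree(Node(children=[Node(label=l) for l in labels[:3]]))
    trees = [base]
    for label in labels[3:]:
        nxt = []
        for t in trees:
            edges = _edges(t.root)
            for idx in range(len(edges)):
                nxt.append(_insert_leaf(t, idx, label))
        trees = nxt
    return trees


def _edges(root):
    out = []

    def walk(parent, child_idx, node):
        out.append((parent, child_idx))
        for i, c in enumerate(node.children):
            walk(node, i, c)

    for i, c in enumerate(root.children):
        walk(root, i, c)
    return out


def _clone(node):
    return Node(label=node.label, length=node.length,
                children=[_clone(c) for c in node.children])


def _insert_leaf(tree, edge_idx, label):
    root = _clone(tree.root)
    edges = _edges(root)
    parent, child_idx = edges[edge_idx]
    old = parent.children[child_idx]
    parent.children[child_idx] = Node(children=[old, Node(label=label)])
    return PhyloTree(root)


def _split_design(tree, labels):
    """Pair x edge indicator matrix for least-squares branch fitting."""
    pairs = list(itertools.combinations(sorted(labels), 2))
    cols = []

    def walk(node):
        if node.is_leaf:
            return frozenset([node.label])
        below = frozenset()
        for c in node.children:
            sub = walk(c)
            cols.append(sub)
            below |= sub
        return below

    for c in tree.root.children:
        cols.append(walk(c))
    cols = list(dict.fromkeys(cols))
    a = np.zeros((len(pairs), len(cols)))
    for r, (x, y) in enumerate(pairs):
        for c, side in enumerate(cols):
            if (x in side) != (y in side):
                a[r, c] = 1.0
    return a, pairs


def best_least_squares_topology(dm):
    """The topology whose least-squares branch fit has minimal residual."""
    labels = sorted(dm.labels)
    index = {l: i for i, l in enumerate(dm.labels)}
    best = None
    for tree in enumerate_topologies(labels):
        a, pairs = _split_design(tree, labels)
        d = np.array([dm.matrix[index[x], index[y]] for x, y in pairs])
        x, *_ = np.linalg.lstsq(a, d, rcond=None)
        res = float(np.sum((a @ x - d) ** 2))
        if best is None or res < best[0]:
            best = (res, tree)
    return best[1]


def random_additive_matrix(rng, n):
    """Distances generated from a random binary tree with random branches."""
    labels = [chr(ord("A") + i) for i in range(n)]
    trees = enumerate_topologies(labels)
    tree = trees[rng.randrange(len(trees))]

    def assign(node):
        node.length = rng.uniform(0.1, 1.0)
        for c in node.children:
            assign(c)

    for c in tree.root.children:
        assign(c)
    return tree.path_distances(), tree
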