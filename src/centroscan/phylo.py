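"""Observed-distance computation, neighbor-joining trees and bootstrap
supports for RT-domain alignments.

Distances are observed (p-) distances with pairwise deletion of gapped
columns, matching the "observed evolutionary distances" convention of
classic GUI phylogeny tools; complete deletion is available by flag. The
tree builder is canonical Saitou-Nei neighbor joining with a deterministic
lexicographic tie-break and zero-clamping of negative branch lengths (the
deficit moves to the sister branch), so on an additive matrix the tree's
path metric reproduces the input exactly. Bootstrap supports come from
column resampling and are attached to the full-data tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

_GAP_CHARS = frozenset("-.")


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels in distance matrix")
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValueError("matrix not symmetric")
        if not np.all(np.abs(np.diag(self.matrix)) == 0):
            raise ValueError("nonzero diagonal")
        if np.any(self.matrix < 0):
            raise ValueError("negative distances")


@dataclass
class Node:
    label: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


class PhyloTree:
    """Unrooted leaf-labeled tree (stored rooted at a basal multifurcation)."""

    def __init__(self, root: Node):
        self.root = root

    def leaves(self) -> list[Node]:
        out = []

        def walk(n: Node):
            if n.is_leaf:
                out.append(n)
            for c in n.children:
                walk(c)

        walk(self.root)
        return out

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def newick(self, include_support: bool = True) -> str:
        def fmt(n: Node, top: bool = False) -> str:
            if n.is_leaf:
                return f"{n.label}:{n.length:.10g}"
            inner = ",".join(fmt(c) for c in n.children)
            label = ""
            if include_support and n.support is not None:
                label = f"{n.support:g}"
            if top:
                return f"({inner}){label}"
            return f"({inner}){label}:{n.length:.10g}"

        return fmt(self.root, top=True) + ";"

    def bipartitions(self) -> set[frozenset[str]]:
        """Nontrivial splits, each canonicalized as the side NOT containing
        the lexicographically smallest leaf label."""
        all_leaves = frozenset(self.leaf_labels())
        ref = min(all_leaves)
        splits: set[frozenset[str]] = set()

        def walk(n: Node) -> frozenset:
            if n.is_leaf:
                return frozenset([n.label])
            below = frozenset().union(*(walk(c) for c in n.children))
            if n is not self.root and 2 <= len(below) <= len(all_leaves) - 2:
                side = below if ref not in below else all_leaves - below
                splits.add(side)
            return below

        walk(self.root)
        return splits

    def internal_nodes(self) -> list[Node]:
        out = []

        def walk(n: Node):
            if not n.is_leaf:
                if n is not self.root:
                    out.append(n)
                for c in n.children:
                    walk(c)

        walk(self.root)
        return out

    def path_distances(self) -> DistanceMatrix:
        """Leaf-to-leaf path-length metric of the tree."""
        labels = sorted(self.leaf_labels())
        index = {l: i for i, l in enumerate(labels)}
        n = len(labels)
        d = np.zeros((n, n))

        def walk(node: Node) -> list[tuple[str, float]]:
            if node.is_leaf:
                return [(node.label, node.length)]
            groups = [walk(c) for c in node.children]
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for la, da in groups[gi]:
                        for lb, db in groups[gj]:
                            d[index[la], index[lb]] = d[index[lb], index[la]] = da + db
            merged = [(l, dist + node.length) for g in groups for l, dist in g]
            return merged

        walk(self.root)
        return DistanceMatrix(labels, d)


def p_distance_matrix(
    alignment: Sequence[tuple[str, str]], deletion: str = "pairwise"
) -> DistanceMatrix:
    """Observed-distance matrix from an aligned set of protein sequences.

    distance = mismatches / comparable columns, where comparable means both
    residues non-gap (``deletion="pairwise"``) or no gap in any sequence
    (``deletion="complete"``). A pair with zero comparable columns is an
    error naming the pair.
    """
    labels = [l for l, _ in alignment]
    seqs = [s.upper() for _, s in alignment]
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    width = len(seqs[0])
    if any(len(s) != width for s in seqs):
        raise ValueError("ragged alignment: sequences differ in aligned length")
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate labels")

    mat = np.array([[1 if c in _GAP_CHARS else ord(c) for c in s] for s in seqs])
    gap = mat == 1
    if deletion == "complete":
        keep = ~gap.any(axis=0)
        mat = mat[:, keep]
        gap = gap[:, keep]
    elif deletion != "pairwise":
        raise ValueError(f"unknown deletion mode {deletion!r}")

    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~gap[i] & ~gap[j]
            total = int(ok.sum())
            if total == 0:
                raise ValueError(
                    f"no comparable columns between {labels[i]!r} and {labels[j]!r}"
                )
            mism = int((mat[i][ok] != mat[j][ok]).sum())
            d[i, j] = d[j, i] = mism / total
    return DistanceMatrix(labels, d)


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Canonical Saitou-Nei neighbor joining.

    Ties in the Q criterion are broken by the lexicographically smallest
    (sorted) label pair; negative branch lengths are clamped to zero with
    the deficit moved to the sister branch. On an additive matrix the
    output's path metric reproduces the input.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    d = dm.matrix.astype(float).copy()
    nodes: list[Node] = [Node(label=l) for l in dm.labels]
    # sort key for tie-breaking: min leaf label under each working node
    keys: list[str] = list(dm.labels)

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                pair_key = tuple(sorted((keys[i], keys[j])))
                cand = (q, pair_key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        if li < 0:
            li, lj = 0.0, d[i, j]
        elif lj < 0:
            li, lj = d[i, j], 0.0
        nodes[i].length, nodes[j].length = li, lj
        new = Node(children=[nodes[i], nodes[j]])
        dist_new = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [x for x in range(m) if x not in (i, j)]
        d_next = np.zeros((len(keep) + 1, len(keep) + 1))
        d_next[:-1, :-1] = d[np.ix_(keep, keep)]
        d_next[-1, :-1] = d_next[:-1, -1] = dist_new[keep]
        d = d_next
        nodes = [nodes[x] for x in keep] + [new]
        keys = [keys[x] for x in keep] + [min(keys[i], keys[j])]

    # resolve the final three nodes with the three-point formulas
    (a, b, c) = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    a.length = max(0.0, 0.5 * (dab + dac - dbc))
    b.length = max(0.0, 0.5 * (dab + dbc - dac))
    c.length = max(0.0, 0.5 * (dac + dbc - dab))
    return PhyloTree(Node(children=[a, b, c]))


def bootstrap_support(
    alignment: Sequence[tuple[str, str]],
    n_replicates: int = 1000,
    seed: int = 0,
    deletion: str = "pairwise",
) -> PhyloTree:
    """NJ tree with bootstrap supports from column resampling.

    ``n_replicates`` alignments are drawn by sampling columns with
    replacement (seeded, hence deterministic); the support of each internal
    edge of the full-data tree is the percentage of replicate trees
    containing the same bipartition.
    """
    if n_replicates < 1:
        raise ValueError("need at least 1 replicate")
    tree = neighbor_joining(p_distance_matrix(alignment, deletion=deletion))
    labels = [l for l, _ in alignment]
    seqs = [s for _, s in alignment]
    width = len(seqs[0])
    rng = np.random.default_rng(seed)

    counts: dict[frozenset, int] = {}
    for _ in range(n_replicates):
        cols = rng.integers(0, width, size=width)
        resampled = [
            (l, "".join(s[c] for c in cols)) for l, s in zip(labels, seqs)
        ]
        try:
            rep_tree = neighbor_joining(p_distance_matrix(resampled, deletion=deletion))
        except ValueError:
            continue  # all-gap pair in a replicate: skip it
        for split in rep_tree.bipartitions():
            counts[split] = counts.get(split, 0) + 1

    all_leaves = frozenset(tree.leaf_labels())
    ref = min(all_leaves)

    def below(node: Node) -> frozenset:
        if node.is_leaf:
            return frozenset([node.label])
        return frozenset().union(*(below(c) for c in node.children))

    for node in tree.internal_nodes():
        side = below(node)
        if not (2 <= len(side) <= len(all_leaves) - 2):
            continue
        canonical = side if ref not in side else all_leaves - side
        node.support = 100.0 * counts.get(canonical, 0) / n_replicates
    return tree
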