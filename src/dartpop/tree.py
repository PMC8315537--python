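"""Average-linkage (UPGMA) hierarchical clustering with Newick export.

The implementation uses the Lance–Williams weighted-average update and
a deterministic tie rule: when several cluster pairs attain the minimal
average distance, the pair whose (smallest-leaf, smallest-leaf) label
pair is lexicographically smallest is merged. Node height is half the
merge distance, so cophenetic distances reproduce the average linkage
distances and the tree is ultrametric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gower import DistanceMatrix


@dataclass
class TreeNode:
    height: float
    name: str | None = None  # leaf name
    children: list = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        return [x for c in self.children for x in c.leaves()]


@dataclass
class Dendrogram:
    root: TreeNode
    labels: list[str]
    #: merge log: (label_a, label_b, merge_distance) in merge order,
    #: labels being each cluster's smallest leaf
    merges: list = field(default_factory=list)

    def newick(self, precision: int = 6) -> str:
        root = self.root
        if root.is_leaf:
            return f"{root.name};"
        inner = ",".join(_newick(c, root.height, precision) for c in root.children)
        return f"({inner});"


def _fmt(x: float, precision: int) -> str:
    s = f"{x:.{precision}f}".rstrip("0").rstrip(".")
    return s if s else "0"


def _newick(node: TreeNode, parent_height: float, precision: int) -> str:
    bl = _fmt(parent_height - node.height, precision)
    if node.is_leaf:
        return f"{node.name}:{bl}"
    inner = ",".join(_newick(c, node.height, precision) for c in node.children)
    return f"({inner}):{bl}"


def upgma(D: DistanceMatrix) -> Dendrogram:
    """UPGMA tree from a distance matrix; node height = merge distance / 2."""
    n = D.n
    if n < 2:
        raise ValueError("need at least 2 samples")
    # active clusters keyed by smallest leaf label
    nodes = {lab: TreeNode(0.0, name=lab) for lab in D.labels}
    sizes = {lab: 1 for lab in D.labels}
    dist = {}
    for i in range(n):
        for j in range(i + 1, n):
            a, b = sorted((D.labels[i], D.labels[j]))
            dist[(a, b)] = D.d[i, j]
    merges = []
    while len(nodes) > 1:
        (a, b) = min(dist, key=lambda p: (dist[p], p))
        h = dist[(a, b)]
        merges.append((a, b, h))
        new = min(a, b)
        other = max(a, b)
        parent = TreeNode(h / 2.0, children=[nodes[a], nodes[b]])
        na, nb = sizes[a], sizes[b]
        for c in list(nodes):
            if c in (a, b):
                continue
            ka = tuple(sorted((a, c)))
            kb = tuple(sorted((b, c)))
            d_new = (na * dist[ka] + nb * dist[kb]) / (na + nb)
            del dist[ka], dist[kb]
            dist[tuple(sorted((new, c)))] = d_new
        del dist[(a, b)]
        del nodes[other], sizes[other]
        nodes[new] = parent
        sizes[new] = na + nb
    (root,) = nodes.values()
    return Dendrogram(root=root, labels=list(D.labels), merges=merges)


def cut_tree(dend: Dendrogram, k: int) -> dict[str, int]:
    """Partition leaves into exactly k clusters by undoing the last k-1 merges.

    Cluster labels 1..k are assigned by leaf order of the input labels.
    """
    n = len(dend.labels)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    parent = {lab: lab for lab in dend.labels}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b, _ in dend.merges[: n - k]:
        ra, rb = find(a), find(b)
        parent[max(ra, rb)] = min(ra, rb)
    clusters: dict[str, int] = {}
    nxt = 1
    out = {}
    for lab in dend.labels:
        r = find(lab)
        if r not in clusters:
            clusters[r] = nxt
            nxt += 1
        out[lab] = clusters[r]
    return out


def cophenetic_matrix(dend: Dendrogram) -> DistanceMatrix:
    """Pairwise cophenetic distances (2 x height of the lowest common ancestor)."""
    labels = dend.labels
    idx = {lab: i for i, lab in enumerate(labels)}
    d = np.zeros((len(labels), len(labels)))

    def walk(node):
        if node.is_leaf:
            return [node.name]
        groups = [walk(c) for c in node.children]
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for x in groups[gi]:
                    for y in groups[gj]:
                        d[idx[x], idx[y]] = d[idx[y], idx[x]] = 2.0 * node.height
        return [x for g in groups for x in g]

    walk(dend.root)
    return DistanceMatrix(list(labels), d)
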