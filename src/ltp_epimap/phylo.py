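"""Neighbor-joining phylogeny on uncorrected distances.

Canonical Saitou–Nei neighbor joining: at each step the pair minimizing the
Q criterion is joined; ties are broken by the lowest (row, column) index in
the current matrix so the result is deterministic.  Branch lengths follow
the standard two-point formulas, negative lengths are clamped to zero, and
the final three nodes are joined onto one unresolved internal node, giving
the conventional unrooted binary tree.  NJ is exact on additive distance
matrices, which is what the test-suite oracle exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np


@dataclass
class TreeNode:
    """Node of an (un)rooted phylogeny; leaves carry names."""

    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def leaf_names(self) -> set[str]:
        return {leaf.name for leaf in self.leaves() if leaf.name is not None}


@dataclass(frozen=True)
class PhyloTree:
    """Unrooted tree, stored rooted at the last unresolved NJ node."""

    root: TreeNode
    leaf_ids: tuple[str, ...]

    def newick(self) -> str:
        return _newick(self.root) + ";"

    def write(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            handle.write(self.newick() + "\n")

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits (as the smaller-side leaf set's complement-free
        frozenset), for topology comparison."""
        all_leaves = frozenset(self.leaf_ids)
        splits: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf:
                return frozenset({node.name})
            below = frozenset().union(*(walk(c) for c, _ in node.children))
            if 1 < len(below) < len(all_leaves) - 1:
                side = below if min(below) < min(all_leaves - below) else all_leaves - below
                splits.add(side)
            return below

        for child, _ in self.root.children:
            walk(child)
        return splits


def _newick(node: TreeNode) -> str:
    if node.is_leaf:
        return node.name or ""
    inner = ",".join(f"{_newick(child)}:{length:.6f}" for child, length in node.children)
    return f"({inner})"


def nj_tree(dist: np.ndarray, labels: Sequence[str]) -> PhyloTree:
    """Neighbor-joining tree from a symmetric distance matrix over *labels*."""
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if dist.shape != (n, n) or n != len(labels):
        raise ValueError("distance matrix shape does not match labels")
    if n < 3:
        raise ValueError("neighbor joining requires >= 3 taxa")
    if not np.allclose(dist, dist.T):
        raise ValueError("distance matrix must be symmetric")
    if len(set(labels)) != n:
        raise ValueError("duplicate labels")

    nodes: list[TreeNode] = [TreeNode(name=label) for label in labels]
    d = dist.copy()
    while len(nodes) > 3:
        m = len(nodes)
        totals = d.sum(axis=1)
        q = (m - 2) * d - totals[:, None] - totals[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest (row, col) among minima: flat argmin scans row-major
        flat = int(np.argmin(q))
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        dij = d[i, j]
        li = 0.5 * dij + (totals[i] - totals[j]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        new_d = 0.5 * (d[i, :] + d[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        d = np.vstack([d[keep][:, keep], new_d[keep][None, :]])
        d = np.hstack([d, np.append(new_d[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]

    # join the last three nodes on one internal node (three-point formulas)
    d01, d02, d12 = d[0, 1], d[0, 2], d[1, 2]
    l0 = max(0.5 * (d01 + d02 - d12), 0.0)
    l1 = max(0.5 * (d01 + d12 - d02), 0.0)
    l2 = max(0.5 * (d02 + d12 - d01), 0.0)
    root = TreeNode(children=[(nodes[0], l0), (nodes[1], l1), (nodes[2], l2)])
    return PhyloTree(root=root, leaf_ids=tuple(labels))


def leaf_path_lengths(tree: PhyloTree) -> dict[tuple[str, str], float]:
    """Patristic distances between all leaf pairs (sum of branch lengths).

    Every leaf pair meets at exactly one node; distances are accumulated at
    that meeting node from the per-subtree leaf depths.
    """
    out: dict[tuple[str, str], float] = {}

    def depths(node: TreeNode, acc: float, store: dict[str, float]) -> None:
        if node.is_leaf and node.name is not None:
            store[node.name] = acc
        for child, length in node.children:
            depths(child, acc + length, store)

    def pairs(node: TreeNode) -> None:
        stores = []
        for child, length in node.children:
            store: dict[str, float] = {}
            depths(child, length, store)
            stores.append(store)
            pairs(child)
        for a in range(len(stores)):
            for b in range(a + 1, len(stores)):
                for la, da in stores[a].items():
                    for lb, db in stores[b].items():
                        key = (la, lb) if la < lb else (lb, la)
                        out[key] = da + db

    pairs(tree.root)
    return out
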