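"""BioNJ agglomeration of distance matrices into unrooted trees.

BioNJ is neighbor joining with a variance-weighted reduction step: pairs are
selected by the usual NJ Q-criterion, branch lengths come from the standard
NJ formulas, but when two nodes i and j are merged into u, the reduced
distances d(u,k) are the convex combination

    d(u,k) = lambda * (d(i,k) - L_i) + (1 - lambda) * (d(j,k) - L_j)

with lambda chosen per step (from a running variance matrix, clamped to
[0, 1]) to minimize the variance of the new estimates.  On additive
(tree-like) matrices every lambda gives the same exact reduction, so BioNJ
inherits NJ's exactness there; on noisy matrices the weighting improves
topology recovery.  With ``variance_weighting=False`` lambda is pinned to
1/2, which is classical NJ (Studier-Keppler form).

Ties in the Q-criterion are broken on the lexicographically smallest pair of
canonical labels (the minimum leaf label in each subtree) so trees are
deterministic across platforms.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from crossmeta.io_ace import InputError

__all__ = ["TreeNode", "PhyloTree", "bionj", "internal_branch_length"]


@dataclass
class TreeNode:
    """Node of a rooted representation of an unrooted tree.

    ``children`` holds ``(child, branch_length)`` pairs.  Leaves carry sample
    labels; internal nodes are unnamed.  The root is the final agglomeration
    point: it has three children for trees with >= 3 leaves (representing the
    unrooted trifurcation) and two for the 2-leaf tree.
    """

    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> list[str]:
        if self.is_leaf:
            return [self.name or ""]
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaf_names())
        return out


_UNQUOTED_OK = re.compile(r"^[^\s()\[\]{}:;,']+$")


def _newick_label(name: str) -> str:
    if _UNQUOTED_OK.match(name):
        return name
    return "'" + name.replace("'", "''") + "'"


@dataclass
class PhyloTree:
    """Unrooted tree over sample labels, with branch lengths."""

    root: TreeNode

    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names())

    # -- serialization ----------------------------------------------------

    def newick(self, with_branch_lengths: bool = True,
               clamp_negative: bool = True) -> str:
        """Serialize as Newick.

        Negative branch lengths (possible for NJ-family methods on non-additive
        input) are clamped to zero by default at serialization time only; the
        stored tree keeps the raw values.  With ``with_branch_lengths=False``
        the output contains no ``:`` at all (topology-only cladogram).
        """

        def fmt(node: TreeNode, length: float | None) -> str:
            if node.is_leaf:
                s = _newick_label(node.name or "")
            else:
                inner = ",".join(fmt(c, l) for c, l in node.children)
                s = "(" + inner + ")"
            if with_branch_lengths and length is not None:
                value = max(length, 0.0) if clamp_negative else length
                s += ":" + format(value, ".10g")
            return s

        inner = ",".join(fmt(c, l) for c, l in self.root.children)
        return "(" + inner + ");"

    # -- structural queries -----------------------------------------------

    def bipartitions(self) -> dict[frozenset[frozenset[str]], float]:
        """Map every internal edge's leaf bipartition to its branch length."""
        all_leaves = frozenset(self.leaf_names())
        out: dict[frozenset[frozenset[str]], float] = {}

        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.name or ""])
            below: set[str] = set()
            for child, length in node.children:
                side = walk(child)
                if 2 <= len(side) <= len(all_leaves) - 2:
                    key = frozenset([side, all_leaves - side])
                    out[key] = length
                below |= side
            return frozenset(below)

        walk(self.root)
        return out

    def path_lengths(self) -> dict[tuple[str, str], float]:
        """All leaf-to-leaf path lengths (sum of branch lengths)."""
        dists: dict[tuple[str, str], float] = {}

        def walk(node: TreeNode) -> dict[str, float]:
            if node.is_leaf:
                return {node.name or "": 0.0}
            per_child = []
            for child, length in node.children:
                sub = walk(child)
                per_child.append({k: v + length for k, v in sub.items()})
            for a in range(len(per_child)):
                for b in range(a + 1, len(per_child)):
                    for la, da in per_child[a].items():
                        for lb, db in per_child[b].items():
                            key = (la, lb) if la <= lb else (lb, la)
                            dists[key] = da + db
            merged: dict[str, float] = {}
            for d in per_child:
                merged.update(d)
            return merged

        walk(self.root)
        return dists


def internal_branch_length(
    tree: PhyloTree, partition: tuple[set[str], set[str]]
) -> float | None:
    """Length of the internal edge inducing exactly this leaf bipartition.

    Returns ``None`` when no edge induces the partition.  Both sides must
    have at least two leaves (a singleton side is a pendant edge, not an
    internal bipartition) and together cover all leaves exactly.
    """
    side_a, side_b = frozenset(partition[0]), frozenset(partition[1])
    leaves = frozenset(tree.leaf_names())
    if side_a & side_b:
        raise InputError("partition sides overlap")
    if side_a | side_b != leaves:
        raise InputError("partition does not cover all leaves")
    if len(side_a) < 2 or len(side_b) < 2:
        raise InputError("both partition sides must contain >=2 leaves")
    return tree.bipartitions().get(frozenset([side_a, side_b]))


# ---------------------------------------------------------------------------
# BioNJ agglomeration


def _validate_matrix(values: np.ndarray, labels: tuple[str, ...]) -> np.ndarray:
    D = np.asarray(values, dtype=float)
    n = len(labels)
    if D.shape != (n, n):
        raise InputError("distance matrix shape does not match labels")
    if not np.allclose(D, D.T, atol=1e-12):
        raise InputError("distance matrix must be symmetric")
    if (D < 0).any():
        raise InputError("distance matrix must be non-negative")
    if not np.allclose(np.diag(D), 0.0, atol=1e-12):
        raise InputError("distance matrix diagonal must be zero")
    if n < 2:
        raise InputError("need >=2 labels to build a tree")
    return D


def bionj(matrix, labels=None, variance_weighting: bool = True) -> PhyloTree:
    """Build an unrooted tree from a distance matrix with BioNJ.

    ``matrix`` may be a :class:`crossmeta.distances.DistanceMatrix` or a
    square array plus ``labels``.  For two taxa the single distance is split
    equally across the two pendant edges.
    """
    if labels is None:
        labels = tuple(matrix.labels)
        values = np.asarray(matrix.values, dtype=float)
    else:
        labels = tuple(labels)
        values = np.asarray(matrix, dtype=float)
    D0 = _validate_matrix(values, labels)
    n = len(labels)

    if n == 2:
        half = float(D0[0, 1]) / 2.0
        root = TreeNode(children=[(TreeNode(labels[0]), half),
                                  (TreeNode(labels[1]), half)])
        return PhyloTree(root=root)

    # working matrices indexed by slot; slots beyond the original n are
    # created as agglomerations happen
    size = 2 * n
    d = np.zeros((size, size))
    v = np.zeros((size, size))
    d[:n, :n] = D0
    v[:n, :n] = D0
    nodes: dict[int, TreeNode] = {i: TreeNode(labels[i]) for i in range(n)}
    canon: dict[int, str] = {i: labels[i] for i in range(n)}
    active = list(range(n))
    nxt = n

    while len(active) > 3:
        m = len(active)
        S = {i: sum(d[i, k] for k in active) for i in active}
        best: tuple | None = None
        for ai in range(m):
            for bj in range(ai + 1, m):
                i, j = active[ai], active[bj]
                q = (m - 2) * d[i, j] - S[i] - S[j]
                lab = (min(canon[i], canon[j]), max(canon[i], canon[j]))
                key = (q, lab)
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        # S may include d[i,j] for both rows; those terms cancel in S_i - S_j,
        # so full row sums give the classical NJ branch length directly
        li = d[i, j] / 2.0 + (S[i] - S[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li

        if variance_weighting and v[i, j] > 0:
            acc = sum(v[j, k] - v[i, k] for k in active if k not in (i, j))
            lam = 0.5 + acc / (2.0 * (m - 2) * v[i, j])
            lam = min(max(lam, 0.0), 1.0)
        else:
            lam = 0.5

        u = nxt
        nxt += 1
        nodes[u] = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        canon[u] = min(canon[i], canon[j])
        for k in active:
            if k in (i, j):
                continue
            d[u, k] = d[k, u] = lam * (d[i, k] - li) + (1.0 - lam) * (d[j, k] - lj)
            v[u, k] = v[k, u] = (
                lam * v[i, k] + (1.0 - lam) * v[j, k] - lam * (1.0 - lam) * v[i, j]
            )
        active = [k for k in active if k not in (i, j)] + [u]
        del nodes[i], nodes[j]

    a, b, c = sorted(active, key=lambda k: canon[k])
    la = (d[a, b] + d[a, c] - d[b, c]) / 2.0
    lb = (d[a, b] + d[b, c] - d[a, c]) / 2.0
    lc = (d[a, c] + d[b, c] - d[a, b]) / 2.0
    root = TreeNode(children=[(nodes[a], la), (nodes[b], lb), (nodes[c], lc)])
    return PhyloTree(root=root)
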