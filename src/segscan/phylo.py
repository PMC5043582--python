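"""p-distances, neighbour-joining trees, bootstrap support and tree comparison.

Distances are uncorrected p-distances (proportion of differing sites among
pairwise-complete columns), matching the practice of decorating a fixed NJ
topology with bootstrap percentages rather than building a consensus tree.

Determinism conventions: Q-criterion ties in NJ break on the smallest
``(i, j)`` index pair of the current working matrix; negative branch lengths
are clamped to zero with the deficit transferred to the sibling branch of the
same join (logged at debug level).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .core_io import Alignment, EmptyInputError, UnknownIdError

logger = logging.getLogger(__name__)


class UndefinedDistanceError(ValueError):
    """A sequence pair shares no non-missing column."""


class RootingError(ValueError):
    """The requested outgroup is not compatible with any edge of the tree."""


# ---------------------------------------------------------------------------
# distance matrices
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric matrix of pairwise p-distances over ordered identifiers."""

    ids: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match identifier count")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.d < 0) or not np.all(np.isfinite(self.d)):
            raise ValueError("distances must be finite and non-negative")

    @property
    def n(self) -> int:
        return len(self.ids)

    def value(self, a: str, b: str) -> float:
        return float(self.d[self.ids.index(a), self.ids.index(b)])


def _pdist_from_array(arr: np.ndarray, missing: np.ndarray, ids: Sequence[str]) -> np.ndarray:
    n = arr.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = ~(missing[i] | missing[j])
            m = int(shared.sum())
            if m == 0:
                raise UndefinedDistanceError(
                    f"no shared non-missing columns between {ids[i]!r} and {ids[j]!r}"
                )
            diff = int(np.sum(arr[i, shared] != arr[j, shared]))
            d[i, j] = d[j, i] = diff / m
    return d


def p_distance_matrix(aln: Alignment) -> DistanceMatrix:
    """Pairwise p-distances with pairwise deletion of gaps and ``N``."""
    if aln.n < 2:
        raise EmptyInputError("need at least two sequences for distances")
    arr = aln.to_array()
    missing = aln.missing_mask()
    return DistanceMatrix(aln.ids, _pdist_from_array(arr, missing, aln.ids))


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterable["TreeNode"]:
        for child in self.children:
            yield from child.postorder()
        yield self

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.postorder() if n.is_leaf]


@dataclass
class Tree:
    """Unrooted binary tree held with an arbitrary degree-3 'root' node.

    ``support`` on an internal node is the bootstrap fraction of the edge
    above that node (set only when bootstrap was run).
    """

    root: TreeNode

    @property
    def leaves(self) -> tuple[str, ...]:
        return tuple(sorted(self.root.leaf_names()))

    def edge_sides(self) -> list[tuple[TreeNode, frozenset[str]]]:
        """For every edge (identified by its child node), the leaf set below."""
        sides = []
        below: dict[int, frozenset[str]] = {}
        for node in self.root.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset([node.name])
            else:
                below[id(node)] = frozenset().union(
                    *(below[id(c)] for c in node.children)
                )
            if node is not self.root:
                sides.append((node, below[id(node)]))
        return sides

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, canonicalized to the side not containing
        the lexicographically smallest leaf."""
        all_leaves = frozenset(self.leaves)
        ref = min(all_leaves)
        out = set()
        for _node, side in self.edge_sides():
            if len(side) < 2 or len(side) > len(all_leaves) - 2:
                continue
            canon = side if ref not in side else all_leaves - side
            out.add(canon)
        return out

    def support_map(self) -> dict[frozenset[str], float | None]:
        all_leaves = frozenset(self.leaves)
        ref = min(all_leaves)
        out: dict[frozenset[str], float | None] = {}
        for node, side in self.edge_sides():
            if len(side) < 2 or len(side) > len(all_leaves) - 2:
                continue
            canon = side if ref not in side else all_leaves - side
            out[canon] = node.support
        return out

    def newick(self, support_percent: bool = True) -> str:
        """ASCII newick; branch lengths with 6 decimals; internal-node labels
        are integer bootstrap percentages when support is present."""

        def render(node: TreeNode) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.6f}"
            inner = ",".join(render(c) for c in node.children)
            label = ""
            if node.support is not None and support_percent:
                label = str(int(round(node.support * 100)))
            return f"({inner}){label}:{node.length:.6f}"

        inner = ",".join(render(c) for c in self.root.children)
        return f"({inner});"


# ---------------------------------------------------------------------------
# neighbour joining
# ---------------------------------------------------------------------------


def _clamp_pair(la: float, lb: float) -> tuple[float, float]:
    # negative branch length: clamp to 0, move the deficit to the sibling
    if la < 0:
        logger.debug("clamping negative branch length %.6g", la)
        lb += la
        la = 0.0
    if lb < 0:
        logger.debug("clamping negative branch length %.6g", lb)
        la += lb
        lb = 0.0
        la = max(la, 0.0)
    return la, lb


def nj_tree(D: DistanceMatrix) -> Tree:
    """Saitou–Nei neighbour joining on a distance matrix (n >= 3)."""
    n = D.n
    if n < 3:
        raise ValueError("neighbour joining needs at least 3 taxa")
    if not np.all(np.isfinite(D.d)):
        raise ValueError("non-finite distances")

    nodes: list[TreeNode] = [TreeNode(name=i) for i in D.ids]
    d = D.d.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # smallest (i, j) pair on ties: argmin of the flattened matrix scans
        # rows then columns, which is exactly lowest-i-then-lowest-j
        flat = np.argmin(q)
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        dij = sub[i, j]
        li = dij / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        li, lj = _clamp_pair(li, lj)
        a, b = active[i], active[j]
        parent = TreeNode(children=[nodes[a], nodes[b]])
        nodes[a].length = li
        nodes[b].length = lj
        # distances from the new node to the remaining taxa
        new_row = np.zeros(d.shape[0] + 1)
        for k in active:
            if k in (a, b):
                continue
            new_row[k] = (d[a, k] + d[b, k] - dij) / 2
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [k for k in active if k not in (a, b)] + [len(nodes) - 1]

    # final three-way join, closed form
    a, b, c = active
    la = (d[a, b] + d[a, c] - d[b, c]) / 2
    lb = d[a, b] - la
    lc = d[a, c] - la
    for node, length in zip((nodes[a], nodes[b], nodes[c]), (la, lb, lc)):
        node.length = max(length, 0.0)
        if length < 0:
            logger.debug("clamping negative terminal branch %.6g", length)
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    return Tree(root)


def patristic_distances(tree: Tree) -> DistanceMatrix:
    """Leaf-to-leaf path-length distances (test utility for NJ exactness)."""
    ids = tuple(sorted(tree.leaves))
    index = {name: k for k, name in enumerate(ids)}
    n = len(ids)
    d = np.zeros((n, n))

    def walk(node: TreeNode) -> dict[str, float]:
        if node.is_leaf:
            return {node.name: 0.0}
        groups = [walk(c) for c in node.children]
        for c, g in zip(node.children, groups):
            for name in g:
                g[name] += c.length
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for na, da in groups[gi].items():
                    for nb, db in groups[gj].items():
                        d[index[na], index[nb]] = d[index[nb], index[na]] = da + db
        merged: dict[str, float] = {}
        for g in groups:
            merged.update(g)
        return merged

    walk(tree.root)
    return DistanceMatrix(ids, d)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


def bootstrap_support(aln: Alignment, replicates: int, seed: int) -> Tree:
    """NJ tree on the full alignment, internal edges annotated with the
    fraction of column-resampled replicate trees containing the same
    bipartition.  Same seed, same output."""
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    point = nj_tree(p_distance_matrix(aln))
    arr = aln.to_array()
    missing = aln.missing_mask()
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {b: 0 for b in point.bipartitions()}
    L = aln.length
    done = 0
    attempts = 0
    while done < replicates:
        attempts += 1
        if attempts > 100 * replicates + 100:
            raise RuntimeError("too many degenerate bootstrap replicates")
        cols = rng.integers(0, L, size=L)
        try:
            dm = DistanceMatrix(
                aln.ids, _pdist_from_array(arr[:, cols], missing[:, cols], aln.ids)
            )
        except UndefinedDistanceError:
            continue  # a resample can drop all shared columns of a pair
        rep_bips = nj_tree(dm).bipartitions()
        for b in counts:
            if b in rep_bips:
                counts[b] += 1
        done += 1
    all_leaves = frozenset(point.leaves)
    ref = min(all_leaves)
    for node, side in point.edge_sides():
        if len(side) < 2 or len(side) > len(all_leaves) - 2:
            continue
        canon = side if ref not in side else all_leaves - side
        node.support = counts[canon] / replicates
    return point


# ---------------------------------------------------------------------------
# tree comparison
# ---------------------------------------------------------------------------


def robinson_foulds(t1: Tree, t2: Tree) -> int:
    """Symmetric-difference cardinality of the non-trivial bipartition sets."""
    if frozenset(t1.leaves) != frozenset(t2.leaves):
        raise ValueError("trees have different leaf sets")
    return len(t1.bipartitions() ^ t2.bipartitions())


def sister_group(tree: Tree, focal: str, outgroup: Sequence[str]) -> frozenset[str]:
    """Leaf set of the focal leaf's sibling subtree after outgroup rooting.

    The tree is conceptually rooted on the edge separating ``outgroup`` from
    the rest; the returned set is the other child of the focal leaf's parent.
    """
    leaves = set(tree.leaves)
    og = frozenset(outgroup)
    if not og:
        raise ValueError("outgroup must be non-empty")
    if focal not in leaves:
        raise UnknownIdError(focal)
    if focal in og:
        raise ValueError("focal sequence cannot be in the outgroup")
    if not og <= leaves:
        raise UnknownIdError(sorted(og - leaves)[0])

    sides = {side for _n, side in tree.edge_sides()}
    if len(og) > 1 and og not in sides and (frozenset(leaves) - og) not in sides:
        raise RootingError("outgroup does not form a clade on any edge")

    # clades of the rooted tree are edge sides disjoint from the outgroup
    clades = [
        s
        for side in sides
        for s in (side, frozenset(leaves) - side)
        if not (s & og) and focal in s and len(s) >= 2
    ]
    if not clades:
        # focal attaches directly at the root edge: its sibling is the outgroup
        return og
    parent_clade = min(clades, key=len)
    return parent_clade - {focal}
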