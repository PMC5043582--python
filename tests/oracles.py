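"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately written without reference to the package's
own algorithms: exhaustive enumeration of unrooted tree topologies,
least-squares branch fitting, Fitch parsimony, codon-table enumeration via
Biopython's translation, and exhaustive placement enumeration for the scan
statistic.
"""

from __future__ import annotations

import itertools
from copy import deepcopy

import numpy as np
from Bio.Seq import Seq


# ---------------------------------------------------------------------------
# unrooted tree enumeration (adjacency dicts; internal nodes are negative ints)
# ---------------------------------------------------------------------------


def enumerate_unrooted_trees(labels: list[str]) -> list[dict]:
    """All unrooted binary topologies on the labels (3 for n=4, 15 for n=5,
    105 for n=6), built by inserting each new leaf on every existing edge."""
    assert len(labels) >= 3
    base = {-1: set(labels[:3])}
    for lab in labels[:3]:
        base[lab] = {-1}
    trees = [(base, -2)]
    for leaf in labels[3:]:
        nxt_trees = []
        for adj, nxt in trees:
            edges = {frozenset((u, v)) for u in adj for v in adj[u]}
            for e in edges:
                u, v = tuple(e)
                a = deepcopy(adj)
                a[u].discard(v)
                a[v].discard(u)
                a[nxt] = {u, v, leaf}
                a[u].add(nxt)
                a[v].add(nxt)
                a[leaf] = {nxt}
                nxt_trees.append((a, nxt - 1))
        trees = nxt_trees
    return [adj for adj, _n in trees]


def tree_bipartitions(adj: dict, labels: list[str]) -> set[frozenset]:
    """Non-trivial bipartitions of an adjacency-dict tree, canonicalized to
    the side not containing the smallest label."""
    ref = min(labels)
    leaves = frozenset(labels)
    out = set()
    edges = {frozenset((u, v)) for u in adj for v in adj[u]}
    for e in edges:
        u, v = tuple(e)
        # leaves reachable from u without crossing v
        seen = {u}
        stack = [u]
        while stack:
            x = stack.pop()
            for y in adj[x]:
                if y != v and y not in seen:
                    seen.add(y)
                    stack.append(y)
        side = frozenset(x for x in seen if isinstance(x, str))
        if 2 <= len(side) <= len(labels) - 2:
            out.add(side if ref not in side else leaves - side)
    return out


def path_edges(adj: dict, a, b) -> list[frozenset]:
    """Edges on the unique path between two nodes."""
    prev = {a: None}
    stack = [a]
    while stack:
        x = stack.pop()
        if x == b:
            break
        for y in adj[x]:
            if y not in prev:
                prev[y] = x
                stack.append(y)
    path = []
    cur = b
    while prev[cur] is not None:
        path.append(frozenset((cur, prev[cur])))
        cur = prev[cur]
    return path


def least_squares_fit(adj: dict, labels: list[str], D: np.ndarray) -> float:
    """Ordinary least-squares residual of fitting branch lengths of one
    topology to a distance matrix (unconstrained)."""
    edges = sorted(
        {frozenset((u, v)) for u in adj for v in adj[u]},
        key=lambda e: sorted(map(str, e)),
    )
    eidx = {e: k for k, e in enumerate(edges)}
    pairs = list(itertools.combinations(range(len(labels)), 2))
    A = np.zeros((len(pairs), len(edges)))
    y = np.zeros(len(pairs))
    for r, (i, j) in enumerate(pairs):
        for e in path_edges(adj, labels[i], labels[j]):
            A[r, eidx[e]] = 1.0
        y[r] = D[i, j]
    x, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(np.sum((A @ x - y) ** 2))


def fitch_score(adj: dict, char: dict[str, str]) -> int:
    """Fitch parsimony score of one character on one topology (tree rooted
    on an arbitrary edge)."""
    u = next(iter(char))
    v = next(iter(adj[u]))
    changes = 0

    def fitch(node, parent) -> frozenset:
        nonlocal changes
        kids = [k for k in adj[node] if k != parent]
        if not kids:
            return frozenset(char[node])
        sets = [fitch(k, node) for k in kids]
        inter = frozenset.intersection(*sets)
        if len(sets) == 1:
            return sets[0]
        if inter:
            return inter
        changes += 1
        return frozenset.union(*sets)

    left = fitch(u, v)
    right = fitch(v, u)
    if not (left & right):
        changes += 1
    return changes


def min_extra_changes_pair(col_a: str, col_b: str) -> int:
    """Minimum, over every unrooted tree on the rows, of the extra state
    changes the two characters jointly force (each character's minimum being
    its state count minus one)."""
    n = len(col_a)
    labels = [f"t{k}" for k in range(n)]
    ca = {labels[k]: col_a[k] for k in range(n)}
    cb = {labels[k]: col_b[k] for k in range(n)}
    base_a = len(set(col_a)) - 1
    base_b = len(set(col_b)) - 1
    best = None
    for adj in enumerate_unrooted_trees(labels):
        extra = (fitch_score(adj, ca) - base_a) + (fitch_score(adj, cb) - base_b)
        if best is None or extra < best:
            best = extra
            if best == 0:
                break
    return best


# ---------------------------------------------------------------------------
# codon-table oracles (independent of the package: Biopython translation)
# ---------------------------------------------------------------------------

BASES = "ACGT"
ALL_CODONS = ["".join(c) for c in itertools.product(BASES, repeat=3)]
STOPS = {c for c in ALL_CODONS if str(Seq(c).translate()) == "*"}
SENSE_CODONS = [c for c in ALL_CODONS if c not in STOPS]


def aa(codon: str) -> str:
    return str(Seq(codon).translate())


def brute_codon_sites(codon: str) -> tuple[float, float]:
    s = 0.0
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt not in STOPS and aa(alt) == aa(codon):
                s += 1 / 3
    return s, 3.0 - s


def brute_codon_differences(c1: str, c2: str) -> tuple[float, float]:
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    results = []
    fallback = []
    for order in itertools.permutations(diff):
        cur, sd, nd, bad = c1, 0.0, 0.0, False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOPS and nxt != c2:
                bad = True
            if cur not in STOPS and nxt not in STOPS and aa(cur) == aa(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        fallback.append((sd, nd))
        if not bad:
            results.append((sd, nd))
    use = results or fallback
    return (
        sum(r[0] for r in use) / len(use),
        sum(r[1] for r in use) / len(use),
    )


# ---------------------------------------------------------------------------
# scan-statistic exact null
# ---------------------------------------------------------------------------


def exact_scan_p(L: int, k: int, window: int, m: int) -> float:
    """Exact probability, under uniform placement of k differences among L
    distinct columns, that some window of `window` consecutive columns holds
    at least m of them (full enumeration; small instances only)."""
    hits = 0
    total = 0
    for placed in itertools.combinations(range(L), k):
        total += 1
        best = 0
        for i, p in enumerate(placed):
            cnt = sum(1 for q in placed[i:] if q < p + window)
            best = max(best, cnt)
        if best >= m:
            hits += 1
    return hits / total
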