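"""Pairwise homoplasy index (PHI) statistic and permutation test.

Recombination leaves nearby site pairs more compatible, on average, than
distant ones; clonal (tree-like) evolution does not.  The statistic is the
mean *refined incompatibility score* over pairs of parsimony-informative
sites whose column separation is at most a window ``w``; the null is built
by uniformly permuting the assignment of informative sites to their column
positions, which destroys any distance effect while preserving the set of
pairwise scores.

The refined incompatibility of two aligned characters equals
``E − V + C`` on the bipartite state co-occurrence graph (edges = observed
joint states, vertices = observed states, C = connected components), which
is the minimum number of extra state changes the pair forces on any single
tree; it is 0 iff the two characters are compatible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_io import Alignment, MISSING_CHARS


@dataclass(frozen=True)
class PhiResult:
    """PHI statistic with its permutation (and optional analytic) p-value.

    ``p_perm`` uses the add-one estimator
    ``(1 + #{Φ_perm <= Φ_obs}) / (permutations + 1)`` so it is never 0; low
    values mean nearby pairs are *more* compatible than permuted site orders
    predict, the signature of recombination.
    """

    phi: float
    window_w: int
    n_informative: int
    p_perm: float | None = None
    p_analytic: float | None = None
    permutations: int | None = None
    seed: int | None = None
    degenerate: bool = False

    def tsv_row(self, region: str = "all") -> str:
        pp = "" if self.p_perm is None else f"{self.p_perm:.6g}"
        pa = "" if self.p_analytic is None else f"{self.p_analytic:.6g}"
        perms = "" if self.permutations is None else str(self.permutations)
        seed = "" if self.seed is None else str(self.seed)
        return (
            f"{region}\t{self.n_informative}\t{self.window_w}\t{self.phi:.6g}"
            f"\t{pp}\t{pa}\t{perms}\t{seed}"
        )


TSV_HEADER = "region\tn_informative\twindow\tphi\tp_perm\tp_analytic\tpermutations\tseed"

DEFAULT_WINDOW = 100
DEFAULT_PERMUTATIONS = 1000


def informative_sites(aln: Alignment) -> list[int]:
    """Columns with at least two states each carried by at least two rows
    (gaps and N count as missing)."""
    arr = aln.to_array()
    out = []
    for j in range(aln.length):
        col = [c for c in arr[:, j] if c not in MISSING_CHARS]
        states = {s: col.count(s) for s in set(col)}
        if sum(1 for v in states.values() if v >= 2) >= 2:
            out.append(j)
    return out


def pair_incompatibility(col_a: str, col_b: str) -> int | None:
    """Refined incompatibility score of two site columns; ``None`` when
    fewer than two rows remain after pairwise deletion of missing states."""
    pairs = {
        (a, b)
        for a, b in zip(col_a, col_b)
        if a not in MISSING_CHARS and b not in MISSING_CHARS
    }
    kept = [
        None
        for a, b in zip(col_a, col_b)
        if a not in MISSING_CHARS and b not in MISSING_CHARS
    ]
    if len(kept) < 2:
        return None
    states_a = {a for a, _b in pairs}
    states_b = {b for _a, b in pairs}
    # union-find over the bipartite state graph
    verts = [("a", s) for s in states_a] + [("b", s) for s in states_b]
    parent = {v: v for v in verts}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for a, b in pairs:
        ra, rb = find(("a", a)), find(("b", b))
        if ra != rb:
            parent[ra] = rb
    components = len({find(v) for v in verts})
    return len(pairs) - len(verts) + components


def _score_matrix(aln: Alignment, sites: list[int]) -> np.ndarray:
    """Pairwise incompatibility scores among informative sites (NaN where
    undefined after pairwise deletion)."""
    arr = aln.to_array()
    cols = ["".join(arr[:, j]) for j in sites]
    m = len(sites)
    M = np.full((m, m), np.nan)
    np.fill_diagonal(M, 0.0)
    for i in range(m):
        for j in range(i + 1, m):
            sc = pair_incompatibility(cols[i], cols[j])
            if sc is not None:
                M[i, j] = M[j, i] = float(sc)
    return M


def _window_pairs(positions: list[int], window_w: int) -> tuple[np.ndarray, np.ndarray]:
    pos = np.asarray(positions)
    m = len(pos)
    ii, jj = np.triu_indices(m, k=1)
    keep = (pos[jj] - pos[ii]) <= window_w
    return ii[keep], jj[keep]


def phi_statistic(aln: Alignment, window_w: int = DEFAULT_WINDOW) -> PhiResult:
    """Mean incompatibility over informative-site pairs within the window."""
    sites = informative_sites(aln)
    ii, jj = _window_pairs(sites, window_w)
    if len(sites) < 2 or len(ii) == 0:
        return PhiResult(0.0, window_w, len(sites), degenerate=True)
    M = _score_matrix(aln, sites)
    vals = M[ii, jj]
    if np.all(np.isnan(vals)):
        return PhiResult(0.0, window_w, len(sites), degenerate=True)
    return PhiResult(float(np.nanmean(vals)), window_w, len(sites))


def _analytic_p(M: np.ndarray, ii: np.ndarray, jj: np.ndarray, obs: float) -> float | None:
    """Normal approximation using the exact permutation mean and variance of
    Φ, derived from the finite population of pairwise scores."""
    m = M.shape[0]
    iu, ju = np.triu_indices(m, k=1)
    x = M[iu, ju]
    if np.any(np.isnan(x)):
        return None  # fall back to the permutation p-value only
    npairs = len(x)
    if npairs < 2 or m < 4:
        return None
    mu = x.mean()
    # population moments of scores over pair supports sharing 0 or 1 indices
    S1 = x.sum()
    S2 = (x**2).sum()
    T = M.copy()
    np.fill_diagonal(T, 0.0)
    row = T.sum(axis=1)
    sum_share1 = float((row**2).sum() - 2 * S2)  # ordered, share exactly one
    sum_disjoint = float(S1**2 + S2 - (row**2).sum())  # ordered, disjoint
    n_share1 = m * (m - 1) * (m - 2)  # ordered pairs of pairs sharing one index
    n_disjoint = npairs**2 - npairs - n_share1
    m2 = S2 / npairs
    m_share = sum_share1 / n_share1 if n_share1 else mu**2
    m_dis = sum_disjoint / n_disjoint if n_disjoint else mu**2
    # window pair-of-pairs counts by shared-index class
    W = len(ii)
    deg = np.zeros(m)
    np.add.at(deg, ii, 1)
    np.add.at(deg, jj, 1)
    c_share1 = float((deg**2).sum() - 2 * W)
    c_disjoint = W**2 - W - c_share1
    var = (
        W * (m2 - mu**2) + c_share1 * (m_share - mu**2) + c_disjoint * (m_dis - mu**2)
    ) / W**2
    if var <= 0:
        return 1.0 if obs >= mu else 0.0
    return float(stats.norm.cdf((obs - mu) / np.sqrt(var)))


def phi_test(
    aln: Alignment,
    window_w: int = DEFAULT_WINDOW,
    permutations: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
    analytic: bool = False,
) -> PhiResult:
    """PHI permutation test of the point-mutation (clonal) null.

    Too few informative sites (or no window pairs, or all scores identical)
    gives a degenerate result reported with p = 1 and the degenerate flag.
    """
    if permutations < 1:
        raise ValueError("permutations must be >= 1")
    sites = informative_sites(aln)
    ii, jj = _window_pairs(sites, window_w)
    if len(sites) < 2 or len(ii) == 0:
        return PhiResult(
            0.0, window_w, len(sites), p_perm=1.0, permutations=permutations,
            seed=seed, degenerate=True,
        )
    M = _score_matrix(aln, sites)
    vals = M[ii, jj]
    if np.all(np.isnan(vals)):
        return PhiResult(
            0.0, window_w, len(sites), p_perm=1.0, permutations=permutations,
            seed=seed, degenerate=True,
        )
    obs = float(np.nanmean(vals))
    rng = np.random.default_rng(seed)
    m = len(sites)
    hits = 0
    for _ in range(permutations):
        perm = rng.permutation(m)
        pv = M[perm[ii], perm[jj]]
        if float(np.nanmean(pv)) <= obs + 1e-12:
            hits += 1
    p_perm = (1 + hits) / (permutations + 1)
    p_analytic = _analytic_p(M, ii, jj, obs) if analytic else None
    return PhiResult(
        phi=obs,
        window_w=window_w,
        n_informative=m,
        p_perm=p_perm,
        p_analytic=p_analytic,
        permutations=permutations,
        seed=seed,
    )
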