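"""Nei–Gojobori (1986) synonymous/non-synonymous counting and a bootstrap
Z-test of selection, plus per-SNP effect classification.

The method counts, per codon, fractional synonymous (S) and non-synonymous
(N) *sites* by enumerating all nine single-base neighbours against the
standard genetic code, and classifies pairwise codon *differences* by
averaging over all mutational pathways (2 pathways for 2 differences, 6 for
3).  Proportions pS = Sd/S and pN = Nd/N are uncorrected p-distances.

Conventions (the common NG86 implementation choices):

* substitutions creating stop codons count as non-synonymous for site
  counting;
* pathways passing through stop codons are excluded and the remaining
  pathways re-weighted equally — if every pathway hits a stop, all pathways
  are used with stop steps counted as non-synonymous;
* the variance of pN − pS for the Z statistic comes from a bootstrap over
  codon columns, not the analytic NG86 variance.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats
from Bio.Data import CodonTable

from .core_io import Alignment, ColumnInterval, EmptyInputError, VariantSite, consensus

_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_TABLE.stop_codons)
BASES = "ACGT"


def translate(codon: str) -> str:
    """One-letter amino acid, ``*`` for stop."""
    if codon in STOP_CODONS:
        return "*"
    return _TABLE.forward_table[codon]


def _is_valid_codon(codon: str) -> bool:
    return len(codon) == 3 and all(b in BASES for b in codon)


class SkippedCodon(Exception):
    """Signals a codon containing gaps/N/ambiguity that must be skipped."""


@lru_cache(maxsize=None)
def codon_sites(codon: str) -> tuple[float, float]:
    """Fractional synonymous and non-synonymous site counts of one codon.

    Per position, the S contribution is the fraction of the three possible
    substitutions that preserve the amino acid; S + N == 3 exactly.
    """
    if not _is_valid_codon(codon):
        raise SkippedCodon(codon)
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon}")
    aa = translate(codon)
    s = 0.0
    for pos in range(3):
        syn = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            # stops count as non-synonymous
            if alt not in STOP_CODONS and translate(alt) == aa:
                syn += 1
        s += syn / 3
    return s, 3.0 - s


@lru_cache(maxsize=None)
def codon_differences(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged synonymous and non-synonymous difference counts."""
    for c in (c1, c2):
        if not _is_valid_codon(c):
            raise SkippedCodon(c)
        if c in STOP_CODONS:
            raise ValueError(f"stop codon {c}")
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order: tuple[int, ...]) -> tuple[bool, float, float]:
        cur = c1
        sd = nd = 0.0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS and nxt != c2:
                through_stop = True
            if (
                cur not in STOP_CODONS
                and nxt not in STOP_CODONS
                and translate(cur) == translate(nxt)
            ):
                sd += 1
            else:
                nd += 1
            cur = nxt
        return through_stop, sd, nd

    paths = [walk(order) for order in itertools.permutations(diff_pos)]
    valid = [(sd, nd) for through, sd, nd in paths if not through]
    if not valid:  # fallback: all pathways hit stops
        valid = [(sd, nd) for _t, sd, nd in paths]
    sd = sum(v[0] for v in valid) / len(valid)
    nd = sum(v[1] for v in valid) / len(valid)
    return sd, nd


@dataclass(frozen=True)
class CodonSelectionResult:
    """Aggregated NG86 counts with the optional bootstrap Z-test.

    S and N are pair-averaged site counts summed over all unordered pairs;
    Sd and Nd are pathway-averaged difference counts summed the same way, so
    pS = Sd/S and pN = Nd/N are the overall-average proportions.
    """

    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    n_pairs: int
    n_codons: int
    Z: float | None = None
    p: float | None = None
    boot_replicates: int | None = None
    seed: int | None = None

    def tsv_row(self, region: str = "all") -> str:
        z = "" if self.Z is None else f"{self.Z:.6g}"
        p = "" if self.p is None else f"{self.p:.6g}"
        reps = "" if self.boot_replicates is None else str(self.boot_replicates)
        seed = "" if self.seed is None else str(self.seed)
        return (
            f"{region}\t{self.S:.6g}\t{self.N:.6g}\t{self.Sd:.6g}\t{self.Nd:.6g}"
            f"\t{self.pN:.6g}\t{self.pS:.6g}\t{z}\t{p}\t{reps}\t{seed}"
        )


TSV_HEADER = "region\tS\tN\tSd\tNd\tpN\tpS\tZ\tp\treplicates\tseed"


def _coding_slice(aln: Alignment, coding_range: ColumnInterval | None, frame: int):
    start, end = (
        (coding_range.start, coding_range.end)
        if coding_range is not None
        else (0, aln.length)
    )
    start += frame
    ncod = (end - start) // 3
    if ncod < 1:
        raise EmptyInputError("no complete codon columns in the coding range")
    return start, ncod


def _pair_codon_tables(
    aln: Alignment, coding_range: ColumnInterval | None, frame: int
):
    """Per unordered pair and codon column: (s, n, sd, nd, valid)."""
    start, ncod = _coding_slice(aln, coding_range, frame)
    pairs = list(itertools.combinations(range(aln.n), 2))
    P, C = len(pairs), ncod
    s = np.zeros((P, C))
    n = np.zeros((P, C))
    sd = np.zeros((P, C))
    nd = np.zeros((P, C))
    valid = np.zeros((P, C), dtype=bool)
    for p, (i, j) in enumerate(pairs):
        ri, rj = aln.rows[i], aln.rows[j]
        for c in range(C):
            a = ri[start + 3 * c : start + 3 * c + 3]
            b = rj[start + 3 * c : start + 3 * c + 3]
            if not (_is_valid_codon(a) and _is_valid_codon(b)):
                continue
            if a in STOP_CODONS or b in STOP_CODONS:
                continue  # stop codons in the data: codon skipped for the pair
            sa, na = codon_sites(a)
            sb, nb = codon_sites(b)
            dsd, dnd = codon_differences(a, b)
            s[p, c] = (sa + sb) / 2
            n[p, c] = (na + nb) / 2
            sd[p, c] = dsd
            nd[p, c] = dnd
            valid[p, c] = True
    if not valid.any():
        raise EmptyInputError("no complete codon columns shared by any pair")
    return s, n, sd, nd, valid


def ng_overall(
    aln: Alignment,
    coding_range: ColumnInterval | None = None,
    frame: int = 0,
) -> CodonSelectionResult:
    """Overall-average NG86 counts over all unordered sequence pairs.

    Codons containing gaps, N or stops in either member of a pair are
    excluded for that pair only.
    """
    if aln.n < 2:
        raise EmptyInputError("need at least two sequences")
    s, n, sd, nd, valid = _pair_codon_tables(aln, coding_range, frame)
    S, N = float(s.sum()), float(n.sum())
    Sd, Nd = float(sd.sum()), float(nd.sum())
    return CodonSelectionResult(
        S=S,
        N=N,
        Sd=Sd,
        Nd=Nd,
        pS=Sd / S if S else 0.0,
        pN=Nd / N if N else 0.0,
        n_pairs=s.shape[0],
        n_codons=s.shape[1],
    )


def selection_z_test(
    aln: Alignment,
    coding_range: ColumnInterval | None = None,
    frame: int = 0,
    replicates: int = 500,
    seed: int = 0,
) -> CodonSelectionResult:
    """Codon-column bootstrap Z-test of pN == pS.

    Z = (pN − pS) / sqrt(Var_boot(pN − pS)), two-tailed p from the standard
    normal.  Zero bootstrap variance with pN != pS is reported as infinite
    |Z| with a warning; pN == pS == 0 gives Z = 0, p = 1.
    """
    if replicates < 2:
        raise ValueError("replicates must be >= 2")
    s, n, sd, nd, valid = _pair_codon_tables(aln, coding_range, frame)
    # column-wise totals over pairs are sufficient statistics for resampling
    s_col, n_col = s.sum(axis=0), n.sum(axis=0)
    sd_col, nd_col = sd.sum(axis=0), nd.sum(axis=0)
    C = s.shape[1]
    S, N, Sd, Nd = s_col.sum(), n_col.sum(), sd_col.sum(), nd_col.sum()
    pS = Sd / S if S else 0.0
    pN = Nd / N if N else 0.0

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, C, size=(replicates, C))
    Sb = s_col[idx].sum(axis=1)
    Nb = n_col[idx].sum(axis=1)
    Sdb = sd_col[idx].sum(axis=1)
    Ndb = nd_col[idx].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        diffs = np.where(Nb > 0, Ndb / Nb, 0.0) - np.where(Sb > 0, Sdb / Sb, 0.0)
    var = float(np.var(diffs, ddof=1))

    obs = pN - pS
    if var > 0:
        Z = obs / math.sqrt(var)
    elif obs == 0:
        Z = 0.0
    else:
        warnings.warn("zero bootstrap variance with pN != pS; |Z| is infinite")
        Z = math.copysign(math.inf, obs)
    p = 1.0 if Z == 0 else float(2 * stats.norm.sf(abs(Z)))
    base = ng_overall(aln, coding_range, frame)
    return CodonSelectionResult(
        S=base.S,
        N=base.N,
        Sd=base.Sd,
        Nd=base.Nd,
        pS=base.pS,
        pN=base.pN,
        n_pairs=base.n_pairs,
        n_codons=base.n_codons,
        Z=Z,
        p=p,
        boot_replicates=replicates,
        seed=seed,
    )


def classify_variants(
    aln: Alignment,
    focal: str,
    background: list[str],
    coding_range: ColumnInterval | None = None,
    frame: int = 0,
) -> list[VariantSite]:
    """Columns where the focal sequence differs from the background consensus.

    Coding effect is computed by substituting the focal base into the
    background consensus codon context; gap states give ``indel``; columns
    outside the coding range are ``non-coding``.  Columns where either state
    is ``N`` are not called.
    """
    focal_row = aln.row(focal)
    cons = consensus(aln, background).sequence
    if coding_range is None:
        start, end = 0, aln.length
    else:
        start, end = coding_range.start, coding_range.end
    out: list[VariantSite] = []
    for col in range(aln.length):
        f, b = focal_row[col], cons[col]
        if f == b or f == "N" or b == "N":
            continue
        if not (start <= col < end):
            effect = "non-coding"
        elif f == "-" or b == "-":
            effect = "indel"
        else:
            codon_idx = (col - start - frame) // 3
            cstart = start + frame + 3 * codon_idx
            if codon_idx < 0 or cstart + 3 > end:
                effect = "non-coding"
            else:
                bg_codon = cons[cstart : cstart + 3]
                pos = col - cstart
                mut = bg_codon[:pos] + f + bg_codon[pos + 1 :]
                if not (_is_valid_codon(bg_codon) and _is_valid_codon(mut)):
                    effect = "indel"
                else:
                    effect = (
                        "synonymous"
                        if translate(bg_codon) == translate(mut)
                        and mut not in STOP_CODONS
                        and bg_codon not in STOP_CODONS
                        else "non-synonymous"
                    )
        out.append(VariantSite(col, f, b, effect))
    return out
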