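"""Clustered-difference (cassette) detection and segmental-exchange inference.

The inference mirrors how exchanged cassettes are found between paralogs of
a multigene family: list the columns where a recipient gene differs from its
closest relatives, test whether those differences are more clustered than
uniform placement by point mutation would produce (Monte-Carlo scan
statistic), excise the cassette intervals, compare the recipient's placement
in bootstrap NJ trees before and after excision, and attribute a donor as
the candidate with the fewest mismatches inside the cassettes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .core_io import (
    Alignment,
    ColumnInterval,
    MISSING_CHARS,
    alignment_from_array,
    consensus,
)
from .phylo import Tree, bootstrap_support, robinson_foulds, sister_group

DEFAULT_GAP_MAX = 6
DEFAULT_MIN_COUNT = 3
DEFAULT_SCAN_WINDOW = 30
DEFAULT_MC_REPLICATES = 10_000


class AmbiguousTilingError(ValueError):
    """Two repeat units tie as the best match at one tiling position."""


# ---------------------------------------------------------------------------
# difference census
# ---------------------------------------------------------------------------


def difference_positions(
    aln: Alignment,
    recipient: str,
    background: list[str],
    mode: str = "consensus",
) -> list[int]:
    """Columns where the recipient differs from its background.

    ``consensus`` mode compares against the strict-majority consensus of the
    background; ``unanimous`` mode reports only columns where the recipient
    differs from *every* background member while the background members all
    agree.  Missing states (gap/N) in the recipient or in the compared state
    are never reported.
    """
    if not background:
        raise ValueError("background must be non-empty")
    if recipient in background:
        raise ValueError("recipient cannot be part of the background")
    rec = aln.row(recipient)
    if mode == "consensus":
        cons = consensus(aln, background).sequence
        return [
            j
            for j in range(aln.length)
            if rec[j] not in MISSING_CHARS
            and cons[j] not in MISSING_CHARS
            and rec[j] != cons[j]
        ]
    if mode == "unanimous":
        rows = [aln.row(b) for b in background]
        out = []
        for j in range(aln.length):
            states = {r[j] for r in rows}
            if len(states) != 1:
                continue
            (bg,) = states
            if bg in MISSING_CHARS or rec[j] in MISSING_CHARS:
                continue
            if rec[j] != bg:
                out.append(j)
        return out
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# scan statistic
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClusterReport:
    difference_columns: tuple[int, ...]
    clusters: tuple[ColumnInterval, ...]
    cluster_counts: tuple[int, ...]
    scan_window: int
    p_cluster: float
    mc_replicates: int
    seed: int
    m_max: int


def _split_runs(cols: list[int], gap_max: int) -> list[list[int]]:
    runs: list[list[int]] = []
    for c in cols:
        if runs and c - runs[-1][-1] <= gap_max:
            runs[-1].append(c)
        else:
            runs.append([c])
    return runs


def _enforce_span(run: list[int], scan_window: int) -> list[list[int]]:
    # an over-long run splits at its largest internal gap (leftmost on ties)
    if run[-1] - run[0] + 1 <= scan_window or len(run) == 1:
        return [run]
    gaps = [run[k + 1] - run[k] for k in range(len(run) - 1)]
    cut = int(np.argmax(gaps))
    return _enforce_span(run[: cut + 1], scan_window) + _enforce_span(
        run[cut + 1 :], scan_window
    )


def max_window_count(columns: np.ndarray, scan_window: int) -> int:
    """Maximum number of columns falling in any window of ``scan_window``
    consecutive columns."""
    if len(columns) == 0:
        return 0
    pos = np.sort(np.asarray(columns))
    # window starting at each difference column: count members within it
    hi = np.searchsorted(pos, pos + scan_window, side="left")
    lo = np.arange(len(pos))
    return int((hi - lo).max())


def cluster_scan(
    columns: list[int],
    L: int,
    scan_window: int = DEFAULT_SCAN_WINDOW,
    min_count: int = DEFAULT_MIN_COUNT,
    gap_max: int = DEFAULT_GAP_MAX,
    mc_replicates: int = DEFAULT_MC_REPLICATES,
    seed: int = 0,
) -> ClusterReport:
    """Find clusters of difference columns and a Monte-Carlo cluster p-value.

    Clusters are maximal runs of difference columns with consecutive spacing
    at most ``gap_max`` and total span at most ``scan_window``, keeping runs
    with at least ``min_count`` members.  ``p_cluster`` is the (add-one)
    Monte-Carlo probability that ``k = len(columns)`` differences placed
    uniformly among ``L`` distinct columns produce some window of
    ``scan_window`` columns holding at least the observed maximum count.
    """
    if not (1 <= scan_window <= L):
        raise ValueError("need 1 <= scan_window <= L")
    if mc_replicates < 1:
        raise ValueError("mc_replicates must be >= 1")
    cols = sorted(columns)
    if any(c < 0 or c >= L for c in cols):
        raise ValueError("difference column outside [0, L)")
    if not cols:
        return ClusterReport((), (), (), scan_window, 1.0, mc_replicates, seed, 0)

    clusters: list[ColumnInterval] = []
    counts: list[int] = []
    for run in _split_runs(cols, gap_max):
        for part in _enforce_span(run, scan_window):
            if len(part) >= min_count:
                clusters.append(ColumnInterval(part[0], part[-1] + 1))
                counts.append(len(part))

    m_obs = max_window_count(np.asarray(cols), scan_window)
    k = len(cols)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(mc_replicates):
        placed = rng.choice(L, size=k, replace=False)
        if max_window_count(placed, scan_window) >= m_obs:
            hits += 1
    p = (1 + hits) / (mc_replicates + 1)
    return ClusterReport(
        tuple(cols), tuple(clusters), tuple(counts), scan_window, p,
        mc_replicates, seed, m_obs,
    )


def cassette_intervals(
    report: ClusterReport,
    frame: int = 0,
    pad_to_codon: bool = False,
) -> list[ColumnInterval]:
    """One interval per cluster, first to last member column (half-open),
    optionally widened outward to codon boundaries of the given frame."""
    out = []
    for iv in report.clusters:
        start, end = iv.start, iv.end
        if pad_to_codon:
            start = frame + 3 * ((start - frame) // 3)
            start = max(start, 0)
            end = frame + 3 * (-((frame - end) // 3))  # ceil to boundary
        out.append(ColumnInterval(start, end))
    return out


def excise_columns(aln: Alignment, intervals: list[ColumnInterval]) -> Alignment:
    """Remove the given disjoint column intervals from every row."""
    if not intervals:
        return aln
    ivs = sorted(intervals, key=lambda iv: iv.start)
    for a, b in zip(ivs, ivs[1:]):
        if a.overlaps(b):
            raise ValueError(f"overlapping intervals {a} and {b}")
    if ivs[-1].end > aln.length:
        raise ValueError("interval beyond alignment end")
    keep = np.ones(aln.length, dtype=bool)
    for iv in ivs:
        keep[iv.start : iv.end] = False
    if not keep.any():
        raise ValueError("excision would remove every column")
    arr = aln.to_array()[:, keep]
    return alignment_from_array(aln.ids, arr, aln.frame_offset)


# ---------------------------------------------------------------------------
# donor attribution
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DonorAttribution:
    mismatches: dict[str, int]
    best_donor: str
    margin: int
    ties: tuple[str, ...]

    @property
    def is_tied(self) -> bool:
        return len(self.ties) > 1


def donor_attribution(
    aln: Alignment,
    recipient: str,
    intervals: list[ColumnInterval],
    candidates: list[str],
) -> DonorAttribution:
    """Mismatch count per candidate against the recipient inside the cassette
    union; the best donor minimizes mismatches.  Ties are reported, with the
    alphabetically first tied candidate as ``best_donor``."""
    if not candidates:
        raise ValueError("candidates must be non-empty")
    if recipient in candidates:
        raise ValueError("recipient cannot be a donor candidate")
    if not intervals:
        raise ValueError("need at least one cassette interval")
    rec = aln.row(recipient)
    cols = sorted({c for iv in intervals for c in range(iv.start, iv.end)})
    mism: dict[str, int] = {}
    for cand in candidates:
        row = aln.row(cand)
        mism[cand] = sum(
            1
            for c in cols
            if rec[c] not in MISSING_CHARS
            and row[c] not in MISSING_CHARS
            and rec[c] != row[c]
        )
    best_count = min(mism.values())
    ties = tuple(sorted(c for c, v in mism.items() if v == best_count))
    others = sorted(v for v in mism.values() if v > best_count)
    margin = (others[0] - best_count) if others else 0
    return DonorAttribution(mism, ties[0], margin, ties)


# ---------------------------------------------------------------------------
# topology shift
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TopologyShiftReport:
    sister_before: frozenset[str]
    support_before: float | None
    sister_after: frozenset[str]
    support_after: float | None
    rf_distance: int
    intervals: tuple[ColumnInterval, ...]
    tree_before: Tree = field(compare=False)
    tree_after: Tree = field(compare=False)


def _sister_support(tree: Tree, focal: str, sister: frozenset[str]) -> float | None:
    clade = frozenset(sister | {focal})
    all_leaves = frozenset(tree.leaves)
    ref = min(all_leaves)
    canon = clade if ref not in clade else all_leaves - clade
    return tree.support_map().get(canon)


def topology_shift(
    aln: Alignment,
    recipient: str,
    intervals: list[ColumnInterval],
    outgroup: list[str],
    boot_replicates: int = 1000,
    seed: int = 0,
) -> TopologyShiftReport:
    """Recipient's sister group and support before and after excising the
    cassette intervals, built with identical bootstrap settings and seed,
    plus the Robinson–Foulds distance between the two point trees."""
    if boot_replicates < 1:
        raise ValueError("boot_replicates must be >= 1")
    before = bootstrap_support(aln, boot_replicates, seed)
    after_aln = excise_columns(aln, intervals)
    after = bootstrap_support(after_aln, boot_replicates, seed)
    sb = sister_group(before, recipient, outgroup)
    sa = sister_group(after, recipient, outgroup)
    return TopologyShiftReport(
        sister_before=sb,
        support_before=_sister_support(before, recipient, sb),
        sister_after=sa,
        support_after=_sister_support(after, recipient, sa),
        rf_distance=robinson_foulds(before, after),
        intervals=tuple(sorted(intervals, key=lambda iv: iv.start)),
        tree_before=before,
        tree_after=after,
    )


# ---------------------------------------------------------------------------
# repeat-unit decomposition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RepeatDecomposition:
    units: tuple[str, ...]
    copy_numbers: dict[str, int]
    remainder: str

    def max_run(self, unit_id: str) -> int:
        best = run = 0
        for u in self.units:
            run = run + 1 if u == unit_id else 0
            best = max(best, run)
        return best


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def repeat_unit_decomposition(
    seq: str,
    unit_library: dict[str, str],
    max_mismatch_per_unit: int = 0,
) -> RepeatDecomposition:
    """Greedy left-to-right tiling of ``seq`` by best-matching repeat units.

    Units must be pairwise distinguishable (same-length unit pairs differing
    at more than ``max_mismatch_per_unit`` positions).  A tie between two
    different units at one position raises :class:`AmbiguousTilingError`; an
    un-tileable tail is returned as ``remainder``.  ``copy_numbers`` maps
    each unit id to its longest run of consecutive occurrences.
    """
    if not unit_library:
        raise ValueError("unit library must be non-empty")
    items = sorted(unit_library.items())
    for k, (ida, ua) in enumerate(items):
        for idb, ub in items[k + 1 :]:
            if len(ua) == len(ub) and _hamming(ua, ub) <= max_mismatch_per_unit:
                raise ValueError(
                    f"units {ida!r} and {idb!r} are not distinguishable at "
                    f"more than {max_mismatch_per_unit} mismatches"
                )
    seq = seq.upper()
    tiles: list[str] = []
    pos = 0
    while pos < len(seq):
        scored = []
        for uid, unit in items:
            if pos + len(unit) <= len(seq):
                mm = _hamming(seq[pos : pos + len(unit)], unit)
                if mm <= max_mismatch_per_unit:
                    scored.append((mm, uid, len(unit)))
        if not scored:
            break
        scored.sort()
        if len(scored) > 1 and scored[0][0] == scored[1][0]:
            raise AmbiguousTilingError(
                f"units {scored[0][1]!r} and {scored[1][1]!r} tie at position {pos}"
            )
        _mm, uid, ulen = scored[0]
        tiles.append(uid)
        pos += ulen
    deco = RepeatDecomposition(tuple(tiles), {}, seq[pos:])
    copy_numbers = {uid: deco.max_run(uid) for uid, _u in items}
    return RepeatDecomposition(tuple(tiles), copy_numbers, seq[pos:])


# ---------------------------------------------------------------------------
# JSON rendering
# ---------------------------------------------------------------------------


def report_json(
    cluster_report: ClusterReport,
    intervals: list[ColumnInterval],
    attribution: DonorAttribution | None,
    shift: TopologyShiftReport | None,
) -> str:
    """Serialize one scan run as JSON (intervals 0-based half-open)."""
    doc: dict = {
        "difference_columns": list(cluster_report.difference_columns),
        "clusters": [
            {"start": iv.start, "end": iv.end, "count": c}
            for iv, c in zip(cluster_report.clusters, cluster_report.cluster_counts)
        ],
        "scan_window": cluster_report.scan_window,
        "m_max": cluster_report.m_max,
        "p_cluster": cluster_report.p_cluster,
        "mc_replicates": cluster_report.mc_replicates,
        "seed": cluster_report.seed,
        "cassette_intervals": [
            {"start": iv.start, "end": iv.end} for iv in intervals
        ],
    }
    if attribution is not None:
        doc["donor_attribution"] = {
            "mismatches": dict(sorted(attribution.mismatches.items())),
            "best_donor": attribution.best_donor,
            "margin": attribution.margin,
            "ties": list(attribution.ties),
        }
    if shift is not None:
        doc["topology_shift"] = {
            "sister_before": sorted(shift.sister_before),
            "support_before": shift.support_before,
            "sister_after": sorted(shift.sister_after),
            "support_after": shift.support_after,
            "rf_distance": shift.rf_distance,
        }
    return json.dumps(doc, indent=2, sort_keys=True)
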