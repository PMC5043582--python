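"""Simulated gene families with known evolutionary history.

Two kinds of generator live here:

* a stochastic family simulator — Jukes–Cantor (JC69) point mutation along a
  fixed or Yule tree, with optional planted conversion (segmental-exchange)
  events that copy the donor lineage's *contemporaneous* tract into the
  recipient, plus a neutral coding variant and a repeat-unit copy-number
  generator;
* deterministic scenario builders that plant exact, auditable geometry
  (difference clusters of known size, a donor matching the recipient's
  cassettes except at one nucleotide, allele sets with fixed variant
  censuses).  These are synthetic stand-ins shaped like the cassette
  exchange observed between paralogs of the chicken BG family.

Every generator is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .core_io import Alignment, ColumnInterval
from .selection import STOP_CODONS, BASES

_BASE_ARRAY = np.array(list(BASES))


# ---------------------------------------------------------------------------
# simulation trees
# ---------------------------------------------------------------------------


@dataclass
class SimNode:
    name: str | None = None
    length: float = 0.0
    time: float = 0.0  # absolute time of this node (root at 0)
    children: list["SimNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def preorder(self):
        yield self
        for c in self.children:
            yield from c.preorder()

    def leaves(self) -> list["SimNode"]:
        return [n for n in self.preorder() if n.is_leaf]

    def newick(self) -> str:
        if self.is_leaf:
            return f"{self.name}:{self.length:.6f}"
        inner = ",".join(c.newick() for c in self.children)
        return f"({inner}):{self.length:.6f}"


def _set_times(root: SimNode) -> None:
    for node in root.preorder():
        for c in node.children:
            c.time = node.time + c.length


def parse_sim_tree(newick: str) -> SimNode:
    """Parse a newick string (branch lengths required) into a SimNode tree."""
    tree = dendropy.Tree.get(data=newick, schema="newick")
    def convert(nd) -> SimNode:
        name = nd.taxon.label if nd.taxon is not None else nd.label
        out = SimNode(name=name, length=float(nd.edge.length or 0.0))
        out.children = [convert(c) for c in nd.child_nodes()]
        return out
    root = convert(tree.seed_node)
    _set_times(root)
    return root


def yule_tree(n_genes: int, birth_rate: float, rng: np.random.Generator) -> SimNode:
    """Pure-birth (Yule) ultrametric tree with ``n_genes`` leaves named
    g1..gn in order of lineage creation."""
    if n_genes < 2:
        raise ValueError("need at least 2 genes")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    root = SimNode(time=0.0)
    a, b = SimNode(time=0.0), SimNode(time=0.0)
    root.children = [a, b]
    active = [a, b]
    t = 0.0
    while len(active) < n_genes:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        k = int(rng.integers(len(active)))
        node = active[k]
        node.length = t - node.time
        c1, c2 = SimNode(time=t), SimNode(time=t)
        node.children = [c1, c2]
        active[k : k + 1] = [c1, c2]
    t += rng.exponential(1.0 / (birth_rate * len(active)))
    for i, node in enumerate(active):
        node.length = t - node.time
        node.time = t
        node.name = f"g{i + 1}"
    _set_times(root)
    return root


# ---------------------------------------------------------------------------
# family simulator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConversionEvent:
    """A planted segmental exchange: the donor lineage's current tract is
    copied into the recipient at ``time`` (fraction along the recipient's
    terminal branch)."""

    donor: str
    recipient: str
    tract: ColumnInterval
    time: float = 0.5

    def __post_init__(self) -> None:
        if self.donor == self.recipient:
            raise ValueError("donor and recipient must differ")
        if not (0.0 <= self.time <= 1.0):
            raise ValueError("event time must be a fraction in [0, 1]")


@dataclass(frozen=True)
class FamilySimConfig:
    """Study conditions for one simulated gene family.

    ``tree`` is either a newick string with branch lengths or ``None``, in
    which case a Yule tree with ``n_genes`` leaves and ``birth_rate`` is
    drawn.  ``subst_rate`` scales substitutions per site per unit branch
    length (JC69).  ``conversion_events`` are planted ground truth.
    """

    n_genes: int = 5
    tree: str | None = None
    seq_length: int = 300
    subst_rate: float = 1.0
    conversion_events: tuple[ConversionEvent, ...] = ()
    birth_rate: float = 1.0
    coding: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seq_length < 3:
            raise ValueError("seq_length must be >= 3")
        if self.coding and self.seq_length % 3:
            raise ValueError("coding sequences need seq_length divisible by 3")
        if self.subst_rate < 0:
            raise ValueError("subst_rate must be >= 0")


@dataclass(frozen=True)
class FamilySimResult:
    alignment: Alignment
    events: tuple[ConversionEvent, ...]
    tree_newick: str


def _branch_events(rng: np.random.Generator, L: int, rate: float, duration: float):
    """Presampled mutation events on one branch: (rel_time, site, base_choice)."""
    n = rng.poisson(rate * duration * L)
    times = np.sort(rng.uniform(0.0, duration, size=n))
    sites = rng.integers(0, L, size=n)
    choices = rng.integers(0, 3, size=n)
    return list(zip(times.tolist(), sites.tolist(), choices.tolist()))


def _apply_event(seq: list[str], site: int, choice: int) -> None:
    cur = seq[site]
    alternatives = [b for b in BASES if b != cur]
    seq[site] = alternatives[choice]


def _build_tree(cfg: FamilySimConfig, rng: np.random.Generator) -> SimNode:
    if cfg.tree is not None:
        return parse_sim_tree(cfg.tree)
    return yule_tree(cfg.n_genes, cfg.birth_rate, rng)


def simulate_family(cfg: FamilySimConfig) -> FamilySimResult:
    """Evolve a gene family by JC69 along a tree with planted conversions.

    Mutation events are presampled per branch (Poisson number, uniform
    times); a conversion event replays the recipient's terminal branch,
    splicing in the donor lineage's sequence as of the event's absolute
    time.  Fixed seed gives bit-identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    root = _build_tree(cfg, rng)
    leaves = root.leaves()
    names = [lf.name for lf in leaves]
    if len(set(names)) != len(names):
        raise ValueError("duplicate leaf names in simulation tree")
    for ev in cfg.conversion_events:
        for who in (ev.donor, ev.recipient):
            if who not in names:
                raise ValueError(f"event references unknown lineage {who!r}")
        if ev.tract.end > cfg.seq_length:
            raise ValueError("conversion tract outside sequence bounds")

    L = cfg.seq_length
    root_seq = [str(b) for b in rng.choice(_BASE_ARRAY, size=L)]

    # presample events in fixed preorder so the draw order is reproducible
    events: dict[int, list] = {}
    for node in root.preorder():
        if node is not root:
            events[id(node)] = _branch_events(rng, L, cfg.subst_rate, node.length)

    seqs: dict[int, list[str]] = {id(root): root_seq}
    parent_of: dict[int, SimNode] = {}
    for node in root.preorder():
        for c in node.children:
            parent_of[id(c)] = node
            seq = list(seqs[id(node)])
            for _t, site, choice in events[id(c)]:
                _apply_event(seq, site, choice)
            seqs[id(c)] = seq

    def donor_seq_at(donor_leaf: SimNode, when: float) -> list[str]:
        path = []
        def descend(node: SimNode) -> bool:
            if node is donor_leaf:
                return True
            for c in node.children:
                if descend(c):
                    path.append(c)
                    return True
            return False
        descend(root)
        path.reverse()
        seq = list(root_seq)
        for node in path:
            t0 = parent_of[id(node)].time
            if node.time <= when:
                for _t, site, choice in events[id(node)]:
                    _apply_event(seq, site, choice)
            else:
                for t, site, choice in events[id(node)]:
                    if t0 + t <= when:
                        _apply_event(seq, site, choice)
                break
        return seq

    by_leaf = {lf.name: lf for lf in leaves}
    per_recipient: dict[str, list[ConversionEvent]] = {}
    for ev in cfg.conversion_events:
        per_recipient.setdefault(ev.recipient, []).append(ev)

    for rec_name, evs in per_recipient.items():
        leaf = by_leaf[rec_name]
        parent = parent_of[id(leaf)]
        branch = events[id(leaf)]
        evs = sorted(evs, key=lambda e: e.time)
        seq = list(seqs[id(parent)])
        cursor = 0
        for ev in evs:
            rel = ev.time * leaf.length
            while cursor < len(branch) and branch[cursor][0] <= rel:
                _t, site, choice = branch[cursor]
                _apply_event(seq, site, choice)
                cursor += 1
            donor = donor_seq_at(by_leaf[ev.donor], parent.time + rel)
            seq[ev.tract.start : ev.tract.end] = donor[ev.tract.start : ev.tract.end]
        for _t, site, choice in branch[cursor:]:
            _apply_event(seq, site, choice)
        seqs[id(leaf)] = seq

    aln = Alignment(
        tuple(names), tuple("".join(seqs[id(lf)]) for lf in leaves),
        frame_offset=0 if cfg.coding else None,
    )
    return FamilySimResult(aln, tuple(cfg.conversion_events), root.newick() + ";")


def simulate_neutral_coding(cfg: FamilySimConfig) -> Alignment:
    """Neutral coding evolution: mutations are accepted regardless of their
    amino-acid effect, but mutations creating internal stop codons are
    rejected and redrawn, so the frame stays open."""
    if not cfg.coding:
        raise ValueError("config must set coding=True")
    rng = np.random.default_rng(cfg.seed)
    root = _build_tree(cfg, rng)
    leaves = root.leaves()
    L = cfg.seq_length

    sense = sorted(
        a + b + c
        for a in BASES for b in BASES for c in BASES
        if a + b + c not in STOP_CODONS
    )
    root_seq = list("".join(rng.choice(sense) for _ in range(L // 3)))

    def mutate_no_stop(seq: list[str], site: int, choice: int) -> None:
        cur = seq[site]
        alternatives = [b for b in BASES if b != cur]
        new = alternatives[choice]
        start = 3 * (site // 3)
        for _ in range(1000):
            codon = seq[start:site] + [new] + seq[site + 1 : start + 3]
            if "".join(codon) not in STOP_CODONS:
                seq[site] = new
                return
            site = int(rng.integers(0, L))
            cur = seq[site]
            new = str(rng.choice([b for b in BASES if b != cur]))
            start = 3 * (site // 3)
        raise RuntimeError("could not place a non-stop mutation")

    seqs: dict[int, list[str]] = {id(root): root_seq}
    for node in root.preorder():
        for c in node.children:
            seq = list(seqs[id(node)])
            for _t, site, choice in _branch_events(rng, L, cfg.subst_rate, c.length):
                mutate_no_stop(seq, site, choice)
            seqs[id(c)] = seq
    return Alignment(
        tuple(lf.name for lf in leaves),
        tuple("".join(seqs[id(lf)]) for lf in leaves),
        frame_offset=0,
    )


def simulate_repeat_cnv(
    unit_library: dict[str, str],
    repeat_unit: str,
    copy_range: tuple[int, int],
    flanks: tuple[list[str], list[str]],
    n_variants: int,
    seed: int = 0,
) -> tuple[list[str], list[int]]:
    """Tandem repeat-unit copy-number variants with ground truth.

    Each variant is left flank + k copies of ``repeat_unit`` + right flank,
    with k drawn uniformly from ``copy_range`` (inclusive).  Mirrors repeat
    blocks whose transcripts vary between one and a few copies of a
    multi-exon unit.
    """
    if not unit_library:
        raise ValueError("unit library must be non-empty")
    if repeat_unit not in unit_library:
        raise ValueError(f"unknown repeat unit {repeat_unit!r}")
    lo, hi = copy_range
    if not (1 <= lo <= hi <= 10):
        raise ValueError("copy_range must satisfy 1 <= lo <= hi <= 10")
    left, right = flanks
    rng = np.random.default_rng(seed)
    seqs, truth = [], []
    for _ in range(n_variants):
        k = int(rng.integers(lo, hi + 1))
        parts = [unit_library[u] for u in left]
        parts += [unit_library[repeat_unit]] * k
        parts += [unit_library[u] for u in right]
        seqs.append("".join(parts))
        truth.append(k)
    return seqs, truth


def jc69_expected_p(subst_per_site: float) -> float:
    """Closed-form JC69 expected p-distance for a given number of
    substitutions per site separating two sequences."""
    return 0.75 * (1.0 - math.exp(-4.0 * subst_per_site / 3.0))


# ---------------------------------------------------------------------------
# deterministic scenario builders (synthetic stand-ins)
# ---------------------------------------------------------------------------


def _pick_spaced(
    rng: np.random.Generator,
    candidates: list[int],
    count: int,
    spacing: int,
    taken: list[int],
) -> list[int]:
    pool = list(candidates)
    rng.shuffle(pool)
    picked: list[int] = []
    for c in pool:
        if all(abs(c - t) > spacing for t in taken + picked):
            picked.append(c)
            if len(picked) == count:
                return sorted(picked)
    raise RuntimeError("could not place spaced columns")


def _mutate_base(rng: np.random.Generator, base: str) -> str:
    return str(rng.choice([b for b in BASES if b != base]))


@dataclass(frozen=True)
class SegmentalExchangeScenario:
    """Synthetic five-gene family (plus outgroup) with two planted cassettes.

    The recipient carries two short tracts copied from the donor — one with
    8 difference columns inside a 9-column span, one with 4 inside a
    7-column span — and one later point mutation inside the first tract, so
    the donor matches the recipient's cassettes except at one nucleotide.
    This reproduces, with known truth, the geometry of the BG6→BG13 cassette
    exchange; the sequences themselves are synthetic.
    """

    alignment: Alignment
    donor: str
    recipient: str
    background: tuple[str, ...]
    outgroup: str
    cassettes: tuple[ColumnInterval, ...]
    cluster_counts: tuple[int, ...]
    donor_mismatch_total: int


def segmental_exchange_family(seed: int = 0, L: int = 300) -> SegmentalExchangeScenario:
    rng = np.random.default_rng(seed)
    backbone = [str(b) for b in rng.choice(_BASE_ARRAY, size=L)]

    cas1 = ColumnInterval(76, 85)   # 8 difference columns in a 9-column span
    cas2 = ColumnInterval(150, 157)  # 4 difference columns in a 7-column span
    cas1_cols = [c for c in range(cas1.start, cas1.end) if c != 80]
    cas2_cols = [150, 152, 154, 156]
    buffer = set(range(cas1.start - 7, cas1.end + 7)) | set(
        range(cas2.start - 7, cas2.end + 7)
    )
    candidates = [c for c in range(L) if c not in buffer]

    # columns that will appear in the recipient-vs-background difference set
    # must stay isolated (spacing > gap_max) so the only clusters are the two
    # planted cassettes; the rest only need to be distinct columns
    taken: list[int] = []
    ab_shared = _pick_spaced(rng, candidates, 5, 7, taken); taken += ab_shared
    cd_shared = _pick_spaced(rng, candidates, 5, 7, taken); taken += cd_shared
    rec_private = _pick_spaced(rng, candidates, 3, 7, taken); taken += rec_private
    leftover = [c for c in candidates if c not in taken]
    rng.shuffle(leftover)
    donor_scatter = sorted(leftover[:4])
    privates = {"BG13": rec_private}
    pos = 4
    for name in ("BG8", "BG9", "BG12"):
        privates[name] = sorted(leftover[pos : pos + 3])
        pos += 3

    def derive(cols: list[int], base_seq: list[str] | None = None) -> dict[int, str]:
        src = base_seq if base_seq is not None else backbone
        return {c: _mutate_base(rng, src[c]) for c in cols}

    donor_cassette = derive(cas1_cols + cas2_cols)
    donor_scatter_m = derive(donor_scatter)
    ab_m = derive(ab_shared)
    cd_m = derive(cd_shared)
    private_m = {g: derive(cols) for g, cols in privates.items()}

    def build(muts: list[dict[int, str]]) -> str:
        seq = list(backbone)
        for m in muts:
            for c, b in m.items():
                seq[c] = b
        return "".join(seq)

    bg6 = build([donor_cassette, donor_scatter_m])
    bg8 = build([ab_m, private_m["BG8"]])
    bg9 = build([ab_m, private_m["BG9"]])
    bg12 = build([cd_m, private_m["BG12"]])
    # recipient: family backbone + shared-with-BG12 columns + both cassettes
    # copied from the donor + one later mutation inside cassette 1
    extra_col = 77
    third = [
        b for b in BASES if b not in (backbone[extra_col], donor_cassette[extra_col])
    ][0]
    bg13 = build([cd_m, private_m["BG13"], donor_cassette, {extra_col: third}])

    out_cols = sorted(rng.choice(L, size=45, replace=False).tolist())
    outg = build([derive(out_cols)])

    aln = Alignment(
        ("BG6", "BG8", "BG9", "BG12", "BG13", "OUT"),
        (bg6, bg8, bg9, bg12, bg13, outg),
    )
    return SegmentalExchangeScenario(
        alignment=aln,
        donor="BG6",
        recipient="BG13",
        background=("BG8", "BG9", "BG12"),
        outgroup="OUT",
        cassettes=(cas1, cas2),
        cluster_counts=(8, 4),
        donor_mismatch_total=1,
    )


#: two clades of three genes; the recipient x3 sits inside the x clade
#: (internal edge above x2+x3) and receives a distant block from donor y3
_BLOCK_TREE = (
    "((x1:0.06,(x2:0.05,x3:0.05):0.05):0.12,"
    "(y1:0.06,(y2:0.05,y3:0.05):0.05):0.12);"
)


def distant_block_exchange(
    seed: int = 0, L: int = 400, tract: ColumnInterval = ColumnInterval(300, 400)
) -> FamilySimResult:
    """Recombinant scenario with strong signal for the PHI test: two diverged
    three-gene clades, with one distant block copied from donor y3 into
    recipient x3 late on its terminal branch."""
    cfg = FamilySimConfig(
        n_genes=6,
        tree=_BLOCK_TREE,
        seq_length=L,
        subst_rate=1.0,
        conversion_events=(ConversionEvent("y3", "x3", tract, time=0.9),),
        seed=seed,
    )
    return simulate_family(cfg)


#: structured family with a long-diverged donor paralog: the family shares a
#: long stem so the donor's tracts are locally dense enough to scan for
_RECOVERY_TREE = "(((r:0.02,f1:0.02):0.01,(f2:0.02,f3:0.02):0.01):0.25,d:0.30);"
RECOVERY_TRACTS = (ColumnInterval(60, 110), ColumnInterval(170, 220))


def conversion_recovery_family(seed: int = 0) -> FamilySimResult:
    """Detection scenario: a tight four-gene family and a donor paralog
    separated by ~0.5 substitutions/site, with two 50-nt tracts copied into
    the recipient midway down its terminal branch.  Local tract divergence
    (~30%) mirrors the density of observed exchanged cassettes."""
    cfg = FamilySimConfig(
        tree=_RECOVERY_TREE,
        seq_length=300,
        subst_rate=1.0,
        conversion_events=tuple(
            ConversionEvent("d", "r", iv, 0.5) for iv in RECOVERY_TRACTS
        ),
        seed=seed,
    )
    return simulate_family(cfg)


#: family with internal structure, a donor adjacent to the recipient's
#: subfamily, and a distant outgroup for rooting
_SISTER_TREE = (
    "((((f3:0.05,r:0.05):0.02,d:0.07):0.05,"
    "(f1:0.10,f2:0.10):0.02):0.06,o:0.18);"
)
SISTER_TRACTS = (ColumnInterval(40, 100), ColumnInterval(160, 220))


def sister_shift_family(seed: int = 0) -> FamilySimResult:
    """Topology-shift scenario: two 60-nt tracts (40% of the sequence)
    copied late into the recipient pull it next to the donor in the
    before-excision tree; excising the true tracts restores its family
    placement.  Root on the ``o`` outgroup."""
    cfg = FamilySimConfig(
        tree=_SISTER_TREE,
        seq_length=300,
        subst_rate=1.0,
        conversion_events=tuple(
            ConversionEvent("d", "r", iv, 0.95) for iv in SISTER_TRACTS
        ),
        seed=seed,
    )
    return simulate_family(cfg)


def clonal_family(seed: int = 0, L: int = 300, n_genes: int = 6) -> Alignment:
    """Point-mutation-only family on the same clade structure (no events);
    the null scenario for PHI calibration."""
    cfg = FamilySimConfig(
        n_genes=n_genes, tree=_BLOCK_TREE, seq_length=L, subst_rate=1.0, seed=seed
    )
    return simulate_family(cfg).alignment


# ---------------------------------------------------------------------------
# allele-set stand-ins with fixed variant censuses
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlleleScenario:
    """Synthetic allele set with a planted variant census."""

    alignment: Alignment
    reference: str
    coding_range: ColumnInterval
    frame: int
    n_variable: int
    n_nonsynonymous: int
    n_synonymous: int


def _random_coding(rng: np.random.Generator, n_codons: int) -> str:
    sense = sorted(
        a + b + c
        for a in BASES for b in BASES for c in BASES
        if a + b + c not in STOP_CODONS
    )
    return "".join(rng.choice(sense) for _ in range(n_codons))


def _aa(codon: str) -> str:
    from .selection import translate

    return translate(codon)


def _plant_coding_variant(
    rng: np.random.Generator, cons: list[str], cstart: int, codon_idx: int,
    synonymous: bool,
) -> tuple[int, str] | None:
    """A single-base change in the given codon with the requested effect;
    returns (column, new_base) or None if the codon cannot host one."""
    start = cstart + 3 * codon_idx
    codon = "".join(cons[start : start + 3])
    options = []
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if mut in STOP_CODONS:
                continue
            if (_aa(mut) == _aa(codon)) == synonymous:
                options.append((start + pos, b))
    if not options:
        return None
    return options[int(rng.integers(len(options)))]


def _allele_scenario(
    rng: np.random.Generator,
    allele_ids: tuple[str, ...],
    utr5: int,
    n_codons: int,
    utr3: int,
    plan: list[tuple[str, int, tuple[str, ...]]],
) -> AlleleScenario:
    """Build an allele alignment from a variant plan.

    ``plan`` rows are (kind, count, carrier allele ids) with kind one of
    ``utr5``, ``utr3``, ``nonsynonymous``, ``synonymous``.  One variant per
    column; coding variants occupy distinct codons.
    """
    L = utr5 + 3 * n_codons + utr3
    coding = ColumnInterval(utr5, utr5 + 3 * n_codons)
    cons = list(
        "".join(str(b) for b in rng.choice(_BASE_ARRAY, size=utr5))
        + _random_coding(rng, n_codons)
        + "".join(str(b) for b in rng.choice(_BASE_ARRAY, size=utr3))
    )
    rows = {a: list(cons) for a in allele_ids}
    used_codons: set[int] = set()
    used_cols: set[int] = set()
    counts = {"variable": 0, "nonsynonymous": 0, "synonymous": 0}

    def fresh_utr_col(lo: int, hi: int) -> int:
        for _ in range(10_000):
            c = int(rng.integers(lo, hi))
            if c not in used_cols:
                used_cols.add(c)
                return c
        raise RuntimeError("no free UTR column")

    for kind, count, carriers in plan:
        for _ in range(count):
            if kind in ("utr5", "utr3"):
                lo, hi = (0, utr5) if kind == "utr5" else (L - utr3, L)
                col = fresh_utr_col(lo, hi)
                newb = _mutate_base(rng, cons[col])
            else:
                placed = None
                for _ in range(10_000):
                    ci = int(rng.integers(n_codons))
                    if ci in used_codons:
                        continue
                    placed = _plant_coding_variant(
                        rng, cons, utr5, ci, synonymous=(kind == "synonymous")
                    )
                    if placed is not None:
                        used_codons.add(ci)
                        break
                if placed is None:
                    raise RuntimeError("could not place coding variant")
                col, newb = placed
                used_cols.add(col)
                counts[kind] += 1
            for a in carriers:
                rows[a][col] = newb
            counts["variable"] += 1

    aln = Alignment(
        allele_ids, tuple("".join(rows[a]) for a in allele_ids), frame_offset=0
    )
    return AlleleScenario(
        alignment=aln,
        reference="".join(cons),
        coding_range=coding,
        frame=0,
        n_variable=counts["variable"],
        n_nonsynonymous=counts["nonsynonymous"],
        n_synonymous=counts["synonymous"],
    )


def bg0_like_alleles(seed: int = 0) -> AlleleScenario:
    """Nearly monomorphic housekeeping-gene stand-in: seven alleles with
    exactly seven isolated variable positions — one in the 5'UTR, four in
    the 3'UTR and two non-synonymous coding SNPs."""
    rng = np.random.default_rng(seed)
    ids = ("UCD001", "line6", "lineC", "line7", "line15", "lineN", "lineP")
    plan = [
        ("utr5", 1, ("line6",)),
        ("utr3", 4, ("line15",)),
        ("nonsynonymous", 1, ("UCD001", "line6")),
        ("nonsynonymous", 1, ("line6",)),
    ]
    return _allele_scenario(rng, ids, utr5=100, n_codons=300, utr3=200, plan=plan)


def bg1_like_alleles(seed: int = 0) -> AlleleScenario:
    """Polymorphic-but-unselected stand-in: six alleles with 39 planted
    non-synonymous and 9 synonymous coding positions (most carried by the
    divergent B15-like allele), six 5'UTR and seven 3'UTR variants.  All
    shared variants carry the same allele split, so the PHI test finds no
    distance-dependent incompatibility (p = 1)."""
    rng = np.random.default_rng(seed)
    ids = ("B2", "B4", "B12", "B14", "B15", "B21")
    plan = [
        ("utr5", 6, ("B15",)),
        ("utr3", 7, ("B15",)),
        ("nonsynonymous", 30, ("B15",)),
        ("nonsynonymous", 3, ("B15", "B14")),
        ("nonsynonymous", 2, ("B2",)),
        ("nonsynonymous", 2, ("B4",)),
        ("nonsynonymous", 2, ("B21",)),
        ("synonymous", 7, ("B15",)),
        ("synonymous", 1, ("B2",)),
        ("synonymous", 1, ("B12",)),
    ]
    return _allele_scenario(rng, ids, utr5=100, n_codons=300, utr3=200, plan=plan)
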