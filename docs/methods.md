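# Methods

This note records the models, conventions and numerical choices behind
`segscan`, and what the synthetic study conditions do and do not establish.

## Data model and coordinates

All stages consume a gap-aware nucleotide alignment (equal-length rows over
`{A,C,G,T,N,-}`). Columns are 0-based and intervals half-open throughout;
1-based figure-style numbering appears only in rendered reports. Gaps and
`N` are missing data everywhere downstream (pairwise deletion), the common
convention for distance methods; the source alignments this design targets
are length-matched single-exon regions, so no de novo alignment or indel
model is attempted. Consensus calls are strict plurality with ties broken
alphabetically (A<C<G<T) and flagged in an ambiguity mask, so results are
deterministic and auditable.

## Distances, trees, bootstrap

Pairwise distances are uncorrected p-distances (differing columns /
pairwise-complete columns). No multiple-hit correction is applied by
default: the analyses this package reproduces used p-distances, and at the
within-family divergences involved (≲25%) corrections change little.

Neighbour joining follows Saitou–Nei with the Q-criterion. Two
conventions make output deterministic and well-formed:

* Q-minimization ties break on the smallest (i, j) index pair of the
  current working matrix.
* Negative intermediate branch lengths are clamped to zero with the
  deficit transferred to the sibling branch of the same join (preserving
  the joined pair's path length), logged at debug level.

On additive matrices the recovered topology is exact and patristic
distances reproduce the input to ≤1e-9 (property-tested against exhaustive
topology enumeration with least-squares fitting).

Bootstrap support resamples alignment columns with replacement, rebuilds
the NJ tree per replicate, and maps the fraction of replicates containing
each bipartition onto the *point-estimate* tree (no consensus tree), the
way alignment-tool bootstrap percentages decorate a fixed topology. A
replicate whose resampled columns leave some pair with no shared
non-missing data is discarded and redrawn (bounded), which only matters
for pathologically gapped inputs. Robinson–Foulds distance is the
symmetric difference of non-trivial bipartition sets (checked against
dendropy). Sister groups are read from the tree rooted on the outgroup
edge; the outgroup must form a clade compatible with some edge.

## Nei–Gojobori selection statistics

Site counts per codon enumerate all nine single-base neighbours against
the standard genetic code; the synonymous fraction per position is
(synonymous substitutions)/3, so S + N = 3 exactly per codon.
Substitutions creating stop codons count as non-synonymous. Pairwise
differences average over mutational pathways (2 for two differences, 6 for
three); pathways passing through stop codons are excluded and the
remainder re-weighted equally, falling back to all pathways (stop steps
non-synonymous) when every pathway hits a stop. These are the common NG86
implementation conventions. Codons containing gaps, `N` or stops in either
member of a pair are skipped for that pair.

The "overall average" aggregates sums of pair-averaged sites and
pathway-averaged differences over all unordered pairs; pN = Nd/N,
pS = Sd/S as uncorrected proportions. The test of selection is
Z = (pN − pS)/√Var, with the variance estimated by bootstrap over codon
columns (default 500 replicates) rather than the analytic NG86 variance —
variance by sequence-level bootstrap is how the figure-generation software
this mirrors operates. The p-value is two-tailed standard normal. On
neutral coding simulations the empirical type-I rate at α = 0.05 sits
inside the binomial 95% band (recomputed by the acceptance script).

## PHI recombination test

Parsimony-informative sites are columns with ≥2 states each carried by ≥2
rows. For a site pair, the refined incompatibility score is E − V + C on
the bipartite state co-occurrence graph (edges = observed joint states);
this equals the minimum extra state changes any single tree must absorb
for the pair (verified by exhaustive tree enumeration with Fitch parsimony
on ≤6 taxa) and is 0 iff the pair is compatible. Φ is the mean score over
informative-site pairs separated by at most `window_w` columns
(default 100, the method's conventional window). Rows missing in either
column are deleted pairwise; a pair left with <2 rows is excluded.

The null permutes the assignment of informative sites to their column
positions (default 1000 permutations); the p-value uses the add-one
estimator, so it is never 0 and is exact up to Monte-Carlo error. The
optional analytic p is a normal approximation whose mean and variance are
computed exactly from the finite population of pairwise scores (moments
over pairs sharing 0 or 1 site indices); it tracks the permutation p
within 0.05 once ≥50 informative sites are available, and is skipped when
any pairwise score is undefined. Degenerate inputs (fewer than two
informative sites, no in-window pairs, or all scores equal) report p = 1
with a flag rather than an error.

## Cluster scan and cassettes

Clusters of difference columns are maximal runs with consecutive spacing
≤ `gap_max` (default 6) and span ≤ `scan_window` (default 30), keeping
runs with ≥ `min_count` (default 3) members; an over-long run splits
recursively at its largest internal gap (leftmost on ties). The defaults
were set so that both of the published cassette geometries — eight
differences within nine columns and four within seven — are detected
without fusing them with isolated SNPs.

The clustering p-value is Monte Carlo (default 10⁴ replicates): place k
differences uniformly on L distinct columns and take the maximum count in
any `scan_window`-column window; p is the add-one fraction of replicates
reaching the observed maximum. Exact enumeration (used as the test oracle)
is feasible only for small instances; the oracle runs at k ≤ 6, L ≤ 30,
where full placement enumeration is ~10⁵–10⁶ configurations.

Cassette intervals span each cluster's first to last member column
(half-open), optionally padded outward to codon boundaries. Cluster-span
boundaries are a convention: published cassette boundaries are themselves
convention-dependent (adjacent cassettes can be read as one segment), so
intervals are reported, not asserted, as the event's true extent. Donor
attribution counts Hamming mismatches per candidate inside the cassette
union with pairwise deletion; ties are reported as ties. The topology
shift builds bootstrap NJ trees on the full and excised alignments with
identical settings and seed and reports sister groups, their supports, and
the Robinson–Foulds distance between point trees.

Repeat-unit decomposition tiles a sequence greedily left-to-right with the
best-matching unit (≤ `max_mismatch_per_unit` mismatches; ties are an
error, not a silent choice), requiring the unit library to be pairwise
distinguishable beyond the mismatch budget. A greedy tiler (no HMM) is
adequate for near-exact repeat units such as tandem exon repeats; copy
number is the longest consecutive run per unit.

## Simulator and study conditions

Sequences evolve by JC69 (single rate; richer models add nothing to
p-distance analyses) along a fixed newick or Yule tree: per branch the
mutation count is Poisson(rate × length × L) with uniform times and sites.
Conversion copies the donor lineage's *contemporaneous* sequence — the
donor's realized sequence at the event's absolute time, found by replaying
its branch events — into the recipient's tract, interleaved with the
recipient's own branch events in time order, so the planted truth is
always consistent with the emitted alignment. The neutral-coding variant
accepts mutations regardless of amino-acid effect but redraws mutations
that would create stop codons. All generators are bit-reproducible under a
fixed seed. Indel evolution and unequal crossing-over of whole genes are
out of scope.

Deterministic scenario builders plant exact geometry rather than sampling
it, and state their truth in their return values:

* **Cassette-exchange family** (5 genes + outgroup, 300 nt): two donor
  tracts with 8 difference columns in a 9-column span and 4 in a 7-column
  span, one later mutation inside the first tract (donor matches the
  recipient's cassettes except one nucleotide), background genes with
  shared and private scattered SNPs spaced > `gap_max` apart so the only
  clusters are the planted ones.
* **Allele sets**: a nearly monomorphic gene with exactly 7 isolated
  variable positions, and a polymorphic gene with 39 non-synonymous and 9
  synonymous coding positions (plus 6+7 UTR variants), mostly on one
  divergent allele — matching the published censuses these stand in for.
  All shared variants carry one split, so PHI correctly finds no signal
  (p = 1).

Stochastic scenarios define the calibration conditions (sizes chosen to
keep the full suite well under practical runtime while leaving Monte-Carlo
bands tight enough to be meaningful):

* **Distant-block exchange** (PHI power): two three-gene clades separated
  by ~0.5 substitutions/site, a 100-nt terminal block copied late from
  donor to recipient. Rejection in ≥90% of seeded runs.
* **Clonal family** (PHI null): same clade structure, no events; 200 runs
  for the type-I band.
* **Recovery family**: tight four-gene family with a donor ~0.5
  substitutions/site away, two 50-nt tracts copied midway down the
  recipient's branch. Local tract divergence (~30%) mirrors the density of
  observed exchanged cassettes (the published cassettes are far denser
  still: 8 differences in 9 columns). Jaccard ≥ 0.5 between detected and
  true tract unions in ≥80% of 50 runs.
* **Sister-shift family**: structured family with the donor adjacent to
  the recipient's subfamily and two 60-nt tracts (40% of the sequence);
  excising the true tracts moves the recipient's sister group from the
  donor back into the family in ≥80% of 50 runs. With a uniform
  substitution rate, a recipient only crosses the tree towards donors of
  comparable overall divergence — locally hyperdiverged cassettes from a
  globally similar donor, as real families show, shift topology much more
  readily than JC69 can emulate, so this scenario is the conservative case.

What passing these conditions shows — and does not. The synthetic families
have uniform rates, no indels, no rate heterogeneity among sites and no
selection; real gene families violate all four. The tests therefore
establish the *machinery* (counting, scanning, tree logic, calibration
under the stated null), not field performance on arbitrary data. Window,
spacing and count thresholds remain user-visible flags because real
cassette geometry varies.

## Pipeline reproducibility

One master seed fans out to per-stage seeds via CRC32 of
`"<seed>:<stage>"` (kept below 2³¹), so stages are independent but the
whole run is reproducible byte for byte; the manifest records every seed
and setting. Reports are plain TSV/JSON/newick so downstream tooling needs
nothing from this package. Any stage failure aborts with the stage name,
preserving earlier outputs.

## Known limitations

* Gene conversion is not distinguished from double reciprocal crossover —
  the signature analysed here is identical for both.
* Cassette boundaries are cluster spans, not event breakpoints; very close
  events merge, and events sparser than `min_count` differences are
  invisible.
* The NG86 Z-test relies on a normal approximation to a bootstrap
  statistic; with very few codons (< ~30) its calibration degrades.
* The PHI analytic p-value is a tail approximation; the permutation
  p-value is authoritative.
* Outgroup rooting requires the estimated tree to contain the outgroup as
  a clade; with weak signal this can fail, and the error is surfaced
  rather than silently re-rooted.
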