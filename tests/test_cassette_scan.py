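import numpy as np
import pytest

from segscan import (
    Alignment,
    ColumnInterval,
    cassette_intervals,
    cluster_scan,
    difference_positions,
    donor_attribution,
    excise_columns,
    repeat_unit_decomposition,
    segmental_exchange_family,
    simulate_repeat_cnv,
    sister_shift_family,
    topology_shift,
)
from segscan.cassette_scan import AmbiguousTilingError, max_window_count

from conftest import random_alignment
from oracles import exact_scan_p


class TestDifferencePositions:
    def test_identical_recipient_gives_empty(self):
        aln = Alignment(("r", "b1", "b2"), ("ACGT", "ACGT", "ACGT"))
        assert difference_positions(aln, "r", ["b1", "b2"]) == []

    def test_planted_divergent_block(self, rng):
        base = "".join(rng.choice(list("ACGT"), size=60))
        rec = list(base)
        for c in range(20, 29):
            rec[c] = {"A": "C", "C": "G", "G": "T", "T": "A"}[rec[c]]
        aln = Alignment(("r", "b1", "b2", "b3"), ("".join(rec), base, base, base))
        for mode in ("consensus", "unanimous"):
            assert difference_positions(aln, "r", ["b1", "b2", "b3"], mode) == list(
                range(20, 29)
            )

    def test_consensus_superset_of_unanimous(self, rng):
        for _ in range(10):
            aln = random_alignment(rng, 5, 40)
            cons = set(difference_positions(aln, "s0", ["s1", "s2", "s3"], "consensus"))
            unan = set(difference_positions(aln, "s0", ["s1", "s2", "s3"], "unanimous"))
            assert unan <= cons

    def test_empty_background_rejected(self):
        aln = Alignment(("r", "b"), ("AC", "AC"))
        with pytest.raises(ValueError):
            difference_positions(aln, "r", [])


class TestClusterScan:
    def test_spread_out_columns_form_no_clusters(self):
        rep = cluster_scan([10, 40, 70, 100, 130], L=200, mc_replicates=100, seed=1)
        assert rep.clusters == ()
        assert rep.p_cluster > 0

    def test_planted_cluster_found_and_significant(self):
        cols = [5 + 30 * k for k in range(4)] + list(range(200, 209))
        cols = sorted(set(cols))[:12]
        # 8 of the 12 differences sit inside a 9-column span
        cols = [5, 35, 65, 95] + [200, 201, 202, 203, 204, 205, 206, 208]
        rep = cluster_scan(cols, L=300, mc_replicates=10_000, seed=2)
        assert any(
            iv.start == 200 and iv.end == 209 and c == 8
            for iv, c in zip(rep.clusters, rep.cluster_counts)
        )
        assert rep.p_cluster < 0.05

    def test_monte_carlo_matches_exact_enumeration(self):
        """MC p-value agrees with full placement enumeration on a small
        instance (k=5 of L=26 columns, window 6)."""
        cols = [3, 4, 5, 6, 20]
        rep = cluster_scan(
            cols, L=26, scan_window=6, min_count=3, mc_replicates=20_000, seed=3
        )
        exact = exact_scan_p(L=26, k=5, window=6, m=rep.m_max)
        assert rep.m_max == 4
        assert rep.p_cluster == pytest.approx(exact, abs=0.01)

    def test_empty_columns_give_unit_p(self):
        rep = cluster_scan([], L=100, mc_replicates=10, seed=0)
        assert rep.p_cluster == 1.0 and rep.clusters == ()

    def test_seed_determinism(self):
        cols = [1, 2, 3, 50, 51, 52]
        a = cluster_scan(cols, 100, mc_replicates=500, seed=9)
        b = cluster_scan(cols, 100, mc_replicates=500, seed=9)
        assert a == b

    def test_max_window_count(self):
        assert max_window_count(np.array([0, 1, 2, 29, 30]), 30) == 4
        assert max_window_count(np.array([5]), 10) == 1


class TestCassetteIntervals:
    def test_span_and_codon_padding(self):
        from segscan.cassette_scan import ClusterReport

        rep = ClusterReport(
            tuple(range(10, 19)), (ColumnInterval(10, 19),), (9,), 30, 0.01, 100, 0, 9
        )
        assert cassette_intervals(rep) == [ColumnInterval(10, 19)]
        assert cassette_intervals(rep, frame=0, pad_to_codon=True) == [
            ColumnInterval(9, 21)
        ]

    def test_empty_report(self):
        from segscan.cassette_scan import ClusterReport

        rep = ClusterReport((), (), (), 30, 1.0, 10, 0, 0)
        assert cassette_intervals(rep) == []


class TestExciseColumns:
    def test_identity_on_empty_intervals(self, rng):
        aln = random_alignment(rng, 4, 50)
        assert excise_columns(aln, []) == aln

    def test_length_arithmetic(self, rng):
        aln = random_alignment(rng, 5, 300)
        out = excise_columns(
            aln, [ColumnInterval(75, 102), ColumnInterval(150, 171)]
        )
        assert out.length == 252

    def test_rows_sliced_identically(self, rng):
        aln = random_alignment(rng, 3, 40)
        ivs = [ColumnInterval(5, 10), ColumnInterval(20, 22)]
        out = excise_columns(aln, ivs)
        keep = [c for c in range(40) if not any(c in iv for iv in ivs)]
        for rid in aln.ids:
            assert out.row(rid) == "".join(aln.row(rid)[c] for c in keep)

    def test_full_excision_rejected(self, rng):
        aln = random_alignment(rng, 3, 10)
        with pytest.raises(ValueError):
            excise_columns(aln, [ColumnInterval(0, 10)])

    def test_overlapping_intervals_rejected(self, rng):
        aln = random_alignment(rng, 3, 20)
        with pytest.raises(ValueError):
            excise_columns(aln, [ColumnInterval(0, 5), ColumnInterval(4, 8)])

    def test_excised_region_carries_no_difference_columns(self):
        scen = segmental_exchange_family(seed=4)
        out = excise_columns(scen.alignment, list(scen.cassettes))
        diffs = difference_positions(out, scen.recipient, list(scen.background))
        # after removing both cassettes only isolated columns remain
        from segscan import cluster_scan as _  # noqa: F401

        rep_cols = set(diffs)
        for iv in scen.cassettes:
            # old cassette coordinates must not reappear as clustered runs
            assert all(
                b - a > 6
                for a, b in zip(sorted(rep_cols), sorted(rep_cols)[1:])
            )


class TestDonorAttribution:
    def test_identical_candidate_scores_zero(self):
        aln = Alignment(("r", "d", "x"), ("ACGTACGT", "ACGTACGT", "TTTTACGT"))
        att = donor_attribution(aln, "r", [ColumnInterval(0, 4)], ["d", "x"])
        assert att.mismatches == {"d": 0, "x": 3}
        assert att.best_donor == "d" and att.margin == 3 and not att.is_tied

    def test_ties_are_reported(self):
        aln = Alignment(("r", "a", "b"), ("AAAA", "AAAT", "AATA"))
        att = donor_attribution(aln, "r", [ColumnInterval(0, 4)], ["a", "b"])
        assert att.is_tied and att.ties == ("a", "b")

    def test_scenario_truth(self):
        scen = segmental_exchange_family(seed=0)
        att = donor_attribution(
            scen.alignment,
            scen.recipient,
            list(scen.cassettes),
            [scen.donor, *scen.background],
        )
        assert att.best_donor == scen.donor
        assert att.mismatches[scen.donor] == scen.donor_mismatch_total
        assert att.margin > 0

    def test_empty_candidates_rejected(self):
        aln = Alignment(("r", "d"), ("AC", "AC"))
        with pytest.raises(ValueError):
            donor_attribution(aln, "r", [ColumnInterval(0, 1)], [])


class TestTopologyShift:
    def test_empty_intervals_are_identity(self):
        scen = segmental_exchange_family(seed=1)
        rep = topology_shift(
            scen.alignment, scen.recipient, [], [scen.outgroup],
            boot_replicates=20, seed=5,
        )
        assert rep.sister_before == rep.sister_after
        assert rep.rf_distance == 0

    def test_scenario_shift(self):
        scen = segmental_exchange_family(seed=0)
        rep = topology_shift(
            scen.alignment, scen.recipient, list(scen.cassettes), [scen.outgroup],
            boot_replicates=100, seed=5,
        )
        assert scen.donor in rep.sister_before
        assert rep.sister_after <= set(scen.background)
        assert rep.rf_distance > 0

    def test_simulated_family_shift(self):
        from segscan.synthetic_data import SISTER_TRACTS

        res = sister_shift_family(seed=2)
        rep = topology_shift(
            res.alignment, "r", list(SISTER_TRACTS), ["o"],
            boot_replicates=50, seed=1,
        )
        assert "d" in rep.sister_before
        assert rep.sister_after & {"f1", "f2", "f3"}


class TestRepeatDecomposition:
    UNITS = {"u1": "AAAACCCC", "u2": "GGGGTTTT", "u3": "ACACACAC"}

    def test_simple_tiling_and_copy_number(self):
        seq = self.UNITS["u1"] + self.UNITS["u2"] * 2 + self.UNITS["u3"]
        d = repeat_unit_decomposition(seq, self.UNITS)
        assert d.units == ("u1", "u2", "u2", "u3")
        assert d.copy_numbers["u2"] == 2 and d.remainder == ""

    def test_single_unit(self):
        d = repeat_unit_decomposition(self.UNITS["u2"], self.UNITS)
        assert d.units == ("u2",) and d.copy_numbers["u2"] == 1

    def test_remainder_reported(self):
        d = repeat_unit_decomposition(self.UNITS["u1"] + "GGG", self.UNITS)
        assert d.units == ("u1",) and d.remainder == "GGG"

    def test_mismatch_tolerance(self):
        noisy = "AAAACCCG" + self.UNITS["u2"]  # one mismatch in u1
        d = repeat_unit_decomposition(noisy, self.UNITS, max_mismatch_per_unit=1)
        assert d.units == ("u1", "u2")

    def test_ambiguous_tie_raises(self):
        units = {"a": "AAAA", "b": "TTTT"}
        with pytest.raises(AmbiguousTilingError):
            repeat_unit_decomposition("AATT" + "AAAA", units, max_mismatch_per_unit=2)

    def test_indistinguishable_units_rejected(self):
        units = {"a": "AAAA", "b": "AAAT"}
        with pytest.raises(ValueError):
            repeat_unit_decomposition("AAAA", units, max_mismatch_per_unit=1)

    def test_recovers_simulated_copy_numbers(self):
        seqs, truth = simulate_repeat_cnv(
            self.UNITS, "u2", (1, 3), (["u1"], ["u3"]), n_variants=8, seed=5
        )
        for seq, k in zip(seqs, truth):
            d = repeat_unit_decomposition(seq, self.UNITS)
            assert d.copy_numbers["u2"] == k
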