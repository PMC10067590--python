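"""SNP/indel calling, K0 and I statistics, group summaries, allele tables."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mtintrons.pairwise_align import PairwiseAlignment, align_pair
from mtintrons.polymorphism import (
    build_discrimination_table,
    call_polymorphisms,
    compute_divergence,
    divergence_between,
    gel_resolvable_pairs,
    jc69,
    k2p,
    summarize_group,
)
from mtintrons.synthetic_data import mutate_sequence, random_dna


class TestCallPolymorphisms:
    def test_identical_sequences(self):
        aln = align_pair("ACGTACGT", "ACGTACGT")
        assert call_polymorphisms(aln) == ([], [])

    def test_single_snp_coordinates(self):
        aln = PairwiseAlignment("a", "b", "ACGTAC", "ACTTAC", 0.0)
        snps, indels = call_polymorphisms(aln)
        assert indels == []
        (s,) = snps
        assert (s.column, s.offset_a, s.offset_b) == (3, 3, 3)
        assert (s.base_a, s.base_b) == ("G", "T")

    def test_ct_like_flag(self):
        aln = PairwiseAlignment("a", "b", "CA", "TG", 0.0)
        snps, _ = call_polymorphisms(aln)
        assert [s.is_ct_like for s in snps] == [True, True]  # C/T and A/G
        aln = PairwiseAlignment("a", "b", "C", "G", 0.0)
        snps, _ = call_polymorphisms(aln)
        assert snps[0].is_ct_like is False

    def test_maximal_gap_runs_are_single_events(self):
        aln = PairwiseAlignment("a", "b", "AC----GT--A", "ACTTTTGTCCA", 0.0)
        _, indels = call_polymorphisms(aln)
        assert [(i.column_start, i.length, i.bearer) for i in indels] == [
            (3, 4, "b_has_insertion"),
            (9, 2, "b_has_insertion"),
        ]

    def test_n_columns_not_called_as_snps(self):
        aln = PairwiseAlignment("a", "b", "ANGT", "ACGT", 0.0)
        snps, _ = call_polymorphisms(aln)
        assert snps == []

    def test_symmetry_under_swap(self):
        a, b = "ACGTACGTACGTACGTACGTACGTACGTAA", "ACGTACGAACGTACGTACGTACGTAA"
        s1, i1 = call_polymorphisms(align_pair(a, b))
        s2, i2 = call_polymorphisms(align_pair(b, a))
        assert len(s1) == len(s2)
        assert sorted(i.length for i in i1) == sorted(i.length for i in i2)
        bearer_flip = {"a_has_insertion": "b_has_insertion",
                       "b_has_insertion": "a_has_insertion"}
        assert sorted(i.bearer for i in i1) == sorted(
            bearer_flip[i.bearer] for i in i2
        )

    def test_planted_mutation_set_recovered_exactly(self, rng):
        root = random_dna(rng, 1200)
        mutated, snps, indels = mutate_sequence(
            root, rng, n_snps=5, n_indels=2,
            indel_length_weights=(0, 0, 1.0, 0, 0, 0, 1.0, 0, 0, 0),  # 3 and 7
            min_spacing=50,
        )
        aln = align_pair(root, mutated)
        called_snps, called_indels = call_polymorphisms(aln)
        assert len(called_snps) == 5
        assert sorted(i.length for i in called_indels) == sorted(
            i.length for i in indels
        )

    def test_indel_lengths_sum_to_stripped_columns(self, rng):
        from mtintrons.pairwise_align import strip_gap_columns

        root = random_dna(rng, 600)
        mutated, _, _ = mutate_sequence(root, rng, n_snps=3, n_indels=3,
                                        min_spacing=40)
        aln = align_pair(root, mutated)
        _, indels = call_polymorphisms(aln)
        _, removed = strip_gap_columns(aln)
        assert sum(i.length for i in indels) == removed


class TestDivergence:
    def test_identity_gives_zero(self):
        stats = divergence_between("ACGTACGTAC", "ACGTACGTAC")
        assert (stats.p, stats.K0, stats.I) == (0.0, 0.0, 0.0)

    def test_jc69_closed_form_on_constructed_pair(self, rng):
        # 1,000 gapless sites, exactly 30 substitutions -> p = 0.03
        root = random_dna(rng, 1000)
        mutated, snps, _ = mutate_sequence(root, rng, n_snps=30, n_indels=0,
                                           min_spacing=2, edge_buffer=1)
        assert len(snps) == 30
        aln = PairwiseAlignment("a", "b", root, mutated, 0.0)
        stats = compute_divergence(aln, "jc69")
        assert stats.p == pytest.approx(0.03)
        assert stats.K0 == pytest.approx(-0.75 * math.log(1 - 4 * 0.03 / 3))

    def test_k2p_on_known_proportions(self):
        # 100 sites: 4 transitions (A<->G), 2 transversions (A<->C)
        a = "A" * 100
        b = "G" * 4 + "C" * 2 + "A" * 94
        stats = compute_divergence(PairwiseAlignment("a", "b", a, b, 0.0), "k2p")
        P, Q = 0.04, 0.02
        expected = -0.5 * math.log((1 - 2 * P - Q) * math.sqrt(1 - 2 * Q))
        assert stats.K0 == pytest.approx(expected)

    def test_k0_at_least_p_and_monotone(self):
        ps = np.linspace(0.0, 0.6, 25)
        ks = [jc69(p) for p in ps]
        assert all(k >= p for p, k in zip(ps, ks))
        assert all(k2 > k1 for k1, k2 in zip(ks, ks[1:]))
        assert jc69(1e-6) == pytest.approx(1e-6, rel=1e-3)

    def test_jc69_saturation_error(self):
        with pytest.raises(ValueError):
            jc69(0.8)

    def test_n_columns_excluded_from_sites(self):
        aln = PairwiseAlignment("a", "b", "ANGTACGTAC", "ACGTACGTAC", 0.0)
        stats = compute_divergence(aln)
        assert stats.n_sites == 9

    def test_indels_per_site(self):
        a = "ACGTACGTAC----ACGTACGTACGTACGTACGTACGTAC"
        b = "ACGTACGTACTTTTACGTACGTACGTACGTACGTACGTAC"
        stats = compute_divergence(PairwiseAlignment("a", "b", a, b, 0.0))
        assert stats.n_indel_events == 1
        assert stats.I == pytest.approx(1 / 36)

    def test_large_insertion_called_as_single_event(self, rng):
        five = random_dna(rng, 632)
        three = random_dna(rng, 133)
        insert = random_dna(rng, 3353)
        aln = align_pair(five + three, five + insert + three)
        snps, indels = call_polymorphisms(aln)
        assert snps == []
        assert [i.length for i in indels] == [3353]
        stats = compute_divergence(aln)
        assert stats.K0 == 0.0
        assert stats.n_sites == 765


class TestGroupSummary:
    def test_single_pair_sd_zero(self):
        s = divergence_between("ACGTACGTAC", "ACGTACGTAC")
        summ = summarize_group([s], "g")
        assert summ.mean_K0 == 0.0 and summ.sd_K0 == 0.0

    def test_mean_sd_match_numpy_oracle(self, rng):
        stats = []
        for _ in range(7):
            root = random_dna(rng, 800)
            mutated, _, _ = mutate_sequence(
                root, rng, n_snps=int(rng.integers(0, 20)), n_indels=1,
                min_spacing=10, edge_buffer=5,
            )
            stats.append(divergence_between(root, mutated))
        summ = summarize_group(stats, "seven")
        k0 = np.array([s.K0 for s in stats])
        ii = np.array([s.I for s in stats])
        assert summ.mean_K0 == pytest.approx(k0.mean())
        assert summ.sd_K0 == pytest.approx(k0.std(ddof=1))
        assert summ.mean_I == pytest.approx(ii.mean())
        assert summ.sd_I == pytest.approx(ii.std(ddof=1))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            summarize_group([], "empty")


class TestDiscriminationTable:
    def test_identical_sequences_share_allele(self):
        seq = "ACGT" * 50
        calls = build_discrimination_table(
            [("e1", "locus", seq), ("e2", "locus", seq)]
        )
        assert [c.allele_index for c in calls] == [1, 1]
        assert all(c.distinguishing_features == () for c in calls)

    def test_alleles_numbered_by_decreasing_length(self):
        long = "ACGT" * 60
        short = "ACGT" * 55
        calls = build_discrimination_table(
            [("short_e", "L", short), ("long_e", "L", long)]
        )
        by_entry = {c.entry: c for c in calls}
        assert by_entry["long_e"].allele_index == 1
        assert by_entry["short_e"].allele_index == 2
        assert by_entry["long_e"].length == 240

    def test_planted_partition_recovered(self, rng):
        a1 = random_dna(rng, 900)
        a2_intron, _, _ = mutate_sequence(a1, rng, n_snps=0, n_indels=1)
        entries = [
            ("e1", "L", a1), ("e2", "L", a1),
            ("e3", "L", a2_intron), ("e4", "L", a2_intron),
        ]
        calls = build_discrimination_table(entries)
        groups = {}
        for c in calls:
            groups.setdefault(c.allele_index, set()).add(c.entry)
        assert sorted(map(sorted, groups.values())) in (
            [["e1", "e2"], ["e3", "e4"]],
            [["e3", "e4"], ["e1", "e2"]],
        )

    def test_gel_resolvability_threshold(self):
        long = "A" * 500 + "ACGTACGTACGT" + "C" * 500
        short = "A" * 500 + "C" * 500
        calls = build_discrimination_table(
            [("x", "L", long), ("y", "L", short)]
        )
        (pair,) = gel_resolvable_pairs(calls, gel_threshold=8)
        assert pair["length_diff"] == 12
        assert pair["gel_resolvable"] is True
        (pair,) = gel_resolvable_pairs(calls, gel_threshold=20)
        assert pair["gel_resolvable"] is False

    def test_single_entry_locus_rejected(self):
        with pytest.raises(ValueError):
            build_discrimination_table([("e1", "L", "ACGT" * 30)])
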