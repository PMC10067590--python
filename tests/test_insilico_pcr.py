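"""In-silico PCR: site finding vs a brute-force oracle, pairing, classes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mtintrons.io_formats import IUPAC_BITS, GenomeRecord, PrimerSet, Topology, reverse_complement
from mtintrons.insilico_pcr import (
    CallSummary,
    MatchClass,
    PcrConfig,
    Strand,
    classify_call,
    extract_amplicon_sequence,
    find_primer_sites,
    pair_amplicons,
    predict_amplicons,
    scan_genome_set,
)

# --------------------------------------------------------------------------
# Independent oracle: per-window IUPAC-aware Hamming scan in pure Python.


def oracle_sites(primer: str, genome: GenomeRecord, max_mm: int):
    """All (strand, start, mismatches) by direct window comparison."""
    n, m = len(genome), len(primer)
    template = genome.sequence
    if genome.topology is Topology.CIRCULAR:
        template = template + template[: m - 1]
    out = set()
    for strand, query in (("plus", primer), ("minus", reverse_complement(primer))):
        for i in range(len(template) - m + 1):
            if i >= n:
                continue
            mm = sum(
                (IUPAC_BITS[template[i + j]] & IUPAC_BITS[query[j]]) == 0
                for j in range(m)
            )
            if mm <= max_mm:
                out.add((strand, i, mm))
    return out


def as_set(hits):
    return {(h.strand.value, h.start, h.mismatches) for h in hits}


dna = st.text(alphabet="ACGT", min_size=30, max_size=200)
iupac_dna = st.text(alphabet="ACGTRYSWKMN", min_size=30, max_size=120)
primer = st.text(alphabet="ACGT", min_size=15, max_size=20)


class TestFindPrimerSites:
    def test_exact_hit_coordinates(self):
        g = GenomeRecord(id="g", sequence="TTACGTTT")
        hits = find_primer_sites("ACGT", g, max_mm=0)
        plus = [h for h in hits if h.strand is Strand.PLUS]
        assert [(h.start, h.end) for h in plus] == [(2, 6)]
        # ACGT is its own reverse complement: the same window is a minus hit
        assert as_set(hits) == {("plus", 2, 0), ("minus", 2, 0)}

    def test_primer_longer_than_genome(self):
        g = GenomeRecord(id="g", sequence="ACG")
        with pytest.raises(ValueError):
            find_primer_sites("ACGTACGT", g, max_mm=0)

    def test_circular_wrap_hit(self):
        g = GenomeRecord(id="g", sequence="GTTTTTAC", topology=Topology.CIRCULAR)
        hits = find_primer_sites("ACGT", g, max_mm=0)
        plus = [h for h in hits if h.strand is Strand.PLUS]
        assert [(h.start, h.end) for h in plus] == [(6, 10)]  # wraps origin

    def test_n_in_template_counts_as_match(self):
        g = GenomeRecord(id="g", sequence="TTANGTTT")
        hits = find_primer_sites("ACGT", g, max_mm=0)
        assert ("plus", 2, 0) in as_set(hits)

    @given(g=dna, p=primer, mm=st.integers(0, 3))
    @settings(max_examples=150)
    def test_matches_brute_force_oracle(self, g, p, mm):
        rec = GenomeRecord(id="g", sequence=g)
        assert as_set(find_primer_sites(p, rec, mm)) == oracle_sites(p, rec, mm)

    @given(g=iupac_dna, p=primer)
    @settings(max_examples=75)
    def test_matches_oracle_on_ambiguous_templates(self, g, p):
        rec = GenomeRecord(id="g", sequence=g)
        assert as_set(find_primer_sites(p, rec, 2)) == oracle_sites(p, rec, 2)

    @given(g=dna, p=primer, shift=st.integers(1, 100))
    @settings(max_examples=50)
    def test_rotation_preserves_circular_hit_count(self, g, p, shift):
        shift %= len(g)
        a = GenomeRecord(id="a", sequence=g, topology=Topology.CIRCULAR)
        b = GenomeRecord(id="b", sequence=g[shift:] + g[:shift],
                         topology=Topology.CIRCULAR)
        ha = find_primer_sites(p, a, 2)
        hb = find_primer_sites(p, b, 2)
        assert sorted(h.mismatches for h in ha) == sorted(h.mismatches for h in hb)

    def test_three_prime_mismatch_counting(self):
        # plant one mismatch at the primer's 3'-terminal base
        g = "T" * 10 + "ATCGGATCCTAGTTCGAAGC"[:-1] + "T" + "T" * 10
        primer_seq = "ATCGGATCCTAGTTCGAAGC"
        rec = GenomeRecord(id="g", sequence=g)
        hits = [h for h in find_primer_sites(primer_seq, rec, 2)
                if h.strand is Strand.PLUS and h.start == 10]
        assert hits and hits[0].mismatches == 1
        assert hits[0].three_prime_mismatches == 1


class TestPairingAndClassification:
    def _primer_set(self):
        return PrimerSet(locus="locusA",
                         forward="ATCGGATCCTAGTTCGAAGC",
                         reverse="CATGGTACGTTAGCCTGAAC")

    def _planted_genome(self, gap=1460):
        ps = self._primer_set()
        seq = ("T" * 100 + ps.forward + "A" * gap
               + reverse_complement(ps.reverse) + "T" * 100)
        return ps, GenomeRecord(id="g", sequence=seq)

    def test_planted_pair_length_and_class(self):
        ps, g = self._planted_genome(gap=1460)
        amps = predict_amplicons(ps, g, PcrConfig(max_mm=0))
        assert len(amps) == 1
        assert amps[0].length == 1460 + 40  # both primers included
        assert amps[0].match_class is MatchClass.PERFECT

    def test_no_reverse_hits_no_amplicons(self):
        ps = self._primer_set()
        g = GenomeRecord(id="g", sequence="T" * 50 + ps.forward + "T" * 50)
        assert predict_amplicons(ps, g, PcrConfig()) == []

    def test_length_equals_primers_plus_gap_always(self, rng):
        ps = self._primer_set()
        for gap in rng.integers(100, 3000, size=5):
            _, g = self._planted_genome(gap=int(gap))
            (amp,) = predict_amplicons(ps, g, PcrConfig(max_mm=0))
            assert amp.length == len(ps.forward) + int(gap) + len(ps.reverse)

    def test_reverse_complement_preserves_amplicons(self, rng):
        ps, g = self._planted_genome()
        rc = GenomeRecord(id="g", sequence=reverse_complement(g.sequence))
        a1 = predict_amplicons(ps, g, PcrConfig())
        a2 = predict_amplicons(ps, rc, PcrConfig())
        assert sorted(a.length for a in a1) == sorted(a.length for a in a2)
        assert sorted(a.match_class for a in a1) == sorted(a.match_class for a in a2)

    def test_circular_rotation_preserves_amplicon_set(self):
        ps, g = self._planted_genome(gap=500)
        seq = g.sequence
        for shift in (0, 173, 450, len(seq) - 37):
            rot = GenomeRecord(id="g", sequence=seq[shift:] + seq[:shift],
                               topology=Topology.CIRCULAR)
            amps = predict_amplicons(ps, rot, PcrConfig(max_mm=0))
            assert [a.length for a in amps] == [540]
            assert amps[0].match_class is MatchClass.PERFECT

    def test_size_window_filters(self):
        ps, g = self._planted_genome(gap=1460)
        assert predict_amplicons(ps, g, PcrConfig(max_len=1000)) == []
        assert predict_amplicons(ps, g, PcrConfig(min_len=2000)) == []

    def test_extract_amplicon_round_trip(self):
        ps, g = self._planted_genome(gap=300)
        (amp,) = predict_amplicons(ps, g, PcrConfig(max_mm=0))
        seq = extract_amplicon_sequence(g, amp)
        assert seq.startswith(ps.forward)
        assert seq.endswith(reverse_complement(ps.reverse))
        assert len(seq) == amp.length


class TestClassifyCall:
    def _amp(self, mm_f, mm_r, ps, genome):
        amps = predict_amplicons(ps, genome, PcrConfig(max_mm=5))
        return amps

    def test_summary_classes(self):
        ps = PrimerSet(locus="L", forward="ATCGGATCCTAGTTCGAAGC",
                       reverse="CATGGTACGTTAGCCTGAAC")
        perfect = ("T" * 60 + ps.forward + "A" * 500
                   + reverse_complement(ps.reverse) + "T" * 60)

        def mutate(site, k):
            flip = {"A": "C", "C": "A", "G": "T", "T": "G"}
            return "".join(flip[c] if i < k else c for i, c in enumerate(site))

        cases = [
            (0, CallSummary.SINGLE_PERFECT),
            (2, CallSummary.SINGLE_STRONG),
            (3, CallSummary.SINGLE_WEAK),   # the 3-mm case joins the weak class
            (4, CallSummary.SINGLE_WEAK),
        ]
        for k, expected in cases:
            seq = ("T" * 60 + mutate(ps.forward, k) + "A" * 500
                   + reverse_complement(ps.reverse) + "T" * 60)
            g = GenomeRecord(id="g", sequence=seq)
            call = classify_call(predict_amplicons(ps, g, PcrConfig(max_mm=5)),
                                 "L", "set")
            assert call.summary is expected, (k, call.summary)

        # two planted products -> multiple_targets
        g2 = GenomeRecord(id="g", sequence=perfect + "G" * 6100 + perfect)
        call = classify_call(predict_amplicons(ps, g2, PcrConfig(max_mm=5)),
                             "L", "set")
        assert call.summary is CallSummary.MULTIPLE_TARGETS
        assert len(call.amplicons) == 2

    def test_no_match(self):
        call = classify_call([], "L", "set")
        assert call.summary is CallSummary.NO_MATCH


class TestScanGenomeSet:
    def test_empty_set_rejected(self, bundled_primers):
        with pytest.raises(ValueError):
            scan_genome_set({"empty": []}, bundled_primers)

    def test_one_call_per_combination(self, bundled_primers):
        g = GenomeRecord(id="g", sequence="ACGT" * 300)
        calls = scan_genome_set({"s1": [g], "s2": [g]}, bundled_primers)
        assert len(calls) == 22  # 11 amplification sets x 2 genome sets
        assert all(c.summary is CallSummary.NO_MATCH for c in calls)

    def test_multi_record_sets_pool_hits(self):
        ps = PrimerSet(locus="L", forward="ATCGGATCCTAGTTCGAAGC",
                       reverse="CATGGTACGTTAGCCTGAAC")
        cassette = ("T" * 60 + ps.forward + "A" * 400
                    + reverse_complement(ps.reverse) + "T" * 60)
        r1 = GenomeRecord(id="c1", sequence=cassette)
        r2 = GenomeRecord(id="c2", sequence=cassette)
        calls = scan_genome_set({"set": [r1, r2]}, [ps])
        assert len(calls) == 1
        assert calls[0].summary is CallSummary.MULTIPLE_TARGETS
        assert {a.record_id for a in calls[0].amplicons} == {"c1", "c2"}
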