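import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import brute_scan
from ecrap1.io_formats import GenomicInterval
from ecrap1.motif_core import (
    AP1_MOTIF,
    ECRE_MOTIF,
    IupacMotif,
    count_in_region,
    match_at,
    reverse_complement,
    scan_sequence,
)
from ecrap1 import synthetic_data as sd

iupac_seq = st.text(alphabet="ACGTRYSWKMBDHVN", min_size=1, max_size=50)


class TestReverseComplement:
    @pytest.mark.parametrize(
        "seq,expected",
        [("TGANTCA", "TGANTCA"), ("ACGT", "ACGT"), ("AAAC", "GTTT"),
         ("RGGTCANTGACCY", "RGGTCANTGACCY")],
    )
    def test_known_values(self, seq, expected):
        assert reverse_complement(seq) == expected

    @settings(deadline=None)
    @given(iupac_seq)
    def test_involution(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq

    def test_invalid_character_rejected(self):
        with pytest.raises(ValueError):
            reverse_complement("ACGX")


class TestIupacMotif:
    def test_both_default_motifs_are_palindromic(self):
        assert AP1_MOTIF.is_palindromic()
        assert ECRE_MOTIF.is_palindromic()

    def test_non_palindromic_motif(self):
        assert not IupacMotif("m", "TGACTCAG").is_palindromic()

    def test_invalid_code_rejected(self):
        with pytest.raises(ValueError):
            IupacMotif("m", "TGAXTCA")


class TestMatchAt:
    @pytest.mark.parametrize(
        "seq,expected",
        [("TGAATCA", True), ("TGACTCA", True), ("TGANTCA", False),  # genome N never matches
         ("TGAATCG", False)],
    )
    def test_ap1_semantics(self, seq, expected):
        assert match_at(AP1_MOTIF, seq, 0) is expected

    def test_ecre_degenerate_positions(self):
        assert match_at(ECRE_MOTIF, "GGGTCAATGACCT", 0)
        assert not match_at(ECRE_MOTIF, "CGGTCAATGACCT", 0)  # R does not allow C

    def test_offset_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            match_at(AP1_MOTIF, "TGACTCA", 1)


class TestScanSequence:
    def test_single_exact_site(self):
        (hit,) = scan_sequence(AP1_MOTIF, "TGACTCA")
        assert (hit.interval.start, hit.interval.end, hit.strand) == (0, 7, "+")
        assert hit.matched_seq == "TGACTCA"

    def test_two_planted_sites_in_clean_background(self):
        hits = scan_sequence(AP1_MOTIF, "TGACTCAAATGATTCA")
        assert [h.interval.start for h in hits] == [0, 9]

    def test_motif_longer_than_sequence_yields_empty(self):
        assert scan_sequence(ECRE_MOTIF, "ACGT") == []

    def test_palindromic_span_reported_once(self):
        hits = scan_sequence(AP1_MOTIF, "TGACTCA")
        assert len(hits) == 1 and hits[0].strand == "+"

    def test_non_palindromic_strands_are_distinct_hits(self):
        motif = IupacMotif("m", "AAAAC")
        hits = scan_sequence(motif, "GTTTTAAAAC")
        assert [(h.interval.start, h.strand) for h in hits] == [(0, "-"), (5, "+")]
        assert all(h.matched_seq == ("GTTTT" if h.strand == "-" else "AAAAC")
                   for h in hits)

    def test_overlapping_occurrences_all_reported(self):
        motif = IupacMotif("m", "ANA")
        hits = scan_sequence(motif, "ACACA")
        assert [h.interval.start for h in hits] == [0, 2]

    def test_matches_bruteforce_on_random_sequences(self, rng):
        for motif in (AP1_MOTIF, ECRE_MOTIF, IupacMotif("asym", "TGASTC")):
            for _ in range(30):
                seq = "".join(rng.choice(list("ACGTN"), size=2_000, p=[0.24] * 4 + [0.04]))
                got = [(h.interval.start, h.strand) for h in scan_sequence(motif, seq)]
                assert got == brute_scan(motif, seq)

    def test_shift_equivariance(self, small_genome):
        genome, truth = small_genome
        seq = genome["chr1"]
        base = [(h.interval.start, h.strand) for h in scan_sequence(AP1_MOTIF, seq)]
        for k in (1, 13, 100):
            shifted = [(h.interval.start - k, h.strand)
                       for h in scan_sequence(AP1_MOTIF, "C" * k + seq)]
            assert shifted == base


class TestCountInRegion:
    def test_planted_count_recovered(self, small_genome):
        genome, truth = small_genome
        region = GenomicInterval("chr1", 0, 10_000)
        assert count_in_region(AP1_MOTIF, genome, region) == 3
        assert count_in_region(ECRE_MOTIF, genome, region) == 1

    def test_all_c_region_has_no_sites(self):
        from ecrap1.io_formats import GenomeSequence

        genome = GenomeSequence({"c": "C" * 100})
        assert count_in_region(AP1_MOTIF, genome, GenomicInterval("c", 0, 100)) == 0

    def test_straddling_site_not_counted(self, small_genome):
        genome, _ = small_genome
        # planted site spans [100, 107); cut through it
        assert count_in_region(AP1_MOTIF, genome, GenomicInterval("chr1", 0, 104)) == 0
        assert count_in_region(AP1_MOTIF, genome, GenomicInterval("chr1", 0, 107)) == 1

    def test_out_of_bounds_region_rejected(self, small_genome):
        genome, _ = small_genome
        with pytest.raises(ValueError):
            count_in_region(AP1_MOTIF, genome, GenomicInterval("chr1", 0, 20_000))

    def test_count_additivity_over_partition(self, small_genome):
        """Whole-region count = sum over parts + hits straddling the cuts."""
        genome, _ = small_genome
        whole = GenomicInterval("chr1", 0, 10_000)
        cuts = [0, 2_503, 7_000, 10_000]
        parts = [GenomicInterval("chr1", a, b) for a, b in zip(cuts, cuts[1:])]
        part_sum = sum(count_in_region(AP1_MOTIF, genome, p) for p in parts)
        all_hits = scan_sequence(AP1_MOTIF, genome["chr1"])
        straddlers = sum(
            any(h.interval.start < c < h.interval.end for c in cuts[1:-1])
            for h in all_hits
        )
        assert count_in_region(AP1_MOTIF, genome, whole) == part_sum + straddlers
        assert straddlers == 1  # the cut at 2503 bisects the site planted at 2500
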