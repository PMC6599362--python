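"""Peak calling, pairing DP vs brute-force oracle, partner search bounds."""

from __future__ import annotations

import numpy as np
import pytest

from plantmir import fixtures as fx
from plantmir.locus_discovery import call_peaks, find_duplex_partner, pairing_matrix
from plantmir.model import GenomeIndex, Peak, ReadAlignment, revcomp_dna


def read(start, end, count=1, strand="+", chrom="chr1"):
    return ReadAlignment(chrom, start, end, strand, "A" * (end - start), count)


class TestCallPeaks:
    def test_single_cluster_total(self, reference_locus):
        planted, hp, locus = reference_locus
        peaks = call_peaks(locus.reads)
        assert len(peaks) == 1
        assert peaks[0].total_count == 114

    def test_two_means_separates_background(self):
        reads = [read(100, 121, count=1000), read(5000, 5021, count=1)]
        peaks = call_peaks(reads)
        assert len(peaks) == 1
        assert peaks[0].total_count == 1000

    def test_floor_rescues_low_group(self):
        reads = [read(100, 121, count=1000), read(5000, 5021, count=27)]
        peaks = call_peaks(reads)
        assert {p.total_count for p in peaks} == {1000, 27}

    def test_no_reads(self):
        assert call_peaks([]) == []

    def test_equal_clusters_all_kept(self):
        reads = [read(i * 1000, i * 1000 + 21, count=3) for i in range(4)]
        assert len(call_peaks(reads)) == 4

    def test_peaks_non_overlapping_per_strand(self):
        rng = np.random.default_rng(11)
        reads = [
            read(int(s), int(s) + 21, count=int(c))
            for s, c in zip(rng.integers(0, 5000, 80), rng.integers(1, 40, 80))
        ]
        peaks = call_peaks(reads)
        peaks.sort(key=lambda p: p.start)
        for a, b in zip(peaks, peaks[1:]):
            assert a.end <= b.start


# ---------------------------------------------------------------------------
# pairing


def _pairs(x, y):
    return {x, y} in ({"C", "G"}, {"A", "U"}, {"G", "U"})


def oracle_pairing(a: str, b: str) -> int:
    """Exhaustive max-pairs alignment with <=2 bulges of <=2 nt, free ends."""
    rb = b[::-1]
    best = 0

    def rec(i, j, bulges, score):
        nonlocal best
        best = max(best, score)
        if i < len(a) and j < len(rb):
            rec(i + 1, j + 1, bulges, score + _pairs(a[i], rb[j]))
        if bulges < 2:
            for d in (1, 2):
                if i + d <= len(a):
                    rec(i + d, j, bulges + 1, score)
                if j + d <= len(rb):
                    rec(i, j + d, bulges + 1, score)

    for i0 in range(len(a)):
        rec(i0, 0, 0, 0)
    for j0 in range(len(rb)):
        rec(0, j0, 0, 0)
    return best


class TestPairingMatrix:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("GGGG", "CCCC", 4),  # perfect C-G complement
            ("GGGG", "AAAA", 0),  # no legal pair
            ("GUGU", "GUGU", 4),  # wobble both ways
            ("AAAA", "UUUU", 4),
            ("ACGU", "ACGU", 4),  # self-reverse-complementary
        ],
    )
    def test_known_values(self, a, b, expected):
        assert pairing_matrix(a, b) == expected

    def test_invalid_nucleotide(self):
        with pytest.raises(ValueError):
            pairing_matrix("ACGT", "ACGU")  # T is not RNA

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(3)
        nts = np.array(list("ACGU"))
        for _ in range(40):
            a = "".join(rng.choice(nts, size=int(rng.integers(4, 8))))
            b = "".join(rng.choice(nts, size=int(rng.integers(4, 8))))
            assert pairing_matrix(a, b) == oracle_pairing(a, b)

    def test_symmetry(self):
        rng = np.random.default_rng(4)
        nts = np.array(list("ACGU"))
        for _ in range(30):
            a = "".join(rng.choice(nts, size=21))
            b = "".join(rng.choice(nts, size=21))
            assert pairing_matrix(a, b) == pairing_matrix(b, a)


# ---------------------------------------------------------------------------
# partner search

PEAK_DNA = "GGCAGCTTGACCTGGAGGCTA"  # 21 nt, U-poor so poly-A background is inert


def _contig_with(insertions: dict[int, str], length: int = 2000) -> GenomeIndex:
    seq = ["A"] * length
    for pos, s in insertions.items():
        seq[pos : pos + len(s)] = list(s)
    return GenomeIndex({"chr1": "".join(seq)})


def _peak(start: int, length: int = 21) -> Peak:
    return Peak("chr1", "+", start, start + length, total_count=50, max_depth=50)


class TestFindDuplexPartner:
    def test_perfect_complement_downstream(self):
        genome = _contig_with({500: PEAK_DNA, 560: revcomp_dna(PEAK_DNA)})
        cand = find_duplex_partner(_peak(500), genome)
        assert cand is not None
        assert cand.partner_offset == 60
        assert cand.pairing_score == len(PEAK_DNA)
        assert cand.start <= 500 and cand.end >= 521  # contains the peak

    def test_poly_a_has_no_partner(self):
        genome = GenomeIndex({"chr1": "A" * 2000})
        assert find_duplex_partner(_peak(500), genome) is None

    def test_complement_beyond_search_radius(self):
        peak = _peak(500)
        genome = _contig_with({peak.end + 351: revcomp_dna(PEAK_DNA)})
        assert find_duplex_partner(peak, genome) is None

    def test_complement_at_radius_edge_found(self):
        peak = _peak(500)
        pos = peak.end + 350 - len(PEAK_DNA)  # window flush with the boundary
        genome = _contig_with({500: PEAK_DNA, pos: revcomp_dna(PEAK_DNA)})
        cand = find_duplex_partner(peak, genome)
        assert cand is not None and cand.pairing_score == len(PEAK_DNA)

    def test_contig_edge_clips_without_error(self):
        genome = _contig_with({10: PEAK_DNA, 200: revcomp_dna(PEAK_DNA)}, length=400)
        cand = find_duplex_partner(_peak(10), genome)
        assert cand is not None

    def test_long_peak_uses_summit_query(self, reference_locus):
        """A merged guide+passenger cloud still finds its opposite arm."""
        planted, hp, locus = reference_locus
        genome, _ = fx.make_genome(
            [fx.make_reference_locus(position=1000)], length=4000, seed=5
        )
        (peak,) = call_peaks(locus.reads)
        assert peak.end - peak.start > 25  # whole-hairpin peak
        cand = find_duplex_partner(peak, genome, reads=locus.reads)
        assert cand is not None
        assert cand.pairing_score >= 14
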