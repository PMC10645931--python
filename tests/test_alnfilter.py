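"""Alignment filters, duplicate marking, mappability mask, contamination."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chexseq import alnfilter
from chexseq.alnfilter import (
    AlignmentRecord,
    FilterThresholds,
    ToyAligner,
    build_mappability_mask,
    filter_alignment,
    in_blacklist,
    is_contaminant,
    load_blacklist,
    mark_duplicates,
)


def rec(**kw):
    base = dict(
        read_id="r1", chrom="chr1", start=100, end=150, strand="+",
        aligner_score=50.0, read_length=50, mapped_length=50,
        matched_bases=50, mismatches=0, non_overlapping_mapped_length=50,
        is_primary=True,
    )
    base.update(kw)
    return AlignmentRecord(**base)


class TestFilter:
    def test_short_mapping_fails_first(self):
        ok, reason = filter_alignment(rec(mapped_length=9))
        assert not ok and reason == "min_mapped_length"

    def test_all_five_inequalities_pass(self):
        # score/len = matched/len = 0.5 >= 0.4; 2/25 = 0.08 <= 0.1
        r = rec(read_length=50, aligner_score=25, matched_bases=25,
                mismatches=2, mapped_length=25, non_overlapping_mapped_length=25)
        assert filter_alignment(r) == (True, None)

    def test_mismatch_rate_boundary(self):
        assert filter_alignment(rec(mismatches=5, mapped_length=50))[0]  # 0.1 inclusive
        ok, reason = filter_alignment(rec(mismatches=6, mapped_length=50))
        assert not ok and reason == "mismatch_rate"

    def test_secondary_and_duplicate_rejected(self):
        assert filter_alignment(rec(is_primary=False)) == (False, "secondary")
        assert filter_alignment(rec(is_duplicate=True)) == (False, "duplicate")

    def test_missing_field_skipped(self):
        ok, reason = filter_alignment(rec(mapped_length=None))
        assert not ok and reason == "missing_field"

    @given(
        score=st.integers(0, 75), matched=st.integers(0, 75),
        mism=st.integers(0, 20), mapped=st.integers(20, 75),
        nonov=st.integers(0, 75),
    )
    @settings(max_examples=200, derandomize=True)
    def test_pass_fail_is_order_independent(self, score, matched, mism, mapped, nonov):
        """The verdict equals the conjunction of independent criteria."""
        mism = min(mism, mapped)
        matched = max(matched, mapped - mism) if matched > mapped else matched
        r = rec(read_length=75, aligner_score=score, matched_bases=min(matched, 75),
                mismatches=mism, mapped_length=mapped,
                non_overlapping_mapped_length=nonov)
        t = FilterThresholds()
        expected = (
            mapped >= t.min_mapped_length
            and score / 75 >= t.min_score_norm
            and min(matched, 75) / 75 >= t.min_matched_norm
            and mism / mapped <= t.max_mismatch_rate
            and nonov >= t.min_non_overlapping
        )
        assert filter_alignment(r, t)[0] == expected


class TestDuplicates:
    def test_best_score_kept(self):
        a = rec(read_id="a", aligner_score=30)
        b = rec(read_id="b", aligner_score=25)
        mark_duplicates([a, b])
        assert not a.is_duplicate and b.is_duplicate

    def test_singleton_not_flagged(self):
        a = rec(read_id="a")
        mark_duplicates([a])
        assert not a.is_duplicate

    def test_tie_chain_score_then_length_then_id(self):
        # equal scores; mapped lengths 40/40/35: a 40 with the smaller id wins
        a = rec(read_id="z", aligner_score=30, mapped_length=40)
        b = rec(read_id="a", aligner_score=30, mapped_length=40)
        c = rec(read_id="m", aligner_score=30, mapped_length=35)
        mark_duplicates([a, b, c])
        assert not b.is_duplicate and a.is_duplicate and c.is_duplicate

    def test_different_positions_not_duplicates(self):
        a = rec(read_id="a", start=100, end=150)
        b = rec(read_id="b", start=120, end=170)
        mark_duplicates([a, b])
        assert not a.is_duplicate and not b.is_duplicate

    def test_minus_strand_keys_on_end(self):
        # same interval, opposite strands -> different 5' ends -> no dup
        a = rec(read_id="a", strand="+")
        b = rec(read_id="b", strand="-")
        mark_duplicates([a, b])
        assert not a.is_duplicate and not b.is_duplicate


class TestContaminant:
    @pytest.mark.parametrize(
        "target,alt,expected", [(30, 35, True), (30, 30, False), (30, None, False)]
    )
    def test_strict_comparison(self, target, alt, expected):
        assert is_contaminant(target, alt) is expected


class TestMappability:
    def test_duplicated_segment_masked_exactly(self, rng):
        """Oracle: exhaustive string search reproduces the masked-bin set."""
        bases = np.array(list("ACGT"))
        seg = "".join(bases[rng.integers(0, 4, 100)])
        chr_a = "".join(bases[rng.integers(0, 4, 150)]) + seg + "".join(bases[rng.integers(0, 4, 150)])
        chr_b = "".join(bases[rng.integers(0, 4, 100)]) + seg + "".join(bases[rng.integers(0, 4, 100)])
        sequences = {"chrA": chr_a, "chrB": chr_b}
        mask = build_mappability_mask(sequences, read_length=20, stride=1)

        # independent oracle: plain text scan for every 20-mer occurrence
        def occurrences(needle):
            out = []
            for chrom, seq in sequences.items():
                for probe in (needle, needle.translate(str.maketrans("ACGT", "TGCA"))[::-1]):
                    i = seq.find(probe)
                    while i >= 0:
                        out.append((chrom, i))
                        i = seq.find(probe, i + 1)
            return out

        expected = set()
        for chrom, seq in sequences.items():
            for pos in range(len(seq) - 19):
                hits = occurrences(seq[pos : pos + 20])
                if any(c != chrom or abs(p - pos) > 10 for c, p in hits):
                    expected.add((chrom, pos // 20))
        assert mask.masked == expected
        assert expected  # the duplication must actually trigger masking

    def test_near_repeat_within_offset_not_masked(self, rng):
        # a 25 bp period-5 repeat: its 20-mers also match 5 bp away (<= 10)
        bases = np.array(list("ACGT"))
        left = "".join(bases[rng.integers(0, 4, 120)])
        right = "".join(bases[rng.integers(0, 4, 120)])
        seq = left + "ACGTG" * 5 + right
        mask = build_mappability_mask({"chr1": seq}, read_length=20, stride=1)
        repeat_bins = {(len(left) + i) // 20 for i in range(6)}
        assert not any(("chr1", b) in mask.masked for b in repeat_bins)

    def test_unique_genome_unmasked(self, rng):
        bases = np.array(list("ACGT"))
        seq = "".join(bases[rng.integers(0, 4, 500)])
        mask = build_mappability_mask({"chr1": seq}, stride=1)
        assert mask.masked == set()


class TestToyAligner:
    def test_exact_hit_both_strands(self):
        genome = {"chr1": "AAAACCCCGGGGTTTTACGTACGTAAACCCGGGTTTACAGATTACA"}
        aligner = ToyAligner(genome, seed_k=8)
        hits = aligner.align("ACGTACGTAAACCCGGG")
        assert [(h.chrom, h.start, h.strand) for h in hits] == [("chr1", 16, "+")]
        rc = "GGGTTTACAGATTACA"[::-1].translate(str.maketrans("ACGT", "TGCA"))
        rc_hits = aligner.align(rc)
        assert [(h.start, h.strand) for h in rc_hits] == [(30, "-")]

    def test_unmapped_returns_none(self):
        aligner = ToyAligner({"chr1": "ACGT" * 30})
        assert aligner.align_record("r", "TTTTTTTTTTTTTTGCGCGA") is None


def test_blacklist_lookup():
    bl = load_blacklist([("chr1", 100, 200), ("chr1", 500, 600), ("chr2", 0, 50)])
    assert in_blacklist("chr1", 150, bl)
    assert in_blacklist("chr1", 100, bl) and not in_blacklist("chr1", 200, bl)
    assert not in_blacklist("chr1", 300, bl)
    assert not in_blacklist("chr3", 10, bl)
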