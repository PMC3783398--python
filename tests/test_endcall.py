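"""End-frequency profiles, modal/consensus calling, GC and strand ratio."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enhancerscope import pipeline, presets, simulate
from enhancerscope.endcall import (
    EndProfile,
    consensus_transcript,
    end_frequency_profile,
    gc_content,
    modal_end,
    strand_ratio,
)
from enhancerscope.mapper import AlignmentHit


def _hit(start, end, strand="+", rid="r", fraction=1.0):
    return AlignmentHit(rid, "ref", start, end, strand, 10.0, 1.0, fraction)


class TestEndFrequencyProfile:
    def test_single_read_is_hundred_percent(self):
        profile = end_frequency_profile([_hit(501, 560)], "five_prime", "+")
        assert profile.percent == {501: 100.0}

    def test_three_prime_tally(self):
        hits = [_hit(700, 800, rid=f"a{i}") for i in range(3)] + [_hit(700, 802, rid="b")]
        profile = end_frequency_profile(hits, "three_prime", "+")
        assert profile.percent == {800: 75.0, 802: 25.0}

    def test_sense_minus_uses_mirrored_terminus(self):
        hits = [_hit(700, 800, strand="-")]
        profile = end_frequency_profile(hits, "five_prime", "-")
        assert profile.counts == {800: 1}

    def test_low_aligned_fraction_excluded(self):
        hits = [_hit(700, 800), _hit(700, 805, rid="clip", fraction=0.5)]
        profile = end_frequency_profile(hits, "three_prime", "+", min_aligned_fraction=0.9)
        assert profile.counts == {800: 1}

    def test_class_mismatch_raises(self):
        with pytest.raises(ValueError, match="product"):
            end_frequency_profile(
                [_hit(1, 50, rid="x")], "five_prime", "+",
                product_classes={"x": "three_prime"},
            )

    @settings(derandomize=True, max_examples=50)
    @given(counts=st.dictionaries(
        st.integers(min_value=1, max_value=10_000),
        st.integers(min_value=1, max_value=1_000),
        min_size=1, max_size=20,
    ))
    def test_percentages_sum_to_hundred(self, counts):
        profile = EndProfile("s", "five_prime", counts)
        assert math.isclose(sum(profile.percent.values()), 100.0, abs_tol=1e-6)


class TestModalEnd:
    def test_single_position(self):
        m = modal_end(EndProfile("s", "five_prime", {501: 7}))
        assert (m.position, m.percent, m.tie) == (501, 100.0, False)

    def test_tie_breaks_outward_for_five_prime(self):
        m = modal_end(EndProfile("s", "five_prime", {700: 5, 703: 5}))
        assert (m.position, m.tie) == (700, True)

    def test_tie_breaks_outward_for_three_prime(self):
        m = modal_end(EndProfile("s", "three_prime", {700: 5, 703: 5}))
        assert (m.position, m.tie) == (703, True)

    def test_tie_on_minus_sense_mirrors(self):
        m = modal_end(EndProfile("s", "five_prime", {700: 5, 703: 5}, sense_strand="-"))
        assert m.position == 703

    def test_plain_maximum(self):
        assert modal_end(EndProfile("s", "five_prime", {700: 5, 703: 6})).position == 703

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            modal_end(EndProfile("s", "five_prime", {}))


class TestGcContent:
    @pytest.mark.parametrize(
        "seq,expected",
        [("ATAT", 0.0), ("GCGC", 1.0), ("ATGCN", 0.5), ("atgc", 0.5)],
    )
    def test_examples(self, seq, expected):
        assert gc_content(seq) == pytest.approx(expected)

    def test_empty_and_all_n_rejected(self):
        with pytest.raises(ValueError):
            gc_content("")
        with pytest.raises(ValueError):
            gc_content("NNNN")


class TestConsensusTranscript:
    def test_inclusive_arithmetic(self):
        p5 = EndProfile("s", "five_prime", {1000: 10})
        p3 = EndProfile("s", "three_prime", {1185: 10})
        ref = "ATGC" * 300
        call = consensus_transcript(p5, p3, ref, tss=1, sense_strand="+")
        assert (call.start, call.end, call.length) == (1000, 1185, 186)
        assert call.gc_fraction == pytest.approx(0.5)

    def test_wrong_order_raises_with_positions(self):
        p5 = EndProfile("s", "five_prime", {1185: 1})
        p3 = EndProfile("s", "three_prime", {1186: 5, 1000: 5})
        # tie in p3 breaks outward to 1186, still fine; force inversion:
        p3_bad = EndProfile("s", "three_prime", {1100: 5})
        with pytest.raises(ValueError, match="1185.*1100"):
            consensus_transcript(p5, p3_bad, "A" * 2000, tss=1, sense_strand="+")

    def test_tss_relative_coordinates_filled(self, hmle_locus):
        tss = hmle_locus.tss_position
        p5 = EndProfile("s", "five_prime", {hmle_locus.genomic(-5185): 3})
        p3 = EndProfile("s", "three_prime", {hmle_locus.genomic(-5000): 3})
        call = consensus_transcript(p5, p3, "GC" * 6000, tss, "+")
        assert (call.tss_relative_start, call.tss_relative_end) == (-5185, -5000)


class TestStrandRatio:
    def test_fivefold(self):
        assert strand_ratio(500, 100) == (5.0, False)

    def test_equal_counts(self):
        assert strand_ratio(42, 42) == (1.0, False)

    def test_zero_against_zero_with_pseudocount(self):
        assert strand_ratio(0, 0, pseudocount=1) == (1.0, False)

    def test_zero_antisense_flagged_infinite(self):
        ratio, infinite = strand_ratio(10, 0)
        assert math.isinf(ratio) and infinite


class TestMirrorSymmetry:
    def test_consensus_invariant_under_locus_reverse_complement(self):
        """Mapping + end calling on a reverse-complemented locus gives the
        mirrored interval with identical length."""
        length = presets.REFERENCE_LENGTH
        fwd_locus = presets.hmle_like_locus()
        rev_locus = presets.hmle_like_locus()
        rev_locus.tss_position = length - fwd_locus.tss_position + 1
        rev_locus.strand = "-"
        rev_locus.erna_sense_strand = "-"
        fwd_ref = simulate.make_reference(length, 0.5, fwd_locus, seed=21)
        from Bio.Seq import reverse_complement

        rev_ref = simulate.ReferenceAssembly(
            "minigenome", reverse_complement(fwd_ref.sequence), rev_locus
        )
        calls = []
        for ref in (fwd_ref, rev_ref):
            cfg = presets.default_read_config(
                n_reads=400, substitution_error_rate=0.0, seed=33, off_target_fraction=0.0
            )
            reads, _ = simulate.simulate_race_reads(ref, ref.locus, cfg)
            manifest = presets.make_manifest(ref)
            products, _ = pipeline.process_reads(reads, manifest)
            hits, classes, _ = pipeline.map_products(products, ref.sequence, ref.name)
            _, consensus, _ = pipeline.call_ends(hits, classes, ref)
            calls.append(consensus)
        fwd, rev = calls
        assert fwd.length == rev.length == 186
        assert (rev.tss_relative_start, rev.tss_relative_end) == (
            fwd.tss_relative_start,
            fwd.tss_relative_end,
        )
        # mirrored genomic interval
        assert rev.start == length - fwd.end + 1
        assert rev.end == length - fwd.start + 1
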