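"""Demultiplexing, trimming and product classification."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enhancerscope import raceio
from enhancerscope.raceio import (
    BarcodeManifest,
    ManifestRow,
    SequencingRead,
    classify_race_product,
    demultiplex,
    length_filter,
    trim_adapter,
    trim_homopolymer_tail,
)


def _read(bases, rid="r1"):
    return SequencingRead(rid, bases, "?" * len(bases))


@pytest.fixture()
def two_barcode_manifest():
    return BarcodeManifest(
        [
            ManifestRow("a", "ACGT", "GATTACAGATTACA", "CCGGTTAACCGGTT"),
            ManifestRow("b", "TGCA", "GATTACAGATTACA", "CCGGTTAACCGGTT"),
        ]
    )


class TestDemultiplex:
    def test_four_sample_pool_gives_four_bins_plus_unassigned(self, manifest, clean_read_pool):
        reads, truth = clean_read_pool
        bins, unassigned, summary = demultiplex(reads, manifest, max_mismatch=0)
        assert set(bins) == set(manifest.samples)
        assert len(bins) == 4
        assert set(summary["bin"]) == set(manifest.samples) | {"unassigned"}
        # error-free pool: every read lands in its truth bin
        expected = truth.groupby("sample").size()
        for sample in manifest.samples:
            assert len(bins[sample]) == expected.get(sample, 0)
        assert not unassigned

    def test_exact_match_removes_prefix(self, two_barcode_manifest):
        bins, _, _ = demultiplex([_read("ACGTTTTTGGGG")], two_barcode_manifest, 0)
        assert bins["a"][0].bases == "TTTTGGGG"

    def test_hamming_assignment_and_rejection(self, two_barcode_manifest):
        # AGGT: distance 1 to ACGT, 3 to TGCA -> sample a
        bins, unassigned, _ = demultiplex(
            [_read("AGGTCCCC", "x"), _read("AAAACCCC", "y")], two_barcode_manifest, 1
        )
        assert [r.id for r in bins["a"]] == ["x"]
        assert [r.id for r in unassigned] == ["y"]

    def test_tie_goes_unassigned(self):
        manifest = BarcodeManifest(
            [ManifestRow("a", "AAAA", "G" * 12, "C" * 12),
             ManifestRow("b", "TTTT", "G" * 12, "C" * 12)]
        )
        # distance 2 to both barcodes
        _, unassigned, _ = demultiplex([_read("AATTGGGG")], manifest, 2)
        assert len(unassigned) == 1

    def test_partition_property(self, manifest, clean_read_pool):
        reads, _ = clean_read_pool
        bins, unassigned, summary = demultiplex(reads, manifest, 1)
        total = sum(len(v) for v in bins.values()) + len(unassigned)
        assert total == len(reads)
        assert summary["count"].sum() == len(reads)
        ids = [r.id for v in bins.values() for r in v] + [r.id for r in unassigned]
        assert len(ids) == len(set(ids))

    def test_duplicate_barcodes_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            BarcodeManifest(
                [ManifestRow("a", "ACGT", "G" * 12, "C" * 12),
                 ManifestRow("b", "ACGT", "G" * 12, "C" * 12)]
            )

    def test_empty_manifest_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            BarcodeManifest([])


class TestTrimAdapter:
    ADAPTER = "ACGTACGTACGTACGTAC"  # 18 bases

    def test_full_adapter_removed_from_left(self):
        bases, removed = trim_adapter(self.ADAPTER + "GGGGTTTT", self.ADAPTER, "left")
        assert (bases, removed) == ("GGGGTTTT", 18)

    def test_absent_adapter_is_noop(self):
        bases, removed = trim_adapter("GGGGTTTTCCCC", self.ADAPTER, "left")
        assert (bases, removed) == ("GGGGTTTTCCCC", 0)

    def test_partial_right_overlap(self):
        # insert followed by the first 6 bases of the adapter
        read = "GGGGTTTTCCCC" + self.ADAPTER[:6]
        bases, removed = trim_adapter(read, self.ADAPTER, "right", min_overlap=5, max_error_rate=0.1)
        assert (bases, removed) == ("GGGGTTTTCCCC", 6)

    def test_tolerates_error_within_budget(self):
        mutated = "T" + self.ADAPTER[1:]  # 1 mismatch over 18 (5.6% <= 10%)
        bases, removed = trim_adapter(mutated + "GGGG", self.ADAPTER, "left")
        assert (bases, removed) == ("GGGG", 18)

    @settings(derandomize=True, max_examples=100)
    @given(insert=st.text(alphabet="ACGT", min_size=1, max_size=40))
    def test_never_lengthens_and_removes_prepended_adapter(self, insert):
        bases, removed = trim_adapter(self.ADAPTER + insert, self.ADAPTER, "left")
        assert len(bases) <= len(self.ADAPTER + insert)
        assert removed >= 18  # at least the full adapter goes


class TestTrimHomopolymerTail:
    def test_left_run_with_scan(self):
        assert trim_homopolymer_tail("CCCCCCATGA", "C", "left", min_run=5) == ("ATGA", 6)

    def test_short_run_untouched(self):
        assert trim_homopolymer_tail("CCCATGA", "C", "left", min_run=5) == ("CCCATGA", 0)

    def test_full_trim_to_empty(self):
        assert trim_homopolymer_tail("CCCC", "C", "left", min_run=4) == ("", 4)

    def test_right_end_with_interruption(self):
        bases, removed = trim_homopolymer_tail(
            "ATGAAAAAGAAAA", "A", "right", min_run=5, max_interruptions=1
        )
        assert (bases, removed) == ("ATG", 10)

    def test_interruption_budget_respected(self):
        # run beyond the interruption stops extension
        bases, removed = trim_homopolymer_tail(
            "AAAAGTTTTT", "T", "right", min_run=5, max_interruptions=0
        )
        assert (bases, removed) == ("AAAAG", 5)

    def test_trimming_is_idempotent(self):
        once, _ = trim_homopolymer_tail("ATGCCCCCCC", "C", "right", min_run=5)
        twice, removed = trim_homopolymer_tail(once, "C", "right", min_run=5)
        assert (twice, removed) == (once, 0)


class TestClassify:
    ROW = ManifestRow("s", "ACGT", "GATTACAGATTACAGGCCAT", "TTCCGGAATTCCGGAACGTA")

    def test_exact_five_prime_primer(self):
        assert classify_race_product("AAAA" + self.ROW.gsp_5prime + "CCCC", self.ROW) == "five_prime"

    def test_reverse_complement_also_matches(self):
        from Bio.Seq import reverse_complement

        read = "AAAA" + reverse_complement(self.ROW.gsp_3prime) + "CCCC"
        assert classify_race_product(read, self.ROW) == "three_prime"

    def test_neither_primer_unclassified(self):
        assert classify_race_product("AAAATTTTGGGGCCCCAAAATTTT", self.ROW) == "unclassified"

    def test_one_mismatch_over_twenty_qualifies(self):
        mutated = "A" + self.ROW.gsp_3prime[1:]  # 1/20 = 5% <= 10%
        read = "GGGG" + mutated + "AAAA"
        assert classify_race_product(read, self.ROW, max_error_rate=0.1) == "three_prime"


class TestLengthFilter:
    def test_examples(self):
        prods = [
            raceio.RaceProduct(f"r{i}", "s", "five_prime", "A" * n)
            for i, n in enumerate([10, 20, 30])
        ]
        kept, dropped = length_filter(prods, 20)
        assert [len(p.trimmed_bases) for p in kept] == [20, 30] and dropped == 1
        assert length_filter(prods, 0) == (prods, 0)
        assert length_filter([], 5) == ([], 0)


class TestFastqRoundTrip:
    def test_write_then_read(self, tmp_path, clean_read_pool):
        reads, _ = clean_read_pool
        path = tmp_path / "pool.fastq"
        raceio.write_fastq(reads[:50], path)
        back = list(raceio.read_fastq(path))
        assert [(r.id, r.bases, r.quals) for r in back] == [
            (r.id, r.bases, r.quals) for r in reads[:50]
        ]
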