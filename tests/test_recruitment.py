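"""Reference filtering, the seed-and-extend aligner, alignment import
and coverage computation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phagetrace.recruitment import (
    AlignmentHit,
    RecruitmentParams,
    align_reads,
    compute_coverage,
    filter_references,
    import_alignments,
)

from conftest import mutate, random_seq, revcomp


class TestFilterReferences:
    def test_strictly_longer_than_threshold(self):
        seqs = {f"c{i}": "A" * n for i, n in enumerate([4999, 5000, 5001])}
        kept = filter_references(seqs, 5000)
        assert list(kept) == ["c2"]

    def test_zero_threshold_keeps_all_in_order(self):
        seqs = {"b": "AC", "a": "GT"}
        assert list(filter_references(seqs, 0)) == ["b", "a"]

    def test_empty_input(self):
        assert filter_references({}, 5000) == {}


class TestAlignReads:
    def test_exact_slice_gives_perfect_hit(self, reference_20kb, reference_index):
        read = reference_20kb["contigA"][5000:5150]
        (hit,) = align_reads([("r1", read)], reference_20kb, molecule="DNA",
                             index=reference_index)
        assert hit.percent_identity == 100.0
        assert hit.aligned_length == 150
        assert (hit.ref_start, hit.ref_end, hit.strand) == (5000, 5150, "+")

    def test_ten_substitutions_over_200_bp_is_95_percent(self, reference_20kb, reference_index):
        ref = reference_20kb["contigA"]
        read = list(ref[8000:8200])
        for p in range(10, 200, 20):  # interior positions, flanked by matches
            read[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[p]]
        (hit,) = align_reads([("r", "".join(read))], reference_20kb, molecule="DNA",
                             index=reference_index)
        assert hit.percent_identity == pytest.approx(95.0)
        assert hit.aligned_length == 200

    def test_reverse_complement_recovers_same_locus(self, reference_20kb, reference_index):
        read = revcomp(reference_20kb["contigA"][3000:3200])
        (hit,) = align_reads([("r", read)], reference_20kb, molecule="DNA",
                             index=reference_index)
        assert hit.strand == "-"
        assert (hit.ref_start, hit.ref_end) == (3000, 3200)

    def test_unrelated_read_has_no_hit(self, reference_20kb, reference_index):
        rng = np.random.default_rng(5)
        reads = [(f"n{i}", random_seq(rng, 150)) for i in range(50)]
        hits = align_reads(reads, reference_20kb, molecule="DNA", index=reference_index)
        assert hits == []

    def test_short_reads_skipped(self, reference_20kb, reference_index):
        hits = align_reads([("tiny", "ACGTACGT")], reference_20kb, molecule="DNA",
                           index=reference_index)
        assert hits == []

    def test_rna_length_filter_stricter_than_dna(self, reference_20kb, reference_index):
        read = reference_20kb["contigA"][100:250]  # 150 bp
        assert align_reads([("r", read)], reference_20kb, molecule="DNA",
                           index=reference_index)
        assert not align_reads([("r", read)], reference_20kb, molecule="RNA",
                               index=reference_index)

    def test_filter_monotonicity(self, reference_20kb, reference_index):
        rng = np.random.default_rng(11)
        ref = reference_20kb["contigA"]
        reads = []
        for i in range(120):
            st_ = int(rng.integers(0, 19700))
            ln = int(rng.integers(100, 260))
            d = float(rng.uniform(0, 0.2))
            reads.append((f"r{i}", mutate(ref[st_:st_ + ln], int(d * ln), rng)))
        counts = []
        for min_len, min_id in [(100, 70.0), (150, 70.0), (150, 90.0), (200, 95.0)]:
            p = RecruitmentParams(min_hit_len_dna=min_len, min_identity=min_id)
            counts.append(len(align_reads(reads, reference_20kb, p, "DNA",
                                          index=reference_index)))
        assert counts == sorted(counts, reverse=True)

    def test_empty_reference_set_is_an_error(self):
        with pytest.raises(ValueError):
            align_reads([("r", "ACGT" * 50)], {})


class TestImportAlignments:
    def test_tabular_reverse_strand_coordinates(self, tmp_path):
        line = "read1\tctg\t97.50\t200\t5\t0\t1\t200\t900\t701\t1e-50\t350.0\n"
        p = tmp_path / "hits.tsv"
        p.write_text(line)
        (hit,) = import_alignments(p, "tabular")
        assert hit.strand == "-"
        assert (hit.ref_start, hit.ref_end) == (700, 900)
        assert hit.percent_identity == 97.5

    def test_tabular_forward_strand(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("r\tctg\t100.00\t100\t0\t0\t1\t100\t11\t110\t0\t200\n")
        (hit,) = import_alignments(p, "tabular")
        assert (hit.ref_start, hit.ref_end, hit.strand) == (10, 110, "+")

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("")
        assert import_alignments(p, "tabular") == []

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("only\tthree\tcols\n")
        with pytest.raises(ValueError, match=":1"):
            import_alignments(p, "tabular")

    def test_sam_identity_recomputed_and_unmapped_skipped(self, tmp_path):
        sam = (
            "@HD\tVN:1.6\n"
            "@SQ\tSN:ctg\tLN:1000\n"
            "r1\t0\tctg\t101\t60\t100M\t*\t0\t0\t" + "A" * 100 + "\t*\tNM:i:5\n"
            "r2\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\t*\n"
        )
        p = tmp_path / "a.sam"
        p.write_text(sam)
        hits = import_alignments(p, "sam")
        assert len(hits) == 1
        assert hits[0].percent_identity == pytest.approx(95.0)
        assert (hits[0].ref_start, hits[0].ref_end) == (100, 200)


class TestCoverage:
    def test_interval_arithmetic(self):
        hits = [
            AlignmentHit("a", "c", 0, 100, 100, 100.0, 100, "+"),
            AlignmentHit("b", "c", 50, 150, 100, 100.0, 100, "+"),
        ]
        prof = compute_coverage(hits, "c", 200)
        assert (prof.depth[:50] == 1).all()
        assert (prof.depth[50:100] == 2).all()
        assert (prof.depth[100:150] == 1).all()
        assert (prof.depth[150:] == 0).all()

    def test_no_hits_all_zero(self):
        assert (compute_coverage([], "c", 50).depth == 0).all()

    def test_full_span_uniform_one(self):
        h = AlignmentHit("a", "c", 0, 80, 80, 100.0, 80, "+")
        assert (compute_coverage([h], "c", 80).depth == 1).all()

    def test_out_of_bounds_hit_raises(self):
        h = AlignmentHit("a", "c", 190, 220, 30, 100.0, 30, "+")
        with pytest.raises(ValueError):
            compute_coverage([h], "c", 200)

    @given(st.lists(st.tuples(st.integers(0, 180), st.integers(1, 120)), max_size=20))
    def test_depth_sum_equals_total_aligned_span(self, intervals):
        hits = []
        for i, (s, ln) in enumerate(intervals):
            e = min(s + ln, 300)
            hits.append(AlignmentHit(f"r{i}", "c", s, e, e - s, 100.0, 1, "+"))
        prof = compute_coverage(hits, "c", 300)
        assert prof.depth.sum() == sum(h.ref_end - h.ref_start for h in hits)
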