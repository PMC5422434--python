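"""Transcript classification: filters, boundaries, loci, demographics,
and the full pipeline against planted truth."""

import pytest
from Bio.Seq import Seq

from linckit.core_io import (
    AnnotationSet,
    Config,
    GenomicInterval,
    TranscriptModel,
)
from linckit.identify import (
    LincRNARecord,
    LncClass,
    annotate_tss,
    assess_coding,
    classify_overlap,
    demographics,
    filter_by_length,
    filter_te,
    find_longest_orf,
    group_into_loci,
    reconcile_known_lincRNAs,
    run_identify,
)

SENSE_CODON = "GCT"  # alanine


def _rec(seq="A" * 300, start=0, strand="+", tid="t1", exons=None, chrom="chr1"):
    if exons is None:
        exons = [GenomicInterval(chrom, start, start + len(seq), strand)]
    return LincRNARecord(TranscriptModel(tid, f"g.{tid}", exons), seq, LncClass.LINCRNA)


class TestOrfFinder:
    def test_100_aa_orf(self):
        seq = "ATG" + SENSE_CODON * 99 + "TAA"
        # independent oracle: translation of the constructed frame
        aa = str(Seq(seq).translate())
        assert aa.index("*") == 100
        assert find_longest_orf(seq) == 100

    def test_reverse_strand_orf_found(self):
        seq = "ATG" + SENSE_CODON * 99 + "TAA"
        assert find_longest_orf(str(Seq(seq).reverse_complement())) == 100

    def test_no_atg_means_no_orf(self):
        assert find_longest_orf("CCCCCC") == 0

    def test_incomplete_orf_not_counted(self):
        # ATG + codons but no stop: no complete ORF
        assert find_longest_orf("ATG" + SENSE_CODON * 50) == 0


class TestLengthFilter:
    @pytest.mark.parametrize("length,kept", [(200, False), (201, True)])
    def test_strict_boundary(self, length, kept):
        r = _rec(seq="A" * length)
        k, rej = filter_by_length([r], 200)
        assert (len(k) == 1) is kept

    def test_empty_input(self):
        assert filter_by_length([], 200) == ([], [])


class TestCodingAssessment:
    def test_101_aa_is_coding(self):
        r = _rec(seq="ATG" + SENSE_CODON * 100 + "TAA")
        assert assess_coding(r, None, Config()).verdict == "coding"

    def test_100_aa_is_noncoding(self):
        r = _rec(seq="ATG" + SENSE_CODON * 99 + "TAA")
        assert assess_coding(r, None, Config()).verdict == "noncoding"

    def test_protein_hit_below_threshold_is_coding(self):
        r = _rec(seq="ATG" + SENSE_CODON * 49 + "TAA")  # 50 aa
        assert assess_coding(r, [1e-6], Config()).verdict == "coding"

    def test_protein_hit_at_threshold_is_coding(self):
        r = _rec()
        assert assess_coding(r, [1e-5], Config()).verdict == "coding"

    def test_weak_protein_hit_stays_noncoding(self):
        r = _rec()
        assert assess_coding(r, [1e-4], Config()).verdict == "noncoding"


class TestTeFilter:
    @pytest.mark.parametrize(
        "bit,e,is_te",
        [
            (250.0, 1e-30, True),
            (150.0, 1e-30, False),   # both conditions required
            (250.0, 1e-10, False),
            (200.0, 1e-20, True),    # boundary: >= and <=
        ],
    )
    def test_conjunction(self, bit, e, is_te):
        r = _rec()
        te, kept = filter_te([r], {"t1": (bit, e)}, Config())
        assert (len(te) == 1) is is_te

    def test_no_database_skips_step(self):
        r = _rec()
        te, kept = filter_te([r], None, Config())
        assert te == [] and kept == [r]


class TestOverlapClassification:
    def _annot(self, strand):
        return AnnotationSet(
            [TranscriptModel("G", "G", [GenomicInterval("chr1", 100, 500, strand)])]
        )

    def test_sense_overlap(self):
        m = TranscriptModel("t", "g", [GenomicInterval("chr1", 300, 700, "+")])
        assert classify_overlap(m, self._annot("+")) == LncClass.SOT

    def test_antisense_overlap(self):
        m = TranscriptModel("t", "g", [GenomicInterval("chr1", 300, 700, "+")])
        assert classify_overlap(m, self._annot("-")) == LncClass.AOT

    def test_unknown_strand_single_exon_is_ambiguous(self):
        m = TranscriptModel("t", "g", [GenomicInterval("chr1", 300, 700, ".")])
        assert classify_overlap(m, self._annot("+")) == LncClass.AMBIGUOUS_OVERLAP

    def test_no_overlap_is_lincrna(self):
        m = TranscriptModel("t", "g", [GenomicInterval("chr1", 600, 900, "+")])
        assert classify_overlap(m, self._annot("+")) == LncClass.LINCRNA


class TestTssAnnotation:
    @pytest.mark.parametrize("distance,flagged", [(0, True), (100, True), (101, False)])
    def test_window_inclusive(self, distance, flagged):
        r = _rec(start=1000)
        tss = [(GenomicInterval("chr1", 1000 - distance, 1001 - distance, "+"), "tss1")]
        annotate_tss([r], tss, Config())
        assert r.cage_plus is flagged

    def test_minus_strand_uses_three_prime_end_coordinate(self):
        r = _rec(start=1000, strand="-")
        # 5' end of a minus-strand span [1000,1300) is position 1299
        tss = [(GenomicInterval("chr1", 1299, 1300, "-"), "tss1")]
        annotate_tss([r], tss, Config())
        assert r.cage_plus


class TestKnownLincRNAs:
    def test_overlap_appends_suffix(self):
        r = _rec(start=100, seq="A" * 300)
        known = AnnotationSet(
            [TranscriptModel("K1", "K1", [GenomicInterval("chr1", 300, 600, "+")])]
        )
        reconcile_known_lincRNAs([r], known)
        assert r.known_lincRNA_id == "K1"
        assert r.output_id.endswith("_overlapping_known_lncRNA")

    def test_no_overlap_leaves_id(self):
        r = _rec(start=100, seq="A" * 100)
        known = AnnotationSet(
            [TranscriptModel("K1", "K1", [GenomicInterval("chr1", 900, 1000, "+")])]
        )
        reconcile_known_lincRNAs([r], known)
        assert r.known_lincRNA_id is None
        assert r.output_id == "t1"

    def test_two_overlaps_record_nearest_and_list_all(self):
        r = _rec(start=100, seq="A" * 300)  # span [100,400), midpoint 250
        known = AnnotationSet(
            [
                TranscriptModel("FAR", "FAR", [GenomicInterval("chr1", 380, 800, "+")]),
                TranscriptModel("NEAR", "NEAR", [GenomicInterval("chr1", 150, 350, "+")]),
            ]
        )
        reconcile_known_lincRNAs([r], known)
        assert r.known_lincRNA_id == "NEAR"
        assert set(r.known_lincRNA_ids) == {"NEAR", "FAR"}


class TestLoci:
    def test_shared_exon_is_one_locus(self):
        a = _rec(tid="a", exons=[GenomicInterval("chr1", 0, 300, "+")])
        b = _rec(tid="b", exons=[GenomicInterval("chr1", 100, 400, "+")])
        assert len(group_into_loci([a, b])) == 1

    def test_opposite_strands_are_two_loci(self):
        a = _rec(tid="a", exons=[GenomicInterval("chr1", 0, 300, "+")])
        b = _rec(tid="b", exons=[GenomicInterval("chr1", 100, 400, "-")])
        assert len(group_into_loci([a, b])) == 2

    def test_disjoint_are_two_loci(self):
        a = _rec(tid="a", exons=[GenomicInterval("chr1", 0, 300, "+")])
        b = _rec(tid="b", exons=[GenomicInterval("chr1", 500, 900, "+")])
        assert len(group_into_loci([a, b])) == 2

    def test_span_overlap_without_exon_overlap_stays_separate(self):
        a = _rec(
            tid="a",
            exons=[GenomicInterval("chr1", 0, 100, "+"), GenomicInterval("chr1", 900, 1000, "+")],
        )
        b = _rec(tid="b", exons=[GenomicInterval("chr1", 300, 600, "+")])
        assert len(group_into_loci([a, b])) == 2


class TestDemographics:
    def test_length_and_gc_statistics(self):
        a = _rec(tid="a", seq="ATGC" * 75)          # 300 nt, GC 50
        b = _rec(tid="b", seq="GGCC" * 125, start=5000)  # 500 nt, GC 100
        table = demographics({LncClass.LINCRNA: [a, b]})
        row = table[table.lnc_class == "lincRNA"].iloc[0]
        assert (row.min_length, row.max_length, row.mean_length) == (300, 500, 400)
        assert row.transcripts == 2 and row.loci == 2
        gc = 100.0 * (150 + 500) / 800
        assert row.gc_percent == round(gc, 2)

    def test_gc_direct_count(self):
        a = _rec(tid="a", seq="ATGC")
        b = _rec(tid="b", seq="GGCC", start=5000)
        table = demographics({LncClass.LINCRNA: [a, b]})
        assert table[table.lnc_class == "lincRNA"].iloc[0].gc_percent == 75.0

    def test_empty_class_has_zero_row(self):
        table = demographics({})
        assert (table.transcripts == 0).all()


class TestPipeline:
    def test_planted_classes_recovered_exactly(self, identify_fixture, tmp_path):
        fx = identify_fixture
        result = run_identify(
            fx.transcripts_gtf, fx.genome, fx.annotation_gff,
            te_db=fx.te_db, tss_bed=fx.tss_bed,
            known_lincrna_gff=fx.known_lincrna_gff,
            protein_hits=fx.protein_hits, out_dir=tmp_path / "out",
        )
        for _, row in fx.truth.iterrows():
            assert result.classes[row.transcript_id].value == row.lnc_class, row.transcript_id
        # partition: every transcript in exactly one class
        assert sum(len(v) for v in result.by_class.values()) == len(fx.truth)
        # planted CAGE and known-lincRNA flags propagate
        lincs = {r.model.transcript_id: r for r in result.lincRNAs}
        for _, row in fx.truth[fx.truth.lnc_class == "lincRNA"].iterrows():
            assert lincs[row.transcript_id].cage_plus == row.cage_plus
            assert (lincs[row.transcript_id].known_lincRNA_id is not None) == row.known_overlap

    def test_no_lincrna_output_violates_thresholds(self, identify_fixture, tmp_path):
        fx = identify_fixture
        result = run_identify(
            fx.transcripts_gtf, fx.genome, fx.annotation_gff,
            te_db=fx.te_db, protein_hits=fx.protein_hits,
        )
        cfg = Config()
        for r in result.lincRNAs:
            assert r.length > cfg.min_transcript_len
            assert find_longest_orf(r.seq) <= cfg.max_noncoding_orf_aa

    def test_deleting_annotation_reclassifies_overlaps(self, identify_fixture, tmp_path):
        fx = identify_fixture
        empty_annot = tmp_path / "empty.gff"
        empty_annot.write_text("##gff-version 3\n")
        result = run_identify(
            fx.transcripts_gtf, fx.genome, empty_annot,
            te_db=fx.te_db, protein_hits=fx.protein_hits,
        )
        for _, row in fx.truth.iterrows():
            if row.lnc_class in ("SOT", "AOT"):
                assert result.classes[row.transcript_id] == LncClass.LINCRNA

    def test_growing_annotation_never_grows_lincrna_set(self, identify_fixture, tmp_path):
        fx = identify_fixture
        with_annot = run_identify(
            fx.transcripts_gtf, fx.genome, fx.annotation_gff,
            te_db=fx.te_db, protein_hits=fx.protein_hits,
        )
        empty_annot = tmp_path / "empty.gff"
        empty_annot.write_text("##gff-version 3\n")
        without = run_identify(
            fx.transcripts_gtf, fx.genome, empty_annot,
            te_db=fx.te_db, protein_hits=fx.protein_hits,
        )
        small = {r.model.transcript_id for r in with_annot.lincRNAs}
        big = {r.model.transcript_id for r in without.lincRNAs}
        assert small <= big

    def test_summary_table_deterministic(self, identify_fixture, tmp_path):
        fx = identify_fixture
        outs = []
        for sub in ("a", "b"):
            run_identify(
                fx.transcripts_gtf, fx.genome, fx.annotation_gff,
                te_db=fx.te_db, tss_bed=fx.tss_bed,
                known_lincrna_gff=fx.known_lincrna_gff,
                protein_hits=fx.protein_hits, out_dir=tmp_path / sub,
            )
            outs.append((tmp_path / sub / "Final_summary_table.tsv").read_bytes())
        assert outs[0] == outs[1]

    def test_empty_gtf_gives_empty_outputs(self, identify_fixture, tmp_path):
        empty = tmp_path / "empty.gtf"
        empty.write_text("")
        result = run_identify(
            empty, identify_fixture.genome, identify_fixture.annotation_gff,
            out_dir=tmp_path / "out",
        )
        assert result.summary.empty
        assert not result.lincRNAs

    def test_absent_chromosome_is_error_naming_transcript(self, identify_fixture, tmp_path):
        bad = tmp_path / "bad.gtf"
        bad.write_text('chrZ\tx\texon\t1\t400\t.\t+\t.\ttranscript_id "TX9";\n')
        with pytest.raises(ValueError, match="TX9"):
            run_identify(bad, identify_fixture.genome, identify_fixture.annotation_gff)
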