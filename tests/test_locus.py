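"""Locus model: FASTA/annotation parsing, windows, TSS offsets, region labels."""

import pytest
from hypothesis import given, strategies as st

from cisscan import (
    AnalysisWindow,
    LocusModel,
    build_window,
    classify_region,
    format_kb,
    from_tss_offset,
    locus_to_bed12,
    parse_annotation,
    parse_fasta,
    to_tss_offset,
    window_to_fasta,
)
from cisscan.errors import (
    DuplicateSequenceIdError,
    EmptyFastaError,
    ExonLayoutError,
    GeneCountError,
    InvalidSequenceError,
    StrandMissingError,
    WindowOutsideSequenceError,
)


# --- FASTA -----------------------------------------------------------------

class TestParseFasta:
    @pytest.mark.parametrize(
        "text,expected",
        [
            (">x\nacgt\n", {"x": "ACGT"}),          # case normalisation
            (">x\nACGU\n", {"x": "ACGT"}),          # RNA -> DNA
            (">x\nACGT\n>y\nTTAA\n", {"x": "ACGT", "y": "TTAA"}),
            (">x\nACRYN\n", {"x": "ACRYN"}),        # IUPAC codes accepted
        ],
    )
    def test_parses_and_normalises(self, tmp_path, text, expected):
        path = tmp_path / "in.fa"
        path.write_text(text)
        assert parse_fasta(path) == expected

    def test_duplicate_ids_rejected(self, tmp_path):
        path = tmp_path / "in.fa"
        path.write_text(">x\nACGT\n>x\nTTTT\n")
        with pytest.raises(DuplicateSequenceIdError):
            parse_fasta(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "in.fa"
        path.write_text("")
        with pytest.raises(EmptyFastaError):
            parse_fasta(path)

    def test_illegal_characters_rejected(self, tmp_path):
        path = tmp_path / "in.fa"
        path.write_text(">x\nACGTQ\n")
        with pytest.raises(InvalidSequenceError):
            parse_fasta(path)


# --- annotation ------------------------------------------------------------

class TestParseAnnotation:
    def test_bed12_half_open_to_one_based(self, tmp_path):
        path = tmp_path / "g.bed"
        path.write_text(
            "chr9\t100\t200\tmygene\t0\t+\t100\t200\t0\t1\t100,\t0,\n"
        )
        locus = parse_annotation(path)
        assert (locus.span_start, locus.span_end) == (101, 200)
        assert locus.tss == 101
        assert locus.exons == ((101, 200),)

    def test_gff3_minus_strand_tss(self, tmp_path):
        path = tmp_path / "g.gff3"
        path.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t101\t200\t.\t-\t.\tID=g1\n"
            "chr1\tsrc\texon\t150\t200\t.\t-\t.\tID=g1.e1;Parent=g1\n"
        )
        locus = parse_annotation(path)
        assert locus.tss == 200
        assert locus.gene_strand == "-"

    def test_exon_outside_gene_span_rejected(self, tmp_path):
        path = tmp_path / "g.gff3"
        path.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t101\t200\t.\t+\t.\tID=g1\n"
            "chr1\tsrc\texon\t101\t250\t.\t+\t.\tID=g1.e1;Parent=g1\n"
        )
        with pytest.raises(ExonLayoutError):
            parse_annotation(path)

    def test_multiple_genes_rejected(self, tmp_path):
        path = tmp_path / "g.bed"
        path.write_text(
            "chr1\t100\t200\ta\t0\t+\n" "chr1\t300\t400\tb\t0\t+\n"
        )
        with pytest.raises(GeneCountError):
            parse_annotation(path)

    def test_missing_strand_rejected(self, tmp_path):
        path = tmp_path / "g.bed"
        path.write_text("chr1\t100\t200\ta\t0\t.\n")
        with pytest.raises(StrandMissingError):
            parse_annotation(path)

    def test_bed12_round_trip(self, tmp_path, plus_locus, minus_locus):
        for locus in (plus_locus, minus_locus):
            path = tmp_path / f"{locus.locus_id}.bed"
            path.write_text(locus_to_bed12(locus))
            again = parse_annotation(path, flank_bp=locus.flank_bp)
            assert again == locus


# --- window ----------------------------------------------------------------

class TestBuildWindow:
    SEQ = {"chrT": "A" * 3000}

    def _locus(self, **kwargs):
        defaults = dict(
            locus_id="g", chrom="chrT", span_start=1001, span_end=2000,
            gene_strand="+", tss=1001, exons=((1001, 2000),), flank_bp=0,
        )
        defaults.update(kwargs)
        return LocusModel(**defaults)

    def test_flank_arithmetic(self):
        window = build_window(self._locus(), self.SEQ, flank_bp=500)
        assert (window.origin, window.length) == (501, 2000)

    def test_clipped_at_sequence_start(self):
        window = build_window(self._locus(), self.SEQ, flank_bp=5000)
        assert window.origin == 1
        assert window.end == 3000

    def test_zero_flank_equals_gene_span(self):
        window = build_window(self._locus(), self.SEQ, flank_bp=0)
        assert (window.origin, window.end) == (1001, 2000)

    def test_missing_chromosome_rejected(self):
        with pytest.raises(WindowOutsideSequenceError):
            build_window(self._locus(chrom="chrX"), self.SEQ, 0)

    def test_window_fasta_header_encodes_origin(self):
        window = build_window(self._locus(), self.SEQ, flank_bp=500)
        text = window_to_fasta(window, "g")
        assert text.startswith(">g chrT:501-2500\n")


# --- coordinates -----------------------------------------------------------

class TestTssOffset:
    def _locus(self, strand):
        tss = 50000 if strand == "+" else 50000
        span = (40000, 90000) if strand == "+" else (10000, 50000)
        exons = ((50000, 60000),) if strand == "+" else ((20000, 50000),)
        span = (exons[0][0] - 10000, exons[0][1]) if strand == "+" else (exons[0][0], exons[0][1])
        return LocusModel(
            "g", "chrT", span[0], span[1], strand, tss, exons, flank_bp=50000
        )

    def test_upstream_is_negative_on_plus(self):
        locus = self._locus("+")
        assert to_tss_offset(19000, locus) == -31000

    def test_zero_at_tss(self):
        locus = self._locus("+")
        assert to_tss_offset(locus.tss, locus) == 0

    def test_strand_symmetry_on_minus(self):
        locus = self._locus("-")
        assert to_tss_offset(81000, locus) == -31000

    @given(position=st.integers(1, 200_000), strand=st.sampled_from("+-"))
    def test_offset_round_trips(self, position, strand):
        locus = self._locus(strand)
        assert from_tss_offset(to_tss_offset(position, locus), locus) == position


class TestFormatKb:
    @pytest.mark.parametrize(
        "offset,ndigits,expected",
        [
            (-31000, 0, "-31 kb"),
            (-30996, 0, "-31 kb"),
            (0, 0, "0 kb"),
            (12000, 0, "+12 kb"),
            (147, 3, "+0.147 kb"),
            (-350, 3, "-0.35 kb"),
        ],
    )
    def test_formats(self, offset, ndigits, expected):
        assert format_kb(offset, ndigits) == expected


# --- region labels ---------------------------------------------------------

class TestClassifyRegion:
    def test_intron_numbering_is_strand_aware(self, plus_locus, minus_locus):
        # interval fully between strand-ordered exons 4 and 5
        i4_plus = plus_locus.intron_interval(4)
        assert classify_region(i4_plus, plus_locus) == "intron_4"
        i4_minus = minus_locus.intron_interval(4)
        assert classify_region(i4_minus, minus_locus) == "intron_4"
        # the same genomic gap carries different numbers on the two strands
        assert classify_region(i4_plus, minus_locus) == "intron_2"

    def test_upstream_is_strand_aware(self, plus_locus, minus_locus):
        left = (plus_locus.span_start - 50, plus_locus.span_start - 40)
        assert classify_region(left, plus_locus) == "upstream"
        assert classify_region(left, minus_locus) == "downstream"

    def test_boundary_straddling_an_exon_edge(self, plus_locus):
        exon2 = plus_locus.exons[1]
        interval = (exon2[0] - 5, exon2[0] + 5)
        assert classify_region(interval, plus_locus) == "boundary"

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_every_position_gets_exactly_one_label(
        self, strand, plus_locus, minus_locus
    ):
        locus = plus_locus if strand == "+" else minus_locus
        lo = locus.span_start - locus.flank_bp
        hi = locus.span_end + locus.flank_bp
        valid = {"upstream", "downstream"} | {
            f"exon_{k}" for k in range(1, locus.n_exons + 1)
        } | {f"intron_{k}" for k in range(1, locus.n_exons)}
        labels = {classify_region((p, p), locus) for p in range(lo, hi + 1)}
        assert labels <= valid
        # each exon and intron is actually reachable
        assert {f"exon_{k}" for k in range(1, locus.n_exons + 1)} <= labels
        assert {f"intron_{k}" for k in range(1, locus.n_exons)} <= labels


# --- model invariants ------------------------------------------------------

class TestLocusModelInvariants:
    def test_tss_must_anchor_exon_one(self):
        with pytest.raises(ExonLayoutError):
            LocusModel(
                "g", "chrT", 1001, 2000, "+", 1500, ((1001, 2000),), 0
            )

    def test_overlapping_exons_rejected(self):
        with pytest.raises(ExonLayoutError):
            LocusModel(
                "g", "chrT", 1001, 2000, "+", 1001,
                ((1001, 1500), (1400, 2000)), 0,
            )

    def test_analysis_window_rejects_non_acgtn(self):
        with pytest.raises(InvalidSequenceError):
            AnalysisWindow(sequence="ACGTR", origin=1)
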