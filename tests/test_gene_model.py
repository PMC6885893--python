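"""Gene model parsing, junction indexing and variant-exon assignment."""

import pytest

from eseskip.gene_model import (
    TranscriptModel,
    VariantAssigner,
    assign_variant_to_exon,
    build_junction_index,
    exon_in_frame,
    is_analyzable,
    normalized_exon_position,
    read_gene_model,
)
from eseskip.io import JunctionKey, ParseError

from conftest import make_transcript, make_variant


class TestReaders:
    def test_refflat_three_exons(self, tmp_path):
        p = tmp_path / "genes.refFlat"
        p.write_text(
            "GENE1\tTX1\tchr1\t+\t100\t600\t100\t600\t3\t100,300,500,\t200,400,600,\n"
        )
        models = read_gene_model(p)
        assert len(models) == 1
        assert models[0].exons == ((100, 200), (300, 400), (500, 600))
        assert len(build_junction_index(models)) == 2

    def test_single_exon_transcript_has_no_junctions(self, tmp_path):
        p = tmp_path / "genes.refFlat"
        p.write_text("G\tT\tchr1\t+\t10\t50\t10\t50\t1\t10,\t50,\n")
        models = read_gene_model(p)
        assert build_junction_index(models) == {}
        v = make_variant(gene="G", pos=20)
        a = assign_variant_to_exon(v, models)
        assert a is not None and not a.is_internal

    def test_bed12_parsing(self, tmp_path):
        p = tmp_path / "genes.bed"
        p.write_text("chr1\t100\t600\tTX1\t0\t+\t100\t600\t0\t3\t100,100,100,\t0,200,400,\n")
        models = read_gene_model(p)
        assert models[0].exons == ((100, 200), (300, 400), (500, 600))

    def test_bed12_block_count_mismatch(self, tmp_path):
        p = tmp_path / "genes.bed"
        p.write_text("chr1\t100\t600\tTX1\t0\t+\t100\t600\t0\t3\t100,100,\t0,200,\n")
        with pytest.raises(ParseError, match="blockCount"):
            read_gene_model(p)

    def test_overlapping_exons_rejected(self):
        with pytest.raises(ValueError, match="unsorted or overlapping"):
            TranscriptModel("G", "T", "chr1", "+", ((100, 250), (200, 300)))


class TestJunctionIndex:
    def test_coordinate_conversion(self, transcript):
        index = build_junction_index([transcript])
        # 0-based half-open [100,200),[300,400) -> 1-based junction (200, 301)
        assert JunctionKey("chr1", 200, 301) in index
        assert JunctionKey("chr1", 400, 501) in index

    def test_shared_junction_accumulates(self, transcript):
        other = make_transcript(tx="TX2", exons=((100, 200), (300, 400)))
        index = build_junction_index([transcript, other])
        assert len(index[JunctionKey("chr1", 200, 301)]) == 2

    def test_empty_model_list(self):
        assert build_junction_index([]) == {}

    def test_entry_count_is_sum_of_exon_gaps(self):
        models = [
            make_transcript(tx=f"T{i}", chrom=f"chr{i + 1}",
                            exons=tuple((100 * j, 100 * j + 50) for j in range(1, n + 1)))
            for i, n in enumerate([2, 3, 5, 7])
        ]
        index = build_junction_index(models)
        assert sum(len(v) for v in index.values()) == sum(n - 1 for n in [2, 3, 5, 7])


class TestAssignment:
    def test_variant_inside_exon(self, transcript):
        a = assign_variant_to_exon(make_variant(pos=150), [transcript])
        assert a.exon_index == 0 and not a.is_internal

    def test_first_base_of_exon_contained(self, transcript):
        # 1-based position 101 is the first base of half-open exon [100, 200)
        a = assign_variant_to_exon(make_variant(pos=101), [transcript])
        assert a is not None and a.exon_index == 0

    def test_intronic_variant_none(self, transcript):
        assert assign_variant_to_exon(make_variant(pos=250), [transcript]) is None

    def test_internal_exon_junction_keys(self, transcript):
        a = assign_variant_to_exon(make_variant(pos=350), [transcript])
        assert a.is_internal
        assert a.junction_prev == JunctionKey("chr1", 200, 301)
        assert a.junction_next == JunctionKey("chr1", 400, 501)
        assert a.junction_skip == JunctionKey("chr1", 200, 501)
        index = build_junction_index([transcript])
        assert a.junction_prev in index and a.junction_next in index

    def test_transcript_selection_prefers_more_exons(self, transcript):
        short = make_transcript(tx="TX0", exons=((300, 400),))
        a = assign_variant_to_exon(make_variant(pos=350), [short, transcript])
        assert a.transcript.transcript_id == "TX1"
        both = VariantAssigner([short, transcript]).assign_all(make_variant(pos=350))
        assert len(both) == 2


class TestAnalyzability:
    def test_sex_chromosome_excluded(self):
        t = make_transcript(chrom="chrX")
        v = make_variant(chrom="chrX", pos=350)
        assert not is_analyzable(assign_variant_to_exon(v, [t]), v)

    def test_autosomal_silent_internal_ok(self):
        t = make_transcript(chrom="chr20")
        v = make_variant(chrom="chr20", pos=350, classification="Silent")
        assert is_analyzable(assign_variant_to_exon(v, [t]), v)

    def test_first_exon_excluded(self, transcript):
        v = make_variant(pos=150)
        assert not is_analyzable(assign_variant_to_exon(v, [transcript]), v)

    def test_splice_site_classification_excluded(self, transcript):
        v = make_variant(pos=350, classification="Splice_Site")
        assert not is_analyzable(assign_variant_to_exon(v, [transcript]), v)

    def test_exon_spanning_indel_dropped(self, transcript):
        v = make_variant(pos=390)
        v = type(v)(**{**v.__dict__, "end_pos": 450, "variant_type": "DEL"})
        assert not is_analyzable(assign_variant_to_exon(v, [transcript]), v)


class TestPosition:
    @pytest.mark.parametrize(
        "strand,pos,expected",
        [("+", 1001, 0.0), ("-", 1100, 0.0), ("+", 1051, 0.50), ("-", 1051, 0.49)],
    )
    def test_normalized_position(self, strand, pos, expected):
        t = make_transcript(strand=strand, exons=((800, 900), (1000, 1100), (1200, 1300)))
        v = make_variant(pos=pos)
        a = assign_variant_to_exon(v, [t])
        assert normalized_exon_position(v, a) == pytest.approx(expected)

    def test_shift_invariance(self):
        for shift in (0, 12345):
            t = make_transcript(
                exons=((800 + shift, 900 + shift), (1000 + shift, 1100 + shift),
                       (1200 + shift, 1300 + shift))
            )
            v = make_variant(pos=1042 + shift)
            a = assign_variant_to_exon(v, [t])
            assert normalized_exon_position(v, a) == pytest.approx(0.41)

    @pytest.mark.parametrize("length,expected", [(99, True), (100, False), (90, True)])
    def test_exon_in_frame(self, length, expected):
        t = make_transcript(exons=((100, 200), (300, 300 + length), (700, 800)))
        a = assign_variant_to_exon(make_variant(pos=301), [t])
        assert exon_in_frame(a) is expected
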