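"""Format parsing, the 0-based half-open convention, and round-trips."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lncannot import genome_io as gio


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestGeneModels:
    def test_gff3_one_based_inclusive_converts_to_half_open(self, tmp_path):
        p = _write(tmp_path, "g.gff3",
                   "chr1\tx\tgene\t101\t200\t.\t+\t.\tID=g1;Name=G1\n"
                   "chr1\tx\texon\t101\t200\t.\t+\t.\tParent=g1\n")
        (gene,) = gio.parse_gene_models(p, "gff3")
        assert gene.span == (100, 200)
        assert gene.exons == [(100, 200)]

    def test_bed12_zero_based_half_open(self, tmp_path):
        p = _write(tmp_path, "g.bed",
                   "chr1\t999\t2000\tg1\t0\t+\t999\t2000\t0\t1\t1001,\t0,\n")
        (gene,) = gio.parse_gene_models(p, "bed12")
        assert gene.span == (999, 2000)
        assert gene.strand == "+"

    def test_bed12_thick_region_defines_utrs(self, tmp_path):
        # 2 exons; CDS (thick) = [150, 950); left-of-thick is 5' UTR on +
        p = _write(tmp_path, "g.bed",
                   "chr1\t100\t1000\tg1\t0\t+\t150\t950\t0\t2\t200,300,\t0,600,\n")
        (gene,) = gio.parse_gene_models(p, "bed12")
        assert gene.utr5 == [(100, 150)]
        assert gene.utr3 == [(950, 1000)]

    def test_missing_strand_rejected(self, tmp_path):
        p = _write(tmp_path, "g.gff3", "chr1\tx\tgene\t1\t10\t.\t.\t.\tID=g1\n")
        with pytest.raises(gio.ParseError, match="missing strand"):
            gio.parse_gene_models(p, "gff3")

    def test_malformed_line_names_line_number(self, tmp_path):
        p = _write(tmp_path, "g.gff3",
                   "chr1\tx\tgene\t1\t10\t.\t+\t.\tID=g1\n"
                   "chr1\tx\tgene\tBAD\t10\t.\t+\t.\tID=g2\n")
        with pytest.raises(gio.ParseError, match="line 2"):
            gio.parse_gene_models(p, "gff3")

    def test_exon_outside_span_rejected(self, tmp_path):
        p = _write(tmp_path, "g.gff3",
                   "chr1\tx\tgene\t101\t200\t.\t+\t.\tID=g1\n"
                   "chr1\tx\texon\t50\t90\t.\t+\t.\tParent=g1\n")
        with pytest.raises(gio.ValidationError, match="outside span"):
            gio.parse_gene_models(p, "gff3")


class TestIntervals:
    def test_dot_strand_is_unknown_single_block(self, tmp_path):
        p = _write(tmp_path, "t.bed", "chr1\t100\t200\tx\t0\t.\n")
        (rec,) = gio.parse_intervals(p)
        assert rec.strand == "."
        assert rec.blocks == [(100, 200)]

    def test_bed12_block_arithmetic(self, tmp_path):
        p = _write(tmp_path, "t.bed",
                   "chr1\t100\t300\tx\t0\t+\t100\t300\t0\t2\t50,50,\t0,150,\n")
        (rec,) = gio.parse_intervals(p)
        assert rec.blocks == [(100, 150), (250, 300)]

    def test_inconsistent_blocks_rejected(self, tmp_path):
        p = _write(tmp_path, "t.bed",
                   "chr1\t100\t300\tx\t0\t+\t100\t300\t0\t2\t50,40,\t0,150,\n")
        with pytest.raises(gio.ParseError, match="line 1"):
            gio.parse_intervals(p)

    def test_empty_file_gives_empty_list(self, tmp_path):
        assert gio.parse_intervals(_write(tmp_path, "e.bed", "")) == []


class TestScoreTrack:
    @pytest.fixture
    def assembly(self):
        return gio.GenomeAssembly(["chr1"], {"chr1": 100})

    def test_bedgraph_half_open_coverage(self, tmp_path, assembly):
        p = _write(tmp_path, "s.bg", "chr1\t0\t3\t1.5\n")
        track = gio.parse_score_track(p, assembly)
        assert list(track.scores["chr1"][:3]) == [1.5, 1.5, 1.5]
        assert list(track.covered["chr1"][:4]) == [True, True, True, False]

    def test_overlapping_records_last_wins(self, tmp_path, assembly, caplog):
        p = _write(tmp_path, "s.bg", "chr1\t0\t5\t1.0\nchr1\t3\t6\t2.0\n")
        with caplog.at_level("WARNING"):
            track = gio.parse_score_track(p, assembly)
        assert track.scores["chr1"][4] == 2.0
        assert track.scores["chr1"][2] == 1.0
        assert "overlapping" in caplog.text

    def test_fixed_step_wiggle_is_one_based(self, tmp_path, assembly):
        p = _write(tmp_path, "s.wig", "fixedStep chrom=chr1 start=1 step=1\n1\n2\n3\n")
        track = gio.parse_score_track(p, assembly)
        assert list(track.scores["chr1"][:3]) == [1.0, 2.0, 3.0]
        assert not track.covered["chr1"][3]

    def test_out_of_bounds_interval_rejected(self, tmp_path, assembly):
        p = _write(tmp_path, "s.bg", "chr1\t90\t200\t1.0\n")
        with pytest.raises(gio.ValidationError, match="out of bounds"):
            gio.parse_score_track(p, assembly)


class TestWriteRoundTrip:
    def test_unknown_strand_written_as_dot(self, tmp_path):
        rec = gio.TranscriptRecord("x", "chr1", ".", [(10, 20)])
        out = tmp_path / "o.bed"
        gio.write_intervals([rec], out)
        assert out.read_text().split("\t")[5] == "."

    def test_shuffled_input_writes_identical_file(self, tmp_path):
        recs = [
            gio.TranscriptRecord(f"t{i}", "chr1", "+", [(i * 100, i * 100 + 50)])
            for i in range(10)
        ]
        a, b = tmp_path / "a.bed", tmp_path / "b.bed"
        gio.write_intervals(recs, a)
        gio.write_intervals(list(reversed(recs)), b)
        assert a.read_bytes() == b.read_bytes()

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(
        st.tuples(st.integers(0, 5000), st.integers(1, 300), st.integers(50, 200),
                  st.sampled_from("+-.")),
        min_size=1, max_size=6, unique_by=lambda t: t[0]))
    def test_round_trip_identity(self, tmp_path_factory, items):
        """parse(write(records)) == records for arbitrary valid block lists."""
        recs = []
        for i, (start, size1, gap, strand) in enumerate(sorted(items)):
            blocks = [(start, start + size1), (start + size1 + gap, start + size1 + gap + 30)]
            recs.append(gio.TranscriptRecord(f"r{i:03d}", "chr1", strand, blocks))
        out = tmp_path_factory.mktemp("rt") / "rt.bed"
        gio.write_intervals(recs, out)
        back = gio.parse_intervals(out)
        key = lambda r: (r.chrom, r.span[0], r.transcript_id)  # noqa: E731
        for orig, new in zip(sorted(recs, key=key), back):
            assert (orig.transcript_id, orig.chrom, orig.strand, orig.blocks) == (
                new.transcript_id, new.chrom, new.strand, new.blocks)

    def test_gff3_round_trip_on_synthetic_genes(self, tmp_path, small_study):
        from lncannot.synthetic_data import write_gff3

        out = tmp_path / "genes.gff3"
        write_gff3(small_study.genes, out)
        back = gio.parse_gene_models(out, "gff3")
        orig = sorted(small_study.genes, key=lambda g: (g.chrom, g.span[0], g.gene_id))
        assert len(back) == len(orig)
        for a, b in zip(orig, back):
            assert (a.gene_id, a.chrom, a.strand, a.span, a.exons, a.utr5, a.utr3) == (
                b.gene_id, b.chrom, b.strand, b.span, b.exons, b.utr5, b.utr3)
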