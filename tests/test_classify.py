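"""Positional classification, neighbor assignment, strand inference."""

import numpy as np
import pytest

from lncannot import classify, synthetic_data as synth
from lncannot.genome_io import GeneModel, GenomeAssembly, TranscriptRecord
from oracles import classify_per_base


def _rec(tid, start, end, strand="+", chrom="chr1", blocks=None):
    return TranscriptRecord(tid, chrom, strand, blocks or [(start, end)])


class TestCategories:
    @pytest.fixture
    def gene(self):
        return [GeneModel("g", "G", "chr1", "+", (1000, 2000),
                          [(1000, 1200), (1800, 2000)])]

    @pytest.mark.parametrize(
        "start,end,expected",
        [
            (1300, 1500, "intronic"),  # inside the intron
            (1900, 2100, "overlapped"),  # 100 bp exon overlap
            (5000, 5600, "intergenic"),
            (1199, 1201, "overlapped"),  # single-base exon overlap
            (1200, 1800, "intronic"),  # exactly the intron, half-open
        ],
    )
    def test_known_positions(self, gene, start, end, expected):
        (ann,) = classify.classify_transcripts([_rec("t", start, end)], gene)
        assert ann.category == expected

    def test_chromosome_without_genes_is_intergenic(self, gene, caplog):
        with caplog.at_level("WARNING"):
            (ann,) = classify.classify_transcripts([_rec("t", 0, 100, chrom="chrX")], gene)
        assert ann.category == "intergenic"

    def test_partition_and_order_invariance(self, small_study):
        anns = classify.classify_transcripts(small_study.ncrnas, small_study.genes)
        counts = classify.category_counts(anns)
        assert sum(counts.values()) == len(small_study.ncrnas)
        shuffled = list(reversed(small_study.ncrnas))
        anns2 = classify.classify_transcripts(shuffled, small_study.genes)
        by_id = {a.transcript_id: a.category for a in anns2}
        assert all(by_id[a.transcript_id] == a.category for a in anns)

    def test_matches_per_base_oracle_on_random_transcripts(self, small_study):
        """Interval-tree classification == brute-force per-base scan."""
        rng = np.random.default_rng(99)
        chrom = small_study.assembly.chrom_names[0]
        clen = small_study.assembly.chrom_lengths[chrom]
        random_recs = []
        for i in range(300):
            length = int(rng.integers(50, 4000))
            start = int(rng.integers(0, clen - length))
            random_recs.append(_rec(f"rand{i}", start, start + length, chrom=chrom))
        anns = classify.classify_transcripts(random_recs, small_study.genes)
        for rec, ann in zip(random_recs, anns):
            assert ann.category == classify_per_base(rec, small_study.genes)


class TestUtrRelated:
    @pytest.fixture
    def gene(self):
        return [GeneModel("g", "G", "chr1", "+", (1000, 2000), [(1000, 2000)])]

    def test_within_1kb_becomes_utr_related(self, gene):
        rec = _rec("t", 2100, 2600)
        anns = classify.classify_transcripts([rec], gene)
        (ann,) = classify.subclassify_utr_related(anns, {"t": rec}, gene)
        assert ann.category == "utr_related"
        assert ann.distance_bp == 100

    def test_beyond_1kb_without_similarity_stays_intergenic(self, gene):
        rec = _rec("t", 6000, 6500)
        anns = classify.classify_transcripts([rec], gene)
        (ann,) = classify.subclassify_utr_related(anns, {"t": rec}, gene)
        assert ann.category == "intergenic"

    def test_utr_similarity_branch(self, gene):
        """A distant transcript identical to an annotated UTR is UTR-related."""
        rng = np.random.default_rng(5)
        utr_seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))
        rec = _rec("t", 5000, 5400)
        anns = classify.classify_transcripts([rec], gene)
        (ann,) = classify.subclassify_utr_related(
            anns, {"t": rec}, gene,
            utr_sequences={"u1": utr_seq}, transcript_sequences={"t": utr_seq},
        )
        assert ann.category == "utr_related"


class TestNearestGene:
    def test_closest_gene_distance_and_end(self, toy_genes):
        gid, dist, end = classify.nearest_gene(_rec("t", 2500, 2600), toy_genes)
        assert (gid, dist, end) == ("gA", 500, "3prime")
        gid, dist, end = classify.nearest_gene(_rec("t", 4000, 4100), toy_genes)
        assert (gid, dist, end) == ("gB", 900, "5prime")

    def test_equidistant_tie_breaks_by_smaller_start(self, toy_genes):
        # midpoint between gA end (2000) and gB start (5000): [3450, 3550)
        gid, dist, _ = classify.nearest_gene(_rec("t", 3450, 3550), toy_genes)
        assert dist == 1450
        assert gid == "gA"

    def test_minus_strand_gene_flips_ends(self):
        genes = [GeneModel("g", "G", "chr1", "-", (1000, 2000), [(1000, 2000)])]
        _, _, end = classify.nearest_gene(_rec("t", 2500, 2600), genes)
        assert end == "5prime"

    def test_no_gene_on_chromosome_returns_none(self, toy_genes):
        assert classify.nearest_gene(_rec("t", 0, 10, chrom="chrZ"), toy_genes) is None

    def test_distance_invariant_under_coordinate_reflection(self, small_study):
        genes = small_study.genes
        chrom = small_study.assembly.chrom_names[0]
        clen = small_study.assembly.chrom_lengths[chrom]
        flip = lambda iv: (clen - iv[1], clen - iv[0])  # noqa: E731
        rgenes = [
            GeneModel(g.gene_id, g.symbol, g.chrom,
                      "-" if g.strand == "+" else "+", flip(g.span),
                      sorted(flip(x) for x in g.exons))
            for g in genes if g.chrom == chrom
        ]
        rng = np.random.default_rng(3)
        for _ in range(40):
            start = int(rng.integers(0, clen - 500))
            rec = _rec("t", start, start + 500, chrom=chrom)
            rrec = _rec("t", *flip((start, start + 500)), chrom=chrom)
            fwd = classify.nearest_gene(rec, [g for g in genes if g.chrom == chrom])
            rev = classify.nearest_gene(rrec, rgenes)
            assert fwd[1] == rev[1]  # distance is reflection-invariant
            assert fwd[2] == rev[2]  # strand flip keeps the facing gene end


class TestStrandInference:
    def _genome(self, seq):
        return GenomeAssembly(["chr1"], {"chr1": len(seq)}, {"chr1": seq})

    def test_canonical_motifs_vote(self):
        seq = list("A" * 100)
        seq[20:22], seq[48:50] = "GT", "AG"  # intron 1: [20, 50)
        seq[60:62], seq[78:80] = "GT", "AG"  # intron 2: [60, 80)
        genome = self._genome("".join(seq))
        rec = _rec("t", 0, 100, strand=".",
                   blocks=[(0, 20), (50, 60), (80, 100)])
        assert classify.infer_strand(rec, genome) == "+"

    def test_reverse_motifs_vote_minus(self):
        seq = list("A" * 60)
        seq[20:22], seq[38:40] = "CT", "AC"
        rec = _rec("t", 0, 60, strand=".", blocks=[(0, 20), (40, 60)])
        assert classify.infer_strand(rec, self._genome("".join(seq))) == "-"

    def test_conflicting_votes_are_unknown(self):
        seq = list("A" * 110)
        seq[20:22], seq[48:50] = "GT", "AG"
        seq[70:72], seq[88:90] = "CT", "AC"
        rec = _rec("t", 0, 110, strand=".",
                   blocks=[(0, 20), (50, 70), (90, 110)])
        assert classify.infer_strand(rec, self._genome("".join(seq))) == "."

    def test_single_block_keeps_declared_strand(self):
        rec = _rec("t", 0, 50, strand="+")
        assert classify.infer_strand(rec, self._genome("A" * 60)) == "+"

    def test_recovers_planted_strands(self, study):
        hits = total = 0
        for t in study.ncrnas:
            if len(t.blocks) < 2:
                continue
            total += 1
            hits += (classify.infer_strand(t, study.assembly)
                     == study.truth.ncrna[t.transcript_id]["strand"])
        assert total > 10
        assert hits == total


class TestOrientationAndSelection:
    @pytest.mark.parametrize("nc,gene,expected", [
        ("+", "+", "sense"), ("-", "+", "antisense"), (".", "+", "unknown"),
    ])
    def test_relative_orientation(self, nc, gene, expected):
        assert classify.relative_orientation(nc, gene) == expected

    def test_proximate_selection_boundaries(self):
        mk = lambda d, cat="intergenic": classify.NcRNAAnnotation(  # noqa: E731
            f"t{d}", cat, neighbor_gene_id="g", distance_bp=d, gene_end="3prime")
        sel = classify.select_gene_proximate([mk(4999), mk(5001), mk(100, "utr_related")])
        picked = [a.transcript_id for a in sel["3prime"]]
        assert picked == ["t4999"]

    def test_histogram_counts_and_overflow(self):
        anns = [
            classify.NcRNAAnnotation("a", "intergenic", "g", 500, "5prime", "sense"),
            classify.NcRNAAnnotation("b", "intergenic", "g", 500, "5prime", "sense"),
            classify.NcRNAAnnotation("c", "intergenic", "g", 70000, "3prime", "antisense"),
        ]
        hist = classify.positional_histogram(anns, bin_edges=[0, 1000, 5000])
        assert hist.counts[("5prime", "sense")][0] == 2
        assert hist.counts[("3prime", "antisense")][-1] == 1  # overflow bin
        assert hist.total() == 3
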