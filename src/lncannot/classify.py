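"""Positional classification of candidate ncRNAs against gene models.

Categories (strand-agnostic):

* ``overlapped`` — any block shares >= 1 bp with any exon of any gene;
* ``intronic``  — no exon overlap, but the span lies wholly inside some
  gene's span (i.e. contained in the gene body);
* ``intergenic`` — everything else, refined to
* ``utr_related`` when within 1 kb of a gene end or highly similar to an
  annotated UTR sequence.

Intergenic transcripts get a nearest ("neighbor") gene, the distance to its
span, the gene end they face (5'/3', strand-aware) and a sense/antisense
orientation.  Strand of spliced transcripts can be inferred from canonical
splice dinucleotides (GT..AG forward, CT..AC reverse).
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree

from . import coding_screen
from .genome_io import GeneModel, GenomeAssembly, TranscriptRecord, spliced_sequence

log = logging.getLogger(__name__)

CATEGORIES = ("intergenic", "intronic", "overlapped", "utr_related")


@dataclass
class NcRNAAnnotation:
    transcript_id: str
    category: str
    neighbor_gene_id: str | None = None
    distance_bp: int | None = None
    gene_end: str | None = None  # 5prime / 3prime
    orientation: str = "unknown"  # sense / antisense / unknown


@dataclass
class ClassifyConfig:
    utr_distance_bp: int = 1000
    proximate_distance_bp: int = 5000
    utr_identity_threshold: float = 90.0
    utr_coverage_threshold: float = 50.0


@dataclass
class PositionalHistogram:
    bin_edges: list[int]
    # (gene_end, orientation) -> counts per bin, last bin = overflow
    counts: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def total(self) -> int:
        return int(sum(c.sum() for c in self.counts.values()))


def _exon_trees(genes: list[GeneModel]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        tree = trees.setdefault(g.chrom, IntervalTree())
        for x0, x1 in g.exons:
            tree.addi(x0, x1, g.gene_id)
    return trees


def _span_trees(genes: list[GeneModel]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.span[0], g.span[1], g)
    return trees


def classify_transcripts(
    transcripts: list[TranscriptRecord], genes: list[GeneModel]
) -> list[NcRNAAnnotation]:
    """Assign the overlapped/intronic/intergenic category to each transcript.

    UTR-related refinement of the intergenic class is a separate step
    (:func:`subclassify_utr_related`).  Transcripts on chromosomes with no
    gene are intergenic (with a warning).
    """
    exon_trees = _exon_trees(genes)
    span_trees = _span_trees(genes)
    gene_chroms = {g.chrom for g in genes}
    out = []
    for t in transcripts:
        if t.chrom not in gene_chroms:
            log.warning("transcript %s on chromosome %s with no genes; intergenic",
                        t.transcript_id, t.chrom)
            out.append(NcRNAAnnotation(t.transcript_id, "intergenic"))
            continue
        etree = exon_trees.get(t.chrom)
        if etree is not None and any(etree.overlap(b0, b1) for b0, b1 in t.blocks):
            out.append(NcRNAAnnotation(t.transcript_id, "overlapped"))
            continue
        s, e = t.span
        containing = [
            iv.data for iv in span_trees.get(t.chrom, IntervalTree()).overlap(s, e)
            if iv.begin <= s and e <= iv.end
        ]
        if containing:
            # nested genes: record the first containing gene by start coordinate
            host = min(containing, key=lambda g: (g.span[0], g.gene_id))
            out.append(NcRNAAnnotation(t.transcript_id, "intronic", neighbor_gene_id=None))
            _ = host  # host identity retrievable via span trees; not part of the contract
        else:
            out.append(NcRNAAnnotation(t.transcript_id, "intergenic"))
    return out


def nearest_gene(
    transcript: TranscriptRecord, genes: list[GeneModel]
) -> tuple[str, int, str] | None:
    """Closest gene (span-to-span gap), which end of it faces the transcript.

    Ties between equidistant genes break by (smaller gene start, then
    lexicographic gene id).  Returns None when the chromosome has no gene.
    """
    s, e = transcript.span
    best: tuple[int, int, str, GeneModel] | None = None
    for g in genes:
        if g.chrom != transcript.chrom:
            continue
        gs, ge = g.span
        if e <= gs:
            dist = gs - e
        elif ge <= s:
            dist = s - ge
        else:
            dist = 0
        key = (dist, gs, g.gene_id)
        if best is None or key < (best[0], best[1], best[2]):
            best = (dist, gs, g.gene_id, g)
    if best is None:
        return None
    dist, _, gid, g = best
    # which side of the gene the transcript lies on, in transcription terms
    mid = (s + e) / 2
    gmid = (g.span[0] + g.span[1]) / 2
    upstream_side = mid < gmid  # genomically left of the gene
    if g.strand == "+":
        gene_end = "5prime" if upstream_side else "3prime"
    else:
        gene_end = "3prime" if upstream_side else "5prime"
    return gid, dist, gene_end


def subclassify_utr_related(
    annotations: list[NcRNAAnnotation],
    transcripts: dict[str, TranscriptRecord],
    genes: list[GeneModel],
    cfg: ClassifyConfig | None = None,
    utr_sequences: dict[str, str] | None = None,
    transcript_sequences: dict[str, str] | None = None,
) -> list[NcRNAAnnotation]:
    """Relabel intergenic annotations as UTR-related.

    An intergenic transcript becomes ``utr_related`` iff its distance to the
    nearest gene is <= ``utr_distance_bp`` or its best local alignment to an
    annotated UTR sequence exceeds the identity and coverage thresholds.
    Neighbor fields are filled for every (still) intergenic and UTR-related
    annotation.
    """
    cfg = cfg or ClassifyConfig()
    screen_cfg = coding_screen.ScreenConfig()
    out = []
    for ann in annotations:
        if ann.category != "intergenic":
            out.append(ann)
            continue
        t = transcripts[ann.transcript_id]
        nearest = nearest_gene(t, genes)
        if nearest is None:
            out.append(ann)
            continue
        gid, dist, gene_end = nearest
        category = "intergenic"
        if dist <= cfg.utr_distance_bp:
            category = "utr_related"
        elif utr_sequences:
            if transcript_sequences is None or ann.transcript_id not in transcript_sequences:
                raise ValueError(
                    f"UTR similarity requested but no sequence for {ann.transcript_id!r}"
                )
            qseq = transcript_sequences[ann.transcript_id]
            for uid, useq in utr_sequences.items():
                stats = coding_screen.local_alignment_stats(qseq, useq, ann.transcript_id,
                                                            uid, screen_cfg)
                if (stats.identity > cfg.utr_identity_threshold
                        and stats.coverage > cfg.utr_coverage_threshold):
                    category = "utr_related"
                    break
        out.append(
            NcRNAAnnotation(ann.transcript_id, category, neighbor_gene_id=gid,
                            distance_bp=dist, gene_end=gene_end,
                            orientation=ann.orientation)
        )
    return out


def infer_strand(transcript: TranscriptRecord, genome: GenomeAssembly) -> str:
    """Deduce strand of a spliced transcript from splice dinucleotides.

    Each intron votes: GT..AG -> '+', CT..AC -> '-'; introns < 4 bp or with
    non-canonical motifs abstain.  A unanimous non-empty vote decides;
    conflict or no votes -> '.' (unknown).  Single-block transcripts keep
    their declared strand.
    """
    introns = transcript.introns
    if not introns or genome.sequence is None:
        return transcript.strand
    seq = genome.sequence.get(transcript.chrom)
    if seq is None:
        return transcript.strand
    votes = set()
    for i0, i1 in introns:
        if i1 - i0 < 4:
            continue
        donor, acceptor = seq[i0 : i0 + 2].upper(), seq[i1 - 2 : i1].upper()
        if donor == "GT" and acceptor == "AG":
            votes.add("+")
        elif donor == "CT" and acceptor == "AC":
            votes.add("-")
    if len(votes) == 1:
        return votes.pop()
    return "."


def relative_orientation(strand: str, gene_strand: str) -> str:
    """sense / antisense / unknown of an ncRNA strand vs its neighbor gene."""
    if strand == ".":
        return "unknown"
    return "sense" if strand == gene_strand else "antisense"


def annotate_orientations(
    annotations: list[NcRNAAnnotation],
    transcripts: dict[str, TranscriptRecord],
    genes: list[GeneModel],
    genome: GenomeAssembly | None = None,
) -> list[NcRNAAnnotation]:
    """Fill the orientation field of neighbor-bearing annotations.

    When genome sequence is available, unknown strands of spliced
    transcripts are first inferred from splice motifs.
    """
    by_id = {g.gene_id: g for g in genes}
    out = []
    for ann in annotations:
        if ann.neighbor_gene_id is None:
            out.append(ann)
            continue
        t = transcripts[ann.transcript_id]
        strand = t.strand
        if strand == "." and genome is not None and genome.sequence is not None:
            strand = infer_strand(t, genome)
        ann.orientation = relative_orientation(strand, by_id[ann.neighbor_gene_id].strand)
        out.append(ann)
    return out


def select_gene_proximate(
    annotations: list[NcRNAAnnotation], cfg: ClassifyConfig | None = None
) -> dict[str, list[NcRNAAnnotation]]:
    """Stringent intergenic annotations within the proximate distance, by gene end."""
    cfg = cfg or ClassifyConfig()
    out: dict[str, list[NcRNAAnnotation]] = {"5prime": [], "3prime": []}
    for ann in annotations:
        if (
            ann.category == "intergenic"
            and ann.distance_bp is not None
            and ann.distance_bp <= cfg.proximate_distance_bp
            and ann.gene_end in out
        ):
            out[ann.gene_end].append(ann)
    return out


def positional_histogram(
    annotations: list[NcRNAAnnotation], bin_edges: list[int] | None = None
) -> PositionalHistogram:
    """Distance histogram split by (gene end) x (orientation).

    Bins are half-open [lo, hi); distances beyond the last edge land in an
    overflow bin.  Only neighbor-bearing annotations are counted.
    """
    if bin_edges is None:
        bin_edges = list(range(0, 50001, 1000))
    hist = PositionalHistogram(bin_edges=bin_edges)
    n_bins = len(bin_edges) - 1
    for ann in annotations:
        if ann.neighbor_gene_id is None or ann.distance_bp is None:
            continue
        key = (ann.gene_end, ann.orientation)
        if key not in hist.counts:
            hist.counts[key] = np.zeros(n_bins + 1, dtype=int)
        d = ann.distance_bp
        idx = bisect_left(bin_edges, d + 1) - 1  # [lo, hi) membership
        if idx >= n_bins or d >= bin_edges[-1]:
            idx = n_bins
        elif idx < 0:
            idx = 0
        hist.counts[key][idx] += 1
    return hist


def category_counts(annotations: list[NcRNAAnnotation]) -> dict[str, int]:
    counts = {c: 0 for c in CATEGORIES}
    for ann in annotations:
        counts[ann.category] += 1
    return counts
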