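"""Seeded synthetic study generator.

Emulates every input the annotation pipeline consumes: a multi-chromosome
genome with spaced multi-exon gene models, planted ncRNAs of each positional
class (with a configurable bias toward 5-kb gene-flanking regions and a
configurable sense/antisense skew), a per-base conservation track whose
score distribution depends on feature class, GO annotations with a planted
over-represented term, and a trio of "species" sharing a configurable
fraction of homologous neighbor genes.  Everything is deterministic under
the configured seed, and every planted record carries ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome_io import (
    GeneModel,
    GenomeAssembly,
    ScoreTrack,
    TranscriptRecord,
    reverse_complement,
)

DNA = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SynthConfig:
    seed: int = 0
    # genome / gene models
    n_chroms: int = 3
    chrom_len: int = 500_000
    genes_per_chrom: int = 10
    exon_count_range: tuple[int, int] = (3, 6)
    exon_len_range: tuple[int, int] = (100, 400)
    intron_len_range: tuple[int, int] = (500, 3000)
    utr_len: int = 60
    min_gene_gap: int = 16_000
    # ncRNAs
    n_ncrnas: int = 200
    class_props: dict[str, float] = field(
        default_factory=lambda: {
            "intergenic": 0.22,
            "intronic": 0.62,
            "overlapped": 0.12,
            "utr_related": 0.04,
        }
    )
    ncrna_len_range: tuple[int, int] = (200, 2000)
    spliced_fraction: float = 0.5
    noncanonical_fraction: float = 0.0
    unknown_strand_fraction: float = 0.0
    p_prox: float = 0.6  # P(intergenic ncRNA within 5 kb of a gene end)
    s3: float = 0.7  # P(sense | 3' gene-proximate)
    s5: float = 0.45  # P(sense | 5' gene-proximate)
    # conservation track
    cons_means: dict[str, float] = field(
        default_factory=lambda: {
            "coding": 3.0,
            "utr_related": 1.5,
            "intergenic": 1.0,
            "intronic": 0.5,
            "background": 0.0,
        }
    )
    cons_sd: float = 0.5
    uncovered_fraction: float = 0.1
    # cross-species trio
    trio_genes: int = 30
    trio_seq_len: int = 500
    homolog_fraction: float = 0.3
    homolog_identity: float = 85.0
    # GO annotation
    go_universe: int = 400
    go_terms: int = 30
    go_base_rate: float = 0.08
    go_fold: float = 5.0
    go_list_size: int = 40
    # coding screen candidates
    screen_len: int = 500
    orf_codons: int = 120

    def __post_init__(self) -> None:
        total = sum(self.class_props.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions must sum to 1, got {total}")
        for name in ("p_prox", "s3", "s5", "spliced_fraction",
                     "noncanonical_fraction", "unknown_strand_fraction",
                     "uncovered_fraction", "homolog_fraction", "go_base_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class GroundTruth:
    # transcript_id -> {category, strand, neighbor, distance, gene_end, proximate}
    ncrna: dict[str, dict] = field(default_factory=dict)
    # species -> gene_id -> homolog group id (None = species-specific)
    homolog_groups: dict[str, dict[str, int | None]] = field(default_factory=dict)
    planted_terms: set[str] = field(default_factory=set)
    # candidate id -> True if coding-like
    coding_labels: dict[str, bool] = field(default_factory=dict)


def _rng(cfg: SynthConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stage])


def _random_seq(rng: np.random.Generator, n: int) -> bytearray:
    return bytearray(DNA[rng.integers(0, 4, n)].tobytes())


# ---------------------------------------------------------------------------
# Genome and gene models
# ---------------------------------------------------------------------------


def generate_genome(cfg: SynthConfig) -> tuple[GenomeAssembly, list[GeneModel]]:
    """Random genome with spaced, non-overlapping multi-exon gene models.

    Gene introns receive canonical splice dinucleotides appropriate to the
    gene's strand.  Gene spacing leaves room for distal intergenic ncRNA
    placement (>= min_gene_gap between spans).
    """
    rng = _rng(cfg, 1)
    names = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    lengths = {n: cfg.chrom_len for n in names}
    seqs = {n: _random_seq(rng, cfg.chrom_len) for n in names}
    genes: list[GeneModel] = []
    gi = 0
    for chrom in names:
        cursor = int(rng.integers(6000, cfg.min_gene_gap))
        for _ in range(cfg.genes_per_chrom):
            n_exons = int(rng.integers(cfg.exon_count_range[0], cfg.exon_count_range[1] + 1))
            exon_lens = rng.integers(cfg.exon_len_range[0], cfg.exon_len_range[1] + 1, n_exons)
            intron_lens = rng.integers(
                cfg.intron_len_range[0], cfg.intron_len_range[1] + 1, n_exons - 1
            )
            gene_len = int(exon_lens.sum() + intron_lens.sum())
            if cursor + gene_len > cfg.chrom_len - 6000:
                raise ValueError(
                    f"genes do not fit on {chrom}: raise chrom_len or lower genes_per_chrom"
                )
            strand = "+" if rng.random() < 0.5 else "-"
            exons = []
            pos = cursor
            for k in range(n_exons):
                exons.append((pos, pos + int(exon_lens[k])))
                pos += int(exon_lens[k])
                if k < n_exons - 1:
                    pos += int(intron_lens[k])
            span = (cursor, pos)
            seq = seqs[chrom]
            for i0, i1 in zip((e[1] for e in exons[:-1]), (e[0] for e in exons[1:])):
                _write_motif(seq, i0, i1, strand)
            utr = cfg.utr_len
            first, last = exons[0], exons[-1]
            left = [(first[0], min(first[0] + utr, first[1]))]
            right = [(max(last[1] - utr, last[0]), last[1])]
            utr5, utr3 = (left, right) if strand == "+" else (right, left)
            gi += 1
            genes.append(
                GeneModel(
                    gene_id=f"gene{gi:04d}", symbol=f"SYM{gi:04d}", chrom=chrom,
                    strand=strand, span=span, exons=exons, utr5=utr5, utr3=utr3,
                )
            )
            cursor = pos + int(rng.integers(cfg.min_gene_gap, int(cfg.min_gene_gap * 1.5)))
    assembly = GenomeAssembly(names, lengths, {n: s.decode() for n, s in seqs.items()})
    assembly._bytes = seqs  # type: ignore[attr-defined]  # kept for in-place splice edits
    return assembly, genes


def _write_motif(seq: bytearray, i0: int, i1: int, strand: str) -> None:
    """Write GT..AG (+) or CT..AC (-) at a genomic intron [i0, i1)."""
    donor, acceptor = (b"GT", b"AG") if strand == "+" else (b"CT", b"AC")
    seq[i0 : i0 + 2] = donor
    seq[i1 - 2 : i1] = acceptor


# ---------------------------------------------------------------------------
# Planted ncRNAs
# ---------------------------------------------------------------------------


def generate_ncrnas(
    cfg: SynthConfig, assembly: GenomeAssembly, genes: list[GeneModel]
) -> tuple[list[TranscriptRecord], GroundTruth]:
    """Plant ncRNAs of each positional class with known ground truth.

    Intergenic ncRNAs land within (1, 5] kb of a random gene end with
    probability ``p_prox`` (else > 5 kb from every gene); UTR-related ones
    within 1 kb.  Strands follow the configured sense skew relative to the
    neighbor gene.  Spliced ncRNAs receive canonical splice motifs written
    into the genome sequence, so strand inference has signal.  Mutates
    ``assembly.sequence`` accordingly.
    """
    rng = _rng(cfg, 2)
    seqs: dict[str, bytearray] = getattr(
        assembly, "_bytes",
        {n: bytearray(s, "ascii") for n, s in (assembly.sequence or {}).items()},
    )
    truth = GroundTruth()
    records: list[TranscriptRecord] = []
    classes = list(cfg.class_props)
    probs = np.array([cfg.class_props[c] for c in classes])
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    # occupied intervals (per chrom) for spliced ncRNAs, to keep motifs intact
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in assembly.chrom_names}

    for idx in range(cfg.n_ncrnas):
        category = classes[int(rng.choice(len(classes), p=probs))]
        spliced = rng.random() < cfg.spliced_fraction
        # the proximate/distal decision is drawn once, outside the retry
        # loop: retrying it would bias the realized fraction away from p_prox
        # because the two placements reject at different rates
        if category == "intergenic":
            flavor = "prox" if rng.random() < cfg.p_prox else "distal"
        else:
            flavor = category
        placed = None
        for _attempt in range(300):
            placed = _try_place(cfg, rng, genes, by_chrom, assembly, flavor)
            if placed is None:
                continue
            chrom, start, end, info = placed
            if spliced and any(
                s0 < end and start < s1 for s0, s1 in occupied[chrom]
            ):
                placed = None
                continue
            break
        if placed is None:
            raise RuntimeError(f"could not place a {category} ncRNA after bounded retries")
        chrom, start, end, info = placed
        tid = f"ncrna{idx:05d}"
        strand = _pick_strand(cfg, rng, category, info)
        blocks = _make_blocks(rng, start, end, spliced, info)
        if spliced and len(blocks) > 1:
            occupied[chrom].append((start, end))
            for k in range(len(blocks) - 1):
                i0, i1 = blocks[k][1], blocks[k + 1][0]
                if rng.random() < cfg.noncanonical_fraction:
                    seqs[chrom][i0 : i0 + 2] = b"AA"
                    seqs[chrom][i1 - 2 : i1] = b"AA"
                else:
                    _write_motif(seqs[chrom], i0, i1, strand)
        emitted_strand = strand
        if rng.random() < cfg.unknown_strand_fraction:
            emitted_strand = "."
        records.append(TranscriptRecord(tid, chrom, emitted_strand, blocks, source="synthetic"))
        truth.ncrna[tid] = {
            "category": category,
            "strand": strand,
            "neighbor": info.get("neighbor"),
            "distance": info.get("distance"),
            "gene_end": info.get("gene_end"),
            "proximate": info.get("proximate", False),
        }
    assembly.sequence = {n: s.decode() for n, s in seqs.items()}
    assembly._bytes = seqs  # type: ignore[attr-defined]
    return records, truth


def _try_place(cfg, rng, genes, by_chrom, assembly, flavor):
    """One placement attempt; returns (chrom, start, end, info) or None."""
    length = int(rng.integers(cfg.ncrna_len_range[0], cfg.ncrna_len_range[1] + 1))
    if flavor == "intronic":
        g = genes[int(rng.integers(len(genes)))]
        introns = [iv for iv in g.introns if iv[1] - iv[0] >= length + 10]
        if not introns:
            introns = [iv for iv in g.introns if iv[1] - iv[0] >= cfg.ncrna_len_range[0] + 10]
            if not introns:
                return None
            i0, i1 = introns[int(rng.integers(len(introns)))]
            length = int(rng.integers(cfg.ncrna_len_range[0], i1 - i0 - 10 + 1))
        else:
            i0, i1 = introns[int(rng.integers(len(introns)))]
        start = int(rng.integers(i0 + 4, i1 - length - 4 + 1))
        return g.chrom, start, start + length, {"host": g.gene_id}
    if flavor == "overlapped":
        g = genes[int(rng.integers(len(genes)))]
        x0, x1 = g.exons[int(rng.integers(len(g.exons)))]
        # cross the exon start boundary by >= 1 bp
        over = int(rng.integers(1, min(length - 1, x1 - x0) + 1))
        start = x0 - (length - over)
        if start < 0:
            return None
        return g.chrom, start, start + length, {"host": g.gene_id}
    # flanking placements: utr_related (<= 1 kb), proximate ((1, 5] kb) or distal
    if flavor == "utr_related":
        return _place_flank(cfg, rng, genes, assembly, length, 1, 1000, False)
    if flavor == "prox":
        return _place_flank(cfg, rng, genes, assembly, length, 1001, 5000, True)
    return _place_distal(cfg, rng, genes, by_chrom, assembly, length)


def _place_flank(cfg, rng, genes, assembly, length, d_lo, d_hi, proximate):
    g = genes[int(rng.integers(len(genes)))]
    side_left = rng.random() < 0.5
    d = int(rng.integers(d_lo, d_hi + 1))
    if side_left:
        end = g.span[0] - d
        start = end - length
    else:
        start = g.span[1] + d
        end = start + length
    if start < 0 or end > assembly.chrom_lengths[g.chrom]:
        return None
    # the chosen gene must be the nearest, at the intended distance band
    dist, nearest = _min_gene_distance(genes, g.chrom, start, end)
    if nearest is not g or not (d_lo <= dist <= d_hi):
        return None
    if g.strand == "+":
        gene_end = "5prime" if side_left else "3prime"
    else:
        gene_end = "3prime" if side_left else "5prime"
    info = {"neighbor": g.gene_id, "neighbor_strand": g.strand, "distance": dist,
            "gene_end": gene_end, "proximate": proximate}
    return g.chrom, start, end, info


def _place_distal(cfg, rng, genes, by_chrom, assembly, length):
    chrom = assembly.chrom_names[int(rng.integers(len(assembly.chrom_names)))]
    start = int(rng.integers(0, assembly.chrom_lengths[chrom] - length))
    dist, nearest = _min_gene_distance(genes, chrom, start, start + length)
    if dist <= 5000 or nearest is None:
        return None
    gene_end = None
    if nearest is not None:
        mid = start + length / 2
        gmid = (nearest.span[0] + nearest.span[1]) / 2
        left = mid < gmid
        if nearest.strand == "+":
            gene_end = "5prime" if left else "3prime"
        else:
            gene_end = "3prime" if left else "5prime"
    return chrom, start, start + length, {
        "neighbor": nearest.gene_id if nearest else None,
        "neighbor_strand": nearest.strand if nearest else None,
        "distance": dist, "gene_end": gene_end, "proximate": False,
    }


def _min_gene_distance(genes, chrom, start, end):
    best, best_gene = None, None
    for g in genes:
        if g.chrom != chrom:
            continue
        gs, ge = g.span
        if end <= gs:
            d = gs - end
        elif ge <= start:
            d = start - ge
        else:
            d = 0
        key = (d, gs, g.gene_id)
        if best is None or key < best:
            best, best_gene = key, g
    if best is None:
        return float("inf"), None
    return best[0], best_gene


def _pick_strand(cfg, rng, category, info):
    gene_end = info.get("gene_end")
    neighbor_strand = info.get("neighbor_strand")
    if info.get("proximate") and neighbor_strand in ("+", "-"):
        p_sense = cfg.s3 if gene_end == "3prime" else cfg.s5
        sense = rng.random() < p_sense
        if sense:
            return neighbor_strand
        return "-" if neighbor_strand == "+" else "+"
    return "+" if rng.random() < 0.5 else "-"


def _make_blocks(rng, start, end, spliced, info):
    length = end - start
    if not spliced or length < 400:
        return [(start, end)]
    n_blocks = int(rng.integers(2, 4))
    # split the span into alternating exon/intron pieces, introns >= 50 bp
    cuts = sorted(rng.choice(np.arange(60, length - 60), size=2 * (n_blocks - 1), replace=False))
    blocks = []
    pos = start
    boundaries = [start] + [start + int(c) for c in cuts] + [end]
    for k in range(0, len(boundaries) - 1, 2):
        b0, b1 = boundaries[k], boundaries[k + 1]
        if b1 - b0 < 20:
            return [(start, end)]
        blocks.append((b0, b1))
    for k in range(len(blocks) - 1):
        if blocks[k + 1][0] - blocks[k][1] < 50:
            return [(start, end)]
    _ = pos
    return blocks


# ---------------------------------------------------------------------------
# Conservation track
# ---------------------------------------------------------------------------


def generate_score_track(
    cfg: SynthConfig,
    assembly: GenomeAssembly,
    genes: list[GeneModel],
    ncrnas: list[TranscriptRecord],
    truth: GroundTruth,
) -> ScoreTrack:
    """Per-base Normal(class mean, sd) scores with a random uncovered mask.

    Class means: background everywhere, then ncRNA blocks by their true
    class (utr_related / intergenic / intronic), then coding exons on top.
    """
    rng = _rng(cfg, 3)
    track = ScoreTrack(assembly)
    means = {c: np.full(assembly.chrom_lengths[c], cfg.cons_means["background"])
             for c in assembly.chrom_names}
    for rec in ncrnas:
        cls = truth.ncrna[rec.transcript_id]["category"]
        if cls in ("utr_related", "intergenic", "intronic"):
            for b0, b1 in rec.blocks:
                means[rec.chrom][b0:b1] = cfg.cons_means[cls]
    for g in genes:
        for x0, x1 in g.exons:
            means[g.chrom][x0:x1] = cfg.cons_means["coding"]
    for chrom in assembly.chrom_names:
        n = assembly.chrom_lengths[chrom]
        scores = means[chrom] + (rng.normal(0.0, cfg.cons_sd, n) if cfg.cons_sd > 0 else 0.0)
        covered = rng.random(n) >= cfg.uncovered_fraction
        track.scores[chrom] = np.asarray(scores, dtype=np.float64)
        track.covered[chrom] = covered
    return track


def write_score_track_bedgraph(track: ScoreTrack, path) -> None:
    """Write covered runs as bedGraph (equal adjacent values merged)."""
    with open(path, "w") as fh:
        for chrom in track.assembly.chrom_names:
            cov = track.covered[chrom]
            sc = track.scores[chrom]
            n = len(cov)
            i = 0
            while i < n:
                if not cov[i]:
                    i += 1
                    continue
                j = i + 1
                while j < n and cov[j] and sc[j] == sc[i]:
                    j += 1
                fh.write(f"{chrom}\t{i}\t{j}\t{sc[i]:.6g}\n")
                i = j


# ---------------------------------------------------------------------------
# Cross-species trio
# ---------------------------------------------------------------------------


def generate_species_trio(
    cfg: SynthConfig,
) -> tuple[dict[str, dict], GroundTruth]:
    """Three species' neighbor-gene sets sharing a fraction of homologs.

    A fraction ``homolog_fraction`` of species-A genes is copied into the
    other two species with point mutations at rate 1 - identity/100,
    retaining the gene symbol; remaining genes are independent random
    sequences with species-unique symbols.
    """
    rng = _rng(cfg, 4)
    species = ["speciesA", "speciesB", "speciesC"]
    sub_rate = 1.0 - cfg.homolog_identity / 100.0
    truth = GroundTruth()
    out: dict[str, dict] = {sp: {"genes": [], "seqs": {}} for sp in species}
    truth.homolog_groups = {sp: {} for sp in species}
    n_homologs = int(round(cfg.homolog_fraction * cfg.trio_genes))
    for i in range(cfg.trio_genes):
        base = _random_seq(rng, cfg.trio_seq_len).decode()
        conserved = i < n_homologs
        for sp_idx, sp in enumerate(species):
            gid = f"{sp}_g{i:03d}"
            if conserved:
                symbol = f"HOM{i:03d}"
                seq = base if sp_idx == 0 else _mutate(rng, base, sub_rate)
                group: int | None = i
            else:
                symbol = f"{sp.upper()}_UNIQ{i:03d}"
                seq = base if sp_idx == 0 else _random_seq(rng, cfg.trio_seq_len).decode()
                group = None
            out[sp]["genes"].append((gid, symbol))
            out[sp]["seqs"][gid] = seq
            truth.homolog_groups[sp][gid] = group
    return out, truth


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.where(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in (b"A", b"C", b"G", b"T") if b != bytes(arr[i])]
        arr[i] = choices[int(rng.integers(3))]
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# GO annotation
# ---------------------------------------------------------------------------


def generate_go_annotation(
    cfg: SynthConfig,
    list_genes: list[str] | None = None,
    universe: list[str] | None = None,
) -> tuple[dict[str, set[str]], list[str], GroundTruth]:
    """Random gene->term annotation with one planted over-represented term.

    Background term frequencies are uniform at ``go_base_rate``; the planted
    term (T000) is assigned to the designated list genes at
    ``go_fold x go_base_rate`` (capped at 1).  Returns (gene_terms,
    list_genes, truth).
    """
    rng = _rng(cfg, 5)
    if universe is None:
        universe = [f"G{i:04d}" for i in range(cfg.go_universe)]
    if list_genes is None:
        list_genes = universe[: cfg.go_list_size]
    list_set = set(list_genes)
    terms = [f"T{i:03d}" for i in range(cfg.go_terms)]
    planted = terms[0]
    p_planted_list = min(1.0, cfg.go_fold * cfg.go_base_rate)
    gene_terms: dict[str, set[str]] = {g: set() for g in universe}
    for term in terms:
        for gene in universe:
            if term == planted and gene in list_set:
                p = p_planted_list
            else:
                p = cfg.go_base_rate
            if rng.random() < p:
                gene_terms[gene].add(term)
    truth = GroundTruth()
    if cfg.go_fold > 1.0:
        truth.planted_terms = {planted}
    return gene_terms, list(list_genes), truth


# ---------------------------------------------------------------------------
# Coding-screen candidates
# ---------------------------------------------------------------------------

_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA", "ATG")
]


def generate_screen_candidates(
    cfg: SynthConfig, n_coding: int = 50, n_noncoding: int = 50
) -> tuple[dict[str, str], GroundTruth]:
    """Coding-like (planted long ORF) vs noncoding-like candidate sequences.

    Noncoding candidates contain no ATG on either strand (no CAT or ATG
    substring), so their longest ORF is zero in all six frames.
    """
    rng = _rng(cfg, 6)
    truth = GroundTruth()
    seqs: dict[str, str] = {}
    for i in range(n_coding):
        pad5 = _random_seq(rng, 30).decode()
        codons = "".join(
            _NONSTOP_CODONS[int(rng.integers(len(_NONSTOP_CODONS)))]
            for _ in range(cfg.orf_codons)
        )
        pad3 = _random_seq(rng, 30).decode()
        cid = f"coding{i:03d}"
        seqs[cid] = pad5 + "ATG" + codons + "TAA" + pad3
        truth.coding_labels[cid] = True
    for i in range(n_noncoding):
        seq = _random_seq(rng, cfg.screen_len).decode()
        seq = _strip_starts(rng, seq)
        cid = f"noncoding{i:03d}"
        seqs[cid] = seq
        truth.coding_labels[cid] = False
    return seqs, truth


def _strip_starts(rng: np.random.Generator, seq: str) -> str:
    """Remove every ATG (forward start) and CAT (reverse-strand start)."""
    arr = list(seq)
    changed = True
    while changed:
        changed = False
        s = "".join(arr)
        for motif in ("ATG", "CAT"):
            idx = s.find(motif)
            while idx != -1:
                arr[idx + 1] = {"T": "C", "A": "G"}[arr[idx + 1]]
                changed = True
                s = "".join(arr)
                idx = s.find(motif)
    return "".join(arr)


# ---------------------------------------------------------------------------
# Bundled study + file emission
# ---------------------------------------------------------------------------


@dataclass
class SynthStudy:
    cfg: SynthConfig
    assembly: GenomeAssembly
    genes: list[GeneModel]
    ncrnas: list[TranscriptRecord]
    track: ScoreTrack
    truth: GroundTruth


def generate_study(cfg: SynthConfig) -> SynthStudy:
    """Genome + genes + planted ncRNAs + conservation track, one seed."""
    assembly, genes = generate_genome(cfg)
    ncrnas, truth = generate_ncrnas(cfg, assembly, genes)
    track = generate_score_track(cfg, assembly, genes, ncrnas, truth)
    return SynthStudy(cfg, assembly, genes, ncrnas, track, truth)


def write_gff3(genes: list[GeneModel], path) -> None:
    """Write gene models as GFF3 (1-based inclusive on output)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.span[0], g.gene_id)):
            s, e = g.span
            fh.write(f"{g.chrom}\tsynth\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                     f"ID={g.gene_id};Name={g.symbol}\n")
            for x0, x1 in g.exons:
                fh.write(f"{g.chrom}\tsynth\texon\t{x0 + 1}\t{x1}\t.\t{g.strand}\t.\t"
                         f"Parent={g.gene_id}\n")
            for u0, u1 in g.utr5:
                fh.write(f"{g.chrom}\tsynth\tfive_prime_UTR\t{u0 + 1}\t{u1}\t.\t{g.strand}\t.\t"
                         f"Parent={g.gene_id}\n")
            for u0, u1 in g.utr3:
                fh.write(f"{g.chrom}\tsynth\tthree_prime_UTR\t{u0 + 1}\t{u1}\t.\t{g.strand}\t.\t"
                         f"Parent={g.gene_id}\n")


def write_truth_tsv(truth: GroundTruth, path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tcategory\tstrand\tneighbor\tdistance\tgene_end\tproximate\n")
        for tid in sorted(truth.ncrna):
            t = truth.ncrna[tid]
            fh.write(
                f"{tid}\t{t['category']}\t{t['strand']}\t{t['neighbor'] or '.'}\t"
                f"{t['distance'] if t['distance'] is not None else '.'}\t"
                f"{t['gene_end'] or '.'}\t{int(t['proximate'])}\n"
            )


def write_study(study: SynthStudy, outdir) -> dict[str, str]:
    """Emit the study in the formats the pipeline reads; returns the paths."""
    from pathlib import Path

    from .genome_io import write_fasta, write_intervals

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": str(out / "genome.fa"),
        "genes": str(out / "genes.gff3"),
        "ncrnas": str(out / "ncrnas.bed"),
        "track": str(out / "conservation.bedgraph"),
        "truth": str(out / "truth.tsv"),
    }
    write_fasta(study.assembly.sequence or {}, paths["genome"])
    write_gff3(study.genes, paths["genes"])
    write_intervals(study.ncrnas, paths["ncrnas"])
    write_score_track_bedgraph(study.track, paths["track"])
    write_truth_tsv(study.truth, paths["truth"])
    return paths
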