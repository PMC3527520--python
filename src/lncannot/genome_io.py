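"""Genomic file formats and the pipeline's coordinate convention.

Every interval inside the package is 0-based, half-open ``[start, end)``.
Conversion from 1-based conventions (GFF3, wiggle) happens here, at the
parse/write boundary, and nowhere else.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

log = logging.getLogger(__name__)

Interval = tuple[int, int]


class ParseError(ValueError):
    """A file did not parse under the declared dialect."""


class ValidationError(ValueError):
    """Parsed content violates an internal invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class GenomeAssembly:
    """Chromosome names/lengths, optionally with nucleotide sequence."""

    chrom_names: list[str]
    chrom_lengths: dict[str, int]
    sequence: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValidationError("duplicate chromosome identifiers")
        for name in self.chrom_names:
            length = self.chrom_lengths.get(name)
            if length is None or length <= 0:
                raise ValidationError(f"chromosome {name!r} has non-positive length")
            if self.sequence is not None and name in self.sequence:
                if len(self.sequence[name]) != length:
                    raise ValidationError(
                        f"sequence length mismatch for {name!r}: "
                        f"{len(self.sequence[name])} != {length}"
                    )


@dataclass
class GeneModel:
    """A protein-coding gene: span, strand, exons and UTR intervals.

    Exons are disjoint, sorted ``[start, end)`` intervals inside the span;
    UTR intervals are contained in exons.  Strand is always known.
    """

    gene_id: str
    symbol: str
    chrom: str
    strand: str
    span: Interval
    exons: list[Interval]
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand must be +/-")
        s, e = self.span
        prev_end = None
        for x0, x1 in self.exons:
            if x0 < s or x1 > e:
                raise ValidationError(f"gene {self.gene_id}: exon outside span")
            if x1 <= x0:
                raise ValidationError(f"gene {self.gene_id}: empty exon")
            if prev_end is not None and x0 < prev_end:
                raise ValidationError(f"gene {self.gene_id}: exons overlap/unsorted")
            prev_end = x1
        for utr in (*self.utr5, *self.utr3):
            if not any(x0 <= utr[0] and utr[1] <= x1 for x0, x1 in self.exons):
                raise ValidationError(f"gene {self.gene_id}: UTR outside exons")

    @property
    def introns(self) -> list[Interval]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
            if self.exons[i + 1][0] > self.exons[i][1]
        ]

    @property
    def tss(self) -> int:
        """Transcription start position (strand-aware)."""
        return self.span[0] if self.strand == "+" else self.span[1] - 1


@dataclass
class TranscriptRecord:
    """A candidate ncRNA: chromosome, sorted disjoint blocks, maybe-unknown strand."""

    transcript_id: str
    chrom: str
    strand: str  # '+', '-' or '.'
    blocks: list[Interval]
    source: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"{self.transcript_id}: bad strand {self.strand!r}")
        if not self.blocks:
            raise ValidationError(f"{self.transcript_id}: no blocks")
        prev_end = None
        for b0, b1 in self.blocks:
            if b1 <= b0:
                raise ValidationError(f"{self.transcript_id}: empty block")
            if prev_end is not None and b0 < prev_end:
                raise ValidationError(f"{self.transcript_id}: blocks overlap/unsorted")
            prev_end = b1

    @property
    def span(self) -> Interval:
        return (self.blocks[0][0], self.blocks[-1][1])

    @property
    def length(self) -> int:
        return sum(b1 - b0 for b0, b1 in self.blocks)

    @property
    def introns(self) -> list[Interval]:
        return [
            (self.blocks[i][1], self.blocks[i + 1][0])
            for i in range(len(self.blocks) - 1)
            if self.blocks[i + 1][0] > self.blocks[i][1]
        ]


class ScoreTrack:
    """Per-base scores with a coverage mask, dense per chromosome."""

    def __init__(self, assembly: GenomeAssembly):
        self.assembly = assembly
        self.scores: dict[str, np.ndarray] = {}
        self.covered: dict[str, np.ndarray] = {}
        for name in assembly.chrom_names:
            n = assembly.chrom_lengths[name]
            self.scores[name] = np.zeros(n, dtype=np.float64)
            self.covered[name] = np.zeros(n, dtype=bool)

    def set_interval(self, chrom: str, start: int, end: int, value) -> None:
        n = self.assembly.chrom_lengths.get(chrom)
        if n is None:
            raise ValidationError(f"unknown chromosome {chrom!r}")
        if start < 0 or end > n or end <= start:
            raise ValidationError(f"interval {chrom}:{start}-{end} out of bounds (len {n})")
        if not np.all(np.isfinite(value)):
            raise ValidationError(f"non-finite score at {chrom}:{start}-{end}")
        self.scores[chrom][start:end] = value
        self.covered[chrom][start:end] = True


# ---------------------------------------------------------------------------
# Parsers
# ---------------------------------------------------------------------------


def _split_fields(line: str, lineno: int, min_fields: int, what: str) -> list[str]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) == 1:  # tolerate whitespace-separated fixtures
        fields = line.split()
    if len(fields) < min_fields:
        raise ParseError(f"line {lineno}: expected >= {min_fields} {what} fields, got {len(fields)}")
    return fields


def _int_field(value: str, lineno: int, what: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise ParseError(f"line {lineno}: non-integer {what}: {value!r}") from None


def _parse_gff3_attrs(attrs: str) -> dict[str, str]:
    out = {}
    for part in attrs.strip().split(";"):
        part = part.strip()
        if part and "=" in part:
            key, val = part.split("=", 1)
            out[key] = val
    return out


def parse_gene_models(path: str | Path, dialect: str = "gff3") -> list[GeneModel]:
    """Read protein-coding gene models from GFF3 or BED12.

    GFF3 coordinates (1-based inclusive) are converted to 0-based half-open.
    In BED12, the thick region is taken as CDS and blocks minus thick as
    UTRs.  Genes with missing strand are rejected.
    """
    if dialect == "gff3":
        return _parse_gene_models_gff3(path)
    if dialect == "bed12":
        return _parse_gene_models_bed12(path)
    raise ValueError(f"unknown gene-model dialect {dialect!r}")


def _parse_gene_models_gff3(path: str | Path) -> list[GeneModel]:
    genes: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = _split_fields(line, lineno, 9, "GFF3")
            chrom, _src, ftype, start_s, end_s, _score, strand, _frame, attrs_s = f[:9]
            start = _int_field(start_s, lineno, "start")
            end = _int_field(end_s, lineno, "end")
            if start < 1 or end < start:
                raise ParseError(f"line {lineno}: bad GFF3 coordinates {start}..{end}")
            iv = (start - 1, end)  # GFF3 is 1-based inclusive
            attrs = _parse_gff3_attrs(attrs_s)
            if ftype == "gene":
                gid = attrs.get("ID")
                if gid is None:
                    raise ParseError(f"line {lineno}: gene feature without ID")
                if strand not in ("+", "-"):
                    raise ParseError(f"line {lineno}: gene {gid} with missing strand")
                genes[gid] = {
                    "symbol": attrs.get("Name", gid),
                    "chrom": chrom,
                    "strand": strand,
                    "span": iv,
                    "exons": [],
                    "utr5": [],
                    "utr3": [],
                }
                order.append(gid)
            elif ftype in ("exon", "five_prime_UTR", "three_prime_UTR"):
                parent = attrs.get("Parent")
                if parent is None or parent not in genes:
                    raise ParseError(f"line {lineno}: {ftype} with unknown Parent")
                key = {"exon": "exons", "five_prime_UTR": "utr5", "three_prime_UTR": "utr3"}[ftype]
                genes[parent][key].append(iv)
    out = []
    for gid in order:
        g = genes[gid]
        s, e = g["span"]
        exons = sorted(g["exons"])
        if not exons:
            exons = [g["span"]]
        for x0, x1 in exons:
            if x0 < s or x1 > e:
                raise ValidationError(f"gene {gid}: exon [{x0},{x1}) outside span [{s},{e})")
        out.append(
            GeneModel(
                gene_id=gid, symbol=g["symbol"], chrom=g["chrom"], strand=g["strand"],
                span=g["span"], exons=exons,
                utr5=sorted(g["utr5"]), utr3=sorted(g["utr3"]),
            )
        )
    return out


def _bed12_blocks(fields: Sequence[str], lineno: int) -> list[Interval]:
    start = _int_field(fields[1], lineno, "start")
    end = _int_field(fields[2], lineno, "end")
    n_blocks = _int_field(fields[9], lineno, "blockCount")
    sizes = [_int_field(x, lineno, "blockSize") for x in fields[10].rstrip(",").split(",")]
    offsets = [_int_field(x, lineno, "blockStart") for x in fields[11].rstrip(",").split(",")]
    if len(sizes) != n_blocks or len(offsets) != n_blocks:
        raise ParseError(f"line {lineno}: blockCount inconsistent with block lists")
    blocks = [(start + off, start + off + size) for off, size in zip(offsets, sizes)]
    if blocks[0][0] != start or blocks[-1][1] != end:
        raise ParseError(f"line {lineno}: blocks inconsistent with span")
    return blocks


def _parse_gene_models_bed12(path: str | Path) -> list[GeneModel]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = _split_fields(line, lineno, 12, "BED12")
            chrom, start_s, end_s, name, _score, strand = f[:6]
            if strand not in ("+", "-"):
                raise ParseError(f"line {lineno}: gene {name} with missing strand")
            start = _int_field(start_s, lineno, "start")
            end = _int_field(end_s, lineno, "end")
            thick_start = _int_field(f[6], lineno, "thickStart")
            thick_end = _int_field(f[7], lineno, "thickEnd")
            blocks = _bed12_blocks(f, lineno)
            # blocks minus the thick (CDS) region are UTR; the left genomic
            # side is 5' on + genes and 3' on - genes
            left, right = [], []
            for b0, b1 in blocks:
                if b0 < thick_start:
                    left.append((b0, min(b1, thick_start)))
                if b1 > thick_end:
                    right.append((max(b0, thick_end), b1))
            utr5, utr3 = (left, right) if strand == "+" else (right, left)
            out.append(
                GeneModel(
                    gene_id=name, symbol=name, chrom=chrom, strand=strand,
                    span=(start, end), exons=blocks, utr5=utr5, utr3=utr3,
                )
            )
    return out


def parse_intervals(path: str | Path) -> list[TranscriptRecord]:
    """Read BED6 or BED12 transcript intervals; '.' strand means unknown."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = _split_fields(line, lineno, 3, "BED")
            chrom = f[0]
            start = _int_field(f[1], lineno, "start")
            end = _int_field(f[2], lineno, "end")
            if end <= start:
                raise ParseError(f"line {lineno}: empty interval")
            name = f[3] if len(f) > 3 else f"iv{lineno}"
            strand = f[5] if len(f) > 5 else "."
            if strand not in ("+", "-", "."):
                raise ParseError(f"line {lineno}: bad strand {strand!r}")
            if len(f) >= 12:
                blocks = _bed12_blocks(f, lineno)
            else:
                blocks = [(start, end)]
            out.append(TranscriptRecord(name, chrom, strand, blocks))
    return out


def parse_score_track(path: str | Path, assembly: GenomeAssembly) -> ScoreTrack:
    """Read a bedGraph or fixed/variable-step wiggle file into a ScoreTrack.

    Overlapping bedGraph records: last record wins (a warning is logged).
    Wiggle coordinates are 1-based and converted here.
    """
    track = ScoreTrack(assembly)
    mode = "bedgraph"
    chrom = None
    pos = 0
    step = span = 1
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                params = dict(p.split("=") for p in line.split()[1:])
                chrom = params["chrom"]
                pos = int(params.get("start", 1)) - 1
                step = int(params.get("step", 1))
                span = int(params.get("span", 1))
                mode = "fixed"
                continue
            if line.startswith("variableStep"):
                params = dict(p.split("=") for p in line.split()[1:])
                chrom = params["chrom"]
                span = int(params.get("span", 1))
                mode = "variable"
                continue
            fields = line.split()
            if mode == "fixed":
                value = float(fields[0])
                _warn_if_overwritten(track, chrom, pos, pos + span, lineno)
                track.set_interval(chrom, pos, pos + span, value)
                pos += step
            elif mode == "variable":
                start = _int_field(fields[0], lineno, "position") - 1
                value = float(fields[1])
                _warn_if_overwritten(track, chrom, start, start + span, lineno)
                track.set_interval(chrom, start, start + span, value)
            else:
                f = _split_fields(line, lineno, 4, "bedGraph")
                start = _int_field(f[1], lineno, "start")
                end = _int_field(f[2], lineno, "end")
                _warn_if_overwritten(track, f[0], start, end, lineno)
                track.set_interval(f[0], start, end, float(f[3]))
    return track


def _warn_if_overwritten(track: ScoreTrack, chrom: str, start: int, end: int, lineno: int) -> None:
    if chrom in track.covered and 0 <= start < end <= len(track.covered[chrom]):
        if track.covered[chrom][start:end].any():
            log.warning("line %d: overlapping score interval %s:%d-%d (last value wins)",
                        lineno, chrom, start, end)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_intervals(records: Iterable[TranscriptRecord], path: str | Path,
                    name_suffix: dict[str, str] | None = None) -> None:
    """Write records as BED12, sorted by (chrom, start, id) for determinism.

    ``name_suffix`` optionally appends ``|value`` to the name column
    (used to carry category labels).
    """
    recs = sorted(records, key=lambda r: (r.chrom, r.span[0], r.transcript_id))
    with open(path, "w") as fh:
        for r in recs:
            start, end = r.span
            name = r.transcript_id
            if name_suffix and r.transcript_id in name_suffix:
                name = f"{name}|{name_suffix[r.transcript_id]}"
            sizes = ",".join(str(b1 - b0) for b0, b1 in r.blocks) + ","
            offsets = ",".join(str(b0 - start) for b0, b1 in r.blocks) + ","
            fh.write(
                "\t".join(
                    [r.chrom, str(start), str(end), name, "0", r.strand,
                     str(start), str(end), "0", str(len(r.blocks)), sizes, offsets]
                )
                + "\n"
            )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> uppercase sequence mapping."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sorted(seqs):
            fh.write(f">{name}\n")
            seq = seqs[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def spliced_sequence(record: TranscriptRecord, assembly: GenomeAssembly) -> str:
    """Exonic sequence of a transcript, reverse-complemented on the - strand."""
    if assembly.sequence is None or record.chrom not in assembly.sequence:
        raise ValidationError(f"no sequence for chromosome {record.chrom!r}")
    chrom_seq = assembly.sequence[record.chrom]
    seq = "".join(chrom_seq[b0:b1] for b0, b1 in record.blocks)
    if record.strand == "-":
        seq = reverse_complement(seq)
    return seq


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
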