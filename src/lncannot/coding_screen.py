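"""Protein-coding screens for candidate ncRNAs.

Two filters: a similarity screen against known transcripts (local alignment,
query identity/coverage thresholds) and a six-frame ORF screen.  A candidate
failing either is removed as putatively protein-coding.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

from .genome_io import reverse_complement

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass
class AlignmentStats:
    query_id: str
    subject_id: str
    identity: float  # percent of aligned columns that match (N never matches)
    coverage: float  # percent of the query inside the aligned region
    aligned_length: int
    score: float = 0.0


@dataclass
class OrfReport:
    transcript_id: str
    longest_orf_aa: int
    frame: str  # +1 +2 +3 -1 -2 -3


@dataclass
class ScreenConfig:
    identity_threshold: float = 90.0
    coverage_threshold: float = 90.0
    orf_aa_threshold: int = 100
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -1.0

    def __post_init__(self) -> None:
        if not (0 <= self.identity_threshold <= 100 and 0 <= self.coverage_threshold <= 100):
            raise ValueError("thresholds must be in [0, 100]")
        if self.orf_aa_threshold < 0:
            raise ValueError("orf_aa_threshold must be >= 0")


def _make_aligner(cfg: ScreenConfig) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    # ACGTN matrix: match score on the diagonal except N, which never matches
    mat = substitution_matrices.Array("ACGTN", dims=2)
    for a in "ACGTN":
        for b in "ACGTN":
            mat[a, b] = cfg.match if (a == b and a != "N") else cfg.mismatch
    aligner.substitution_matrix = mat
    aligner.open_gap_score = cfg.gap_open
    aligner.extend_gap_score = cfg.gap_extend
    return aligner


def local_alignment_stats(
    query: str,
    subject: str,
    query_id: str = "query",
    subject_id: str = "subject",
    cfg: ScreenConfig | None = None,
) -> AlignmentStats:
    """Best local alignment of query vs subject with identity and query coverage.

    Scoring defaults: match +1, mismatch -1, gap open -2, gap extend -1
    (a gap of length L costs open + (L-1)*extend).  Identity is the percent
    of aligned columns (gap columns included) whose residues match; coverage
    is the percent of the query length spanned by the aligned region.
    """
    if not query or not subject:
        raise ValueError("sequences must be non-empty")
    cfg = cfg or ScreenConfig()
    query = query.upper()
    subject = subject.upper()
    aligner = _make_aligner(cfg)
    score = aligner.score(query, subject)
    if score <= 0:
        return AlignmentStats(query_id, subject_id, 0.0, 0.0, 0, 0.0)
    aln = aligner.align(query, subject)[0]
    qa, sa = str(aln[0]), str(aln[1])
    columns = len(qa)
    matches = sum(1 for a, b in zip(qa, sa) if a == b and a not in ("-", "N"))
    q_start, q_end = aln.aligned[0][0][0], aln.aligned[0][-1][1]
    identity = 100.0 * matches / columns if columns else 0.0
    coverage = 100.0 * (q_end - q_start) / len(query)
    return AlignmentStats(query_id, subject_id, identity, coverage, columns, float(score))


def best_local_alignment(
    query: str,
    targets: dict[str, str],
    query_id: str = "query",
    cfg: ScreenConfig | None = None,
) -> AlignmentStats | None:
    """Stats of the best-scoring target (score prescreen, one traceback).

    Ties break by target id.  Returns None when ``targets`` is empty.
    """
    if not targets:
        return None
    cfg = cfg or ScreenConfig()
    aligner = _make_aligner(cfg)
    q = query.upper()
    best_id, best_score = None, -1.0
    for tid in sorted(targets):
        score = aligner.score(q, targets[tid].upper())
        if score > best_score:
            best_id, best_score = tid, score
    assert best_id is not None
    return local_alignment_stats(q, targets[best_id], query_id, best_id, cfg)


def find_longest_orf(seq: str, transcript_id: str = "") -> OrfReport:
    """Longest ATG..stop ORF over all six reading frames.

    The stop codon is not counted in the amino-acid length.  Ties break by
    frame order +1, +2, +3, -1, -2, -3.  An ORF requires an in-frame stop.
    """
    seq = seq.upper()
    best_aa, best_frame = 0, "+1"
    frames = [("+1", seq, 0), ("+2", seq, 1), ("+3", seq, 2)]
    rc = reverse_complement(seq)
    frames += [("-1", rc, 0), ("-2", rc, 1), ("-3", rc, 2)]
    for frame_name, s, offset in frames:
        aa = _longest_orf_in_frame(s, offset)
        if aa > best_aa:
            best_aa, best_frame = aa, frame_name
    return OrfReport(transcript_id, best_aa, best_frame)


def _longest_orf_in_frame(seq: str, offset: int) -> int:
    best = 0
    start = None
    for i in range(offset, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if start is None:
            if codon == "ATG":
                start = i
        elif codon in STOP_CODONS:
            best = max(best, (i - start) // 3)
            start = None
    return best


def filter_noncoding(
    candidates: dict[str, str],
    references: dict[str, str],
    cfg: ScreenConfig | None = None,
) -> tuple[list[str], list[dict]]:
    """Partition candidate ids into retained (noncoding) and removed (coding).

    A candidate is removed iff some reference alignment exceeds both the
    identity and coverage thresholds, or its longest six-frame ORF reaches
    the amino-acid threshold.  Returns (retained ids, removal records).
    """
    cfg = cfg or ScreenConfig()
    retained: list[str] = []
    removed: list[dict] = []
    for cid in candidates:
        seq = candidates[cid]
        if not seq:
            raise ValueError(f"candidate {cid!r} has no sequence")
        best_ident, best_cov, best_ref = 0.0, 0.0, ""
        reason = None
        for rid, rseq in references.items():
            stats = local_alignment_stats(seq, rseq, cid, rid, cfg)
            if stats.identity > best_ident or (
                stats.identity == best_ident and stats.coverage > best_cov
            ):
                best_ident, best_cov, best_ref = stats.identity, stats.coverage, rid
            if (
                stats.identity > cfg.identity_threshold
                and stats.coverage > cfg.coverage_threshold
            ):
                reason = "similarity"
                best_ident, best_cov, best_ref = stats.identity, stats.coverage, rid
                break
        orf = find_longest_orf(seq, cid)
        if reason is None and orf.longest_orf_aa >= cfg.orf_aa_threshold:
            reason = "orf"
        if reason is None:
            retained.append(cid)
        else:
            removed.append(
                {
                    "transcript_id": cid,
                    "reason": reason,
                    "best_identity": round(best_ident, 2),
                    "best_coverage": round(best_cov, 2),
                    "best_reference": best_ref,
                    "longest_orf_aa": orf.longest_orf_aa,
                }
            )
    return retained, removed
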