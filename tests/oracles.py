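"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a quantity by the most direct method available
(naive loops, per-base scans, exhaustive enumeration) and shares no code
with the implementation it checks.
"""

from __future__ import annotations

from math import comb


def smith_waterman_score(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -2.0,
    gap_extend: float = -1.0,
) -> float:
    """Optimal local alignment score, affine gaps (first gap base costs
    gap_open, each further base gap_extend).  N never matches anything.
    Pure-Python Gotoh recursion."""
    n, m = len(a), len(b)
    neg = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a (horizontal)
    F = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b (vertical)
    best = 0.0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = match if (ai == b[j - 1] and ai != "N") else mismatch
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


def longest_orf_scan(seq: str) -> int:
    """Longest ORF in amino acids over all six frames by exhaustive scan:
    enumerate every ATG and walk to the next in-frame stop."""
    comp = str.maketrans("ACGTN", "TGCAN")
    best = 0
    for s in (seq.upper(), seq.upper().translate(comp)[::-1]):
        for start in range(len(s) - 2):
            if s[start : start + 3] != "ATG":
                continue
            for j in range(start + 3, len(s) - 2, 3):
                if s[j : j + 3] in ("TAA", "TAG", "TGA"):
                    best = max(best, (j - start) // 3)
                    break
    return best


def classify_per_base(transcript, genes) -> str:
    """Positional class by per-base membership: any exonic base ->
    overlapped; else span fully inside some gene span -> intronic; else
    intergenic."""
    exonic = set()
    for g in genes:
        if g.chrom != transcript.chrom:
            continue
        for x0, x1 in g.exons:
            exonic.update(range(x0, x1))
    for b0, b1 in transcript.blocks:
        if any(p in exonic for p in range(b0, b1)):
            return "overlapped"
    s, e = transcript.span
    for g in genes:
        if g.chrom == transcript.chrom and g.span[0] <= s and e <= g.span[1]:
            return "intronic"
    return "intergenic"


def naive_interval_mean(transcript, track) -> tuple[float, float]:
    """(mean over covered bases, covered fraction) by a per-position loop."""
    total, n_cov, n_bases = 0.0, 0, 0
    scores = track.scores[transcript.chrom]
    covered = track.covered[transcript.chrom]
    for b0, b1 in transcript.blocks:
        for p in range(b0, b1):
            n_bases += 1
            if covered[p]:
                total += float(scores[p])
                n_cov += 1
    if n_cov == 0:
        return float("nan"), 0.0
    return total / n_cov, n_cov / n_bases


def all_pairs_overlaps(ours, theirs) -> set[tuple[str, str]]:
    """Every (our id, their id) pair with >= 1 bp span overlap, O(n*m)."""
    pairs = set()
    for a in ours:
        s0, e0 = a.span
        for b in theirs:
            if a.chrom != b.chrom:
                continue
            s1, e1 = b.span
            if s0 < e1 and s1 < e0:
                pairs.add((a.transcript_id, b.transcript_id))
    return pairs


def venn_tally(ours, datasets) -> dict[frozenset, int]:
    """Exclusive-subset counts by brute-force membership vectors."""
    counts: dict[frozenset, int] = {}
    for a in ours:
        member = frozenset(
            name for name, recs in datasets.items()
            if any(
                a.chrom == b.chrom and a.span[0] < b.span[1] and b.span[0] < a.span[1]
                for b in recs
            )
        )
        if member:
            counts[member] = counts.get(member, 0) + 1
    return counts


def hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), by explicit summation."""
    if k <= 0:
        return 1.0
    hi = min(K, n)
    if k > hi:
        return 0.0
    return sum(comb(K, x) * comb(N - K, n - x) for x in range(k, hi + 1)) / comb(N, n)


def ease_by_summation(k: int, n: int, K: int, N: int) -> float:
    """EASE score by the decrement-then-tail definition, independent path."""
    return hypergeom_tail(max(k - 1, 0), n, K, N)
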