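"""Overlap accounting between our ncRNAs and external long-ncRNA datasets.

Overlap is span-based, strand-agnostic, >= 1 bp.  Each of our ncRNAs is
counted once per dataset regardless of how many external records it hits;
the intergenic percentage is taken over all intergenic ncRNAs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

from intervaltree import IntervalTree

from .classify import NcRNAAnnotation
from .genome_io import TranscriptRecord
from .reporting import percentage


@dataclass
class OverlapPairing:
    ours_to_theirs: dict[str, set[str]]
    theirs_to_ours: dict[str, set[str]]


@dataclass
class OverlapReport:
    dataset_name: str
    intronic: int
    overlapped: int
    utr_related: int
    intergenic: int
    intergenic_percent: float | None  # None when there is no intergenic ncRNA
    total: int
    reciprocal_count: int


@dataclass
class VennCounts:
    dataset_names: list[str]
    # frozenset of dataset names -> number of our ncRNAs overlapping exactly that subset
    counts: dict[frozenset, int] = field(default_factory=dict)

    def n_overlapping_any(self) -> int:
        return sum(self.counts.values())


def overlap_datasets(
    ours: list[TranscriptRecord], theirs: list[TranscriptRecord]
) -> OverlapPairing:
    """All >= 1 bp span overlaps between our records and an external dataset."""
    trees: dict[str, IntervalTree] = {}
    for rec in theirs:
        s, e = rec.span
        trees.setdefault(rec.chrom, IntervalTree()).addi(s, e, rec.transcript_id)
    ours_to_theirs: dict[str, set[str]] = {}
    theirs_to_ours: dict[str, set[str]] = {}
    for rec in ours:
        tree = trees.get(rec.chrom)
        if tree is None:
            continue
        s, e = rec.span
        hits = {iv.data for iv in tree.overlap(s, e)}
        if hits:
            ours_to_theirs[rec.transcript_id] = hits
            for h in hits:
                theirs_to_ours.setdefault(h, set()).add(rec.transcript_id)
    return OverlapPairing(ours_to_theirs, theirs_to_ours)


def category_report(
    pairing: OverlapPairing,
    annotations: list[NcRNAAnnotation],
    total_intergenic: int,
    dataset_name: str = "",
) -> OverlapReport:
    """Per-category counts of our ncRNAs hitting the dataset, with the
    intergenic percentage over all intergenic ncRNAs."""
    by_id = {a.transcript_id: a.category for a in annotations}
    counts = {"intronic": 0, "overlapped": 0, "utr_related": 0, "intergenic": 0}
    for tid in pairing.ours_to_theirs:
        cat = by_id.get(tid)
        if cat in counts:
            counts[cat] += 1
    percent = (
        percentage(counts["intergenic"], total_intergenic)
        if total_intergenic > 0
        else None
    )
    return OverlapReport(
        dataset_name=dataset_name,
        intronic=counts["intronic"],
        overlapped=counts["overlapped"],
        utr_related=counts["utr_related"],
        intergenic=counts["intergenic"],
        intergenic_percent=percent,
        total=sum(counts.values()),
        reciprocal_count=len(pairing.theirs_to_ours),
    )


def venn_counts(
    ours: list[TranscriptRecord], datasets: dict[str, list[TranscriptRecord]]
) -> VennCounts:
    """Exclusive-subset counts of our ncRNAs over the given datasets.

    Each of our records is assigned to the exact subset of datasets it
    overlaps; records hitting no dataset are not counted.
    """
    if len(datasets) > 5:
        raise ValueError("venn counting supports at most 5 datasets")
    membership: dict[str, set[str]] = {}
    for name, recs in datasets.items():
        pairing = overlap_datasets(ours, recs)
        for tid in pairing.ours_to_theirs:
            membership.setdefault(tid, set()).add(name)
    counts: dict[frozenset, int] = {}
    names = list(datasets)
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            counts[frozenset(combo)] = 0
    for subset in membership.values():
        counts[frozenset(subset)] += 1
    return VennCounts(names, {k: v for k, v in counts.items() if v or len(k) == 1})
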