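"""Cross-species conservation of ncRNA neighbor genes.

Two routes: symbol intersection (case-insensitive) across species, and
sequence similarity — a neighbor gene counts as conserved when its best
local alignment against every other species' neighbor-gene set exceeds the
identity and coverage thresholds (both default 60%, measured on the query).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

from .coding_screen import ScreenConfig, best_local_alignment


@dataclass
class NeighborGeneSet:
    species: str
    end: str  # 5prime / 3prime
    genes: list[tuple[str, str]]  # (gene_id, symbol)
    sequences: dict[str, str] = field(default_factory=dict)  # gene_id -> sequence

    def __post_init__(self) -> None:
        ids = [g for g, _ in self.genes]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate gene ids in {self.species}/{self.end} set")

    @property
    def symbols(self) -> set[str]:
        return {sym.casefold() for _, sym in self.genes}


@dataclass
class ConservationMatch:
    gene_id: str
    symbol: str
    matches: dict[str, dict]  # species -> {"gene_id", "identity", "coverage"}
    conserved: bool


def symbol_intersection(
    sets: list[NeighborGeneSet],
) -> tuple[set[str], dict[frozenset, set[str]]]:
    """Case-folded symbol intersection across all species, plus pairwise regions.

    Returns (symbols common to every species, {frozenset of species ->
    symbols shared by exactly those pairs-or-more intersections}) — the
    Venn-region building blocks.
    """
    if len(sets) < 2:
        raise ValueError("need >= 2 species")
    by_species = {s.species: s.symbols for s in sets}
    common = set.intersection(*by_species.values())
    pairwise: dict[frozenset, set[str]] = {}
    for r in range(2, len(by_species) + 1):
        for combo in combinations(by_species, r):
            pairwise[frozenset(combo)] = set.intersection(
                *(by_species[sp] for sp in combo)
            )
    return common, pairwise


def sequence_conserved_neighbors(
    query_set: NeighborGeneSet,
    target_sets: list[NeighborGeneSet],
    identity_threshold: float = 60.0,
    coverage_threshold: float = 60.0,
    require_all_species: bool = True,
    cfg: ScreenConfig | None = None,
) -> list[ConservationMatch]:
    """Per query gene, best alignment against each other species' set.

    A gene is conserved iff the thresholds are exceeded in every other
    species (or any, with ``require_all_species=False``).  Genes without a
    sequence are excluded with a flag entry.
    """
    cfg = cfg or ScreenConfig()
    out = []
    for gene_id, symbol in query_set.genes:
        qseq = query_set.sequences.get(gene_id)
        if not qseq:
            out.append(ConservationMatch(gene_id, symbol, {"_missing_sequence": {}}, False))
            continue
        per_species: dict[str, dict] = {}
        passed_species = []
        for tset in target_sets:
            targets = {tid: tset.sequences[tid] for tid, _ in tset.genes
                       if tset.sequences.get(tid)}
            best = best_local_alignment(qseq, targets, gene_id, cfg)
            if best is None:
                per_species[tset.species] = {}
                continue
            per_species[tset.species] = {
                "gene_id": best.subject_id,
                "identity": round(best.identity, 2),
                "coverage": round(best.coverage, 2),
            }
            if best.identity > identity_threshold and best.coverage > coverage_threshold:
                passed_species.append(tset.species)
        if require_all_species:
            conserved = len(passed_species) == len(target_sets) and target_sets != []
        else:
            conserved = bool(passed_species)
        out.append(ConservationMatch(gene_id, symbol, per_species, conserved))
    return out


def conserved_accounting(
    matches_5prime: list[ConservationMatch],
    matches_3prime: list[ConservationMatch],
) -> dict[str, int]:
    """Per-end conserved neighbor-gene counts and their sum."""
    n5 = sum(1 for m in matches_5prime if m.conserved)
    n3 = sum(1 for m in matches_3prime if m.conserved)
    return {"conserved_5prime": n5, "conserved_3prime": n3, "conserved_total": n5 + n3}
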