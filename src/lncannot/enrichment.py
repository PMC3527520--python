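"""GO over-representation of neighbor-gene lists with the EASE score.

The EASE score is a conservative variant of the one-sided Fisher exact
test: one gene is removed from the list-hit cell before computing the
hypergeometric enrichment tail, so a single-hit term can never look
significant.  Terms pass in "catalog mode" when the list hit count
exceeds 5 and the EASE p-value is below 0.05 (raw, no multiple-testing
correction); a Benjamini-Hochberg column is emitted alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from scipy import stats as sps


@dataclass
class GoAnnotation:
    gene_terms: dict[str, set[str]]  # gene -> term ids
    term_names: dict[str, str] = field(default_factory=dict)

    @property
    def universe(self) -> set[str]:
        return set(self.gene_terms)

    def genes_for_term(self, term: str) -> set[str]:
        return {g for g, ts in self.gene_terms.items() if term in ts}


@dataclass
class EnrichmentResult:
    term: str
    name: str
    list_hits: int  # k
    list_size: int  # n
    background_hits: int  # K
    background_size: int  # N
    ease_p: float
    bh_q: float = 1.0
    significant: bool = False


@dataclass
class EnrichConfig:
    min_count: int = 6  # "gene count > 5"
    p_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")


def ease_pvalue(k: int, n: int, K: int, N: int) -> float:
    """EASE score: one-sided Fisher enrichment p with k decremented by one.

    k list hits out of a list of n, K background hits out of N; margins are
    kept and the upper hypergeometric tail P(X >= k-1) is returned.
    k = 0 (and k = 1, by the decrement) give p = 1.
    """
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValueError(f"inconsistent margins k={k} n={n} K={K} N={N}")
    k_adj = max(k - 1, 0)
    if k_adj == 0:
        return 1.0
    # P(X >= k_adj) for X ~ Hypergeom(N, K, n)
    return float(sps.hypergeom.sf(k_adj - 1, N, K, n))


def enrich_terms(
    gene_list: set[str],
    annotation: GoAnnotation,
    background: set[str] | None = None,
    cfg: EnrichConfig | None = None,
) -> list[EnrichmentResult]:
    """EASE over-representation of every term with >= 1 list hit.

    The background universe defaults to all annotated genes.  Results are
    sorted by ascending EASE p (ties by term id) and flagged significant
    iff list hits >= min_count and p < p_threshold.
    """
    cfg = cfg or EnrichConfig()
    if background is None:
        background = annotation.universe
    if not background:
        raise ValueError("empty background universe")
    if not gene_list <= background:
        raise ValueError("gene list is not a subset of the background universe")
    N = len(background)
    n = len(gene_list)
    term_background: dict[str, set[str]] = {}
    for gene in background:
        for term in annotation.gene_terms.get(gene, ()):
            term_background.setdefault(term, set()).add(gene)
    results = []
    for term, bg_genes in term_background.items():
        k = len(bg_genes & gene_list)
        if k == 0:
            continue
        K = len(bg_genes)
        p = ease_pvalue(k, n, K, N)
        results.append(
            EnrichmentResult(
                term=term, name=annotation.term_names.get(term, term),
                list_hits=k, list_size=n, background_hits=K, background_size=N,
                ease_p=p,
            )
        )
    results.sort(key=lambda r: (r.ease_p, r.term))
    _add_bh(results)
    for r in results:
        r.significant = r.list_hits >= cfg.min_count and r.ease_p < cfg.p_threshold
    return results


def _add_bh(results: list[EnrichmentResult]) -> None:
    m = len(results)
    running_min = 1.0
    for i in range(m - 1, -1, -1):
        q = results[i].ease_p * m / (i + 1)
        running_min = min(running_min, q)
        results[i].bh_q = min(running_min, 1.0)


def common_terms(
    per_species: dict[str, list[EnrichmentResult]]
) -> list[dict]:
    """Terms significant in every species, ordered by the first species' p.

    Returns rows with the term, its name, and per-species EASE p-values.
    """
    if len(per_species) < 2:
        raise ValueError("need significant-term lists from >= 2 species")
    species = list(per_species)
    sig_maps = {
        sp: {r.term: r for r in results if r.significant}
        for sp, results in per_species.items()
    }
    shared = set.intersection(*(set(m) for m in sig_maps.values()))
    rows = []
    for term in shared:
        first = sig_maps[species[0]][term]
        rows.append(
            {
                "term": term,
                "name": first.name,
                **{f"p_{sp}": sig_maps[sp][term].ease_p for sp in species},
            }
        )
    rows.sort(key=lambda r: (r[f"p_{species[0]}"], r["term"]))
    return rows


def parse_go_annotation(path: str) -> GoAnnotation:
    """Read a two-column (gene, term) TSV; extra columns name the term."""
    gene_terms: dict[str, set[str]] = {}
    term_names: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            gene, term = fields[0], fields[1]
            gene_terms.setdefault(gene, set()).add(term)
            if len(fields) > 2:
                term_names[term] = fields[2]
    return GoAnnotation(gene_terms, term_names)
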