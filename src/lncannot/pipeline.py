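"""End-to-end orchestration: screen, classify, conserve, overlap, enrich.

``run_all`` drives every stage on file inputs and writes TSV tables plus a
single machine-readable JSON summary.  Stages whose inputs are absent are
skipped; any stage failure aborts with the stage name, leaving prior
outputs intact.  Every output carries a header with the tool version, the
seed, and a hash of the configuration, and reruns with identical
seed/config/input are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__, classify, conservation, coding_screen, enrichment
from . import genome_io, overlap_compare
from .reporting import percentage

__all__ = ["RunConfig", "run_all", "percentage"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    genes: str  # GFF3 or BED12 gene models
    transcripts: str  # candidate ncRNA BED
    out_dir: str
    genome: str | None = None  # FASTA, enables strand inference
    track: str | None = None  # bedGraph/wiggle conservation scores
    datasets: dict[str, str] = field(default_factory=dict)  # name -> BED
    go_annotation: str | None = None  # gene<TAB>term TSV
    candidates_fasta: str | None = None  # screen stage inputs
    references_fasta: str | None = None
    gene_dialect: str = "gff3"
    seed: int = 0
    screen: coding_screen.ScreenConfig = field(default_factory=coding_screen.ScreenConfig)
    classify: classify.ClassifyConfig = field(default_factory=classify.ClassifyConfig)
    enrich: enrichment.EnrichConfig = field(default_factory=enrichment.EnrichConfig)
    n_controls: int | None = None  # None = match the number of scored ncRNAs

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: str(v) for k, v in sorted(self.__dict__.items()) if k != "out_dir"},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _header(cfg: RunConfig) -> str:
    return f"# lncannot {__version__} seed={cfg.seed} config={cfg.config_hash()}\n"


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_all(cfg: RunConfig) -> dict:
    """Run every applicable stage; returns the JSON-able summary dict."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "tool": "lncannot",
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
    }

    stage = "io"
    try:
        genes = genome_io.parse_gene_models(cfg.genes, cfg.gene_dialect)
        transcripts = genome_io.parse_intervals(cfg.transcripts)
        genome = None
        if cfg.genome:
            seqs = genome_io.read_fasta(cfg.genome)
            genome = genome_io.GenomeAssembly(
                sorted(seqs), {c: len(s) for c, s in seqs.items()}, seqs
            )
        summary["inputs"] = {"n_genes": len(genes), "n_transcripts": len(transcripts)}
    except Exception as exc:  # noqa: BLE001 - stage contract
        raise StageError(stage, exc) from exc

    if cfg.candidates_fasta and cfg.references_fasta:
        stage = "screen"
        try:
            cands = genome_io.read_fasta(cfg.candidates_fasta)
            refs = genome_io.read_fasta(cfg.references_fasta)
            retained, removed = coding_screen.filter_noncoding(cands, refs, cfg.screen)
            _write_tsv(
                out / "screen_removed.tsv", cfg,
                ["transcript_id", "reason", "best_identity", "best_coverage",
                 "best_reference", "longest_orf_aa"],
                [[r[k] for k in ("transcript_id", "reason", "best_identity",
                                 "best_coverage", "best_reference", "longest_orf_aa")]
                 for r in sorted(removed, key=lambda r: r["transcript_id"])],
            )
            summary["screen"] = {
                "candidates": len(cands), "retained": len(retained),
                "removed": len(removed),
            }
            retained_ids = set(retained)
            transcripts = [t for t in transcripts if t.transcript_id in retained_ids] or transcripts
        except StageError:
            raise
        except Exception as exc:
            raise StageError(stage, exc) from exc

    stage = "classify"
    try:
        tr_by_id = {t.transcript_id: t for t in transcripts}
        anns = classify.classify_transcripts(transcripts, genes)
        anns = classify.subclassify_utr_related(anns, tr_by_id, genes, cfg.classify)
        anns = classify.annotate_orientations(anns, tr_by_id, genes, genome)
        counts = classify.category_counts(anns)
        summary["classification"] = dict(counts)
        summary["classification"]["total"] = len(anns)
        _write_tsv(
            out / "annotation.tsv", cfg,
            ["transcript_id", "category", "neighbor", "distance", "gene_end", "orientation"],
            [[a.transcript_id, a.category, a.neighbor_gene_id or ".",
              a.distance_bp if a.distance_bp is not None else ".",
              a.gene_end or ".", a.orientation]
             for a in sorted(anns, key=lambda a: a.transcript_id)],
        )
        genome_io.write_intervals(
            transcripts, out / "classified.bed",
            name_suffix={a.transcript_id: a.category for a in anns},
        )
        hist = classify.positional_histogram(anns)
        _write_tsv(
            out / "positional_histogram.tsv", cfg,
            ["gene_end", "orientation", "bin_lo", "bin_hi", "count"],
            [[end, ori, hist.bin_edges[i] if i < len(hist.bin_edges) - 1 else hist.bin_edges[-1],
              hist.bin_edges[i + 1] if i < len(hist.bin_edges) - 1 else "inf", int(c)]
             for (end, ori) in sorted(hist.counts)
             for i, c in enumerate(hist.counts[(end, ori)])],
        )
        prox = classify.select_gene_proximate(anns, cfg.classify)
        summary["gene_proximate"] = {end: len(v) for end, v in prox.items()}
    except Exception as exc:
        raise StageError(stage, exc) from exc

    if cfg.track and genome is not None:
        stage = "conservation"
        try:
            track = genome_io.parse_score_track(cfg.track, genome)
            by_cat: dict[str, list] = {}
            for a in anns:
                by_cat.setdefault(a.category, []).append(tr_by_id[a.transcript_id])
            groups = {
                cat: conservation.interval_mean_score(recs, track)
                for cat, recs in by_cat.items() if recs
            }
            coding_recs = [
                genome_io.TranscriptRecord(g.gene_id, g.chrom, g.strand, list(g.exons))
                for g in genes
            ]
            groups["coding"] = conservation.interval_mean_score(coding_recs, track)
            excluded: dict[str, list] = {}
            for g in genes:
                excluded.setdefault(g.chrom, []).append(g.span)
            for t in transcripts:
                excluded.setdefault(t.chrom, []).append(t.span)
            n_controls = cfg.n_controls or len(transcripts)
            controls = conservation.sample_untranscribed_controls(
                genome, excluded,
                conservation.ControlSamplerConfig(n_controls=n_controls, seed=cfg.seed),
            )
            genome_io.write_intervals(controls, out / "controls.bed")
            groups["control"] = conservation.interval_mean_score(controls, track)
            comparison = conservation.compare_conservation(groups)
            summary["conservation"] = {
                "group_means": {k: round(v, 6) for k, v in comparison.group_means.items()},
                "ordering": comparison.ordering(),
                "n_controls": len(controls),
            }
            _write_tsv(
                out / "conservation_ecdf.tsv", cfg,
                ["group", "value", "cumulative_fraction"],
                [[grp, f"{v:.6g}", f"{f:.6g}"]
                 for grp in sorted(comparison.ecdfs)
                 for v, f in zip(comparison.ecdfs[grp].values,
                                 comparison.ecdfs[grp].fractions)],
            )
        except Exception as exc:
            raise StageError(stage, exc) from exc

    if cfg.datasets:
        stage = "overlap"
        try:
            total_intergenic = summary["classification"]["intergenic"]
            rows = []
            dataset_records = {}
            for name, path in cfg.datasets.items():
                theirs = genome_io.parse_intervals(path)
                dataset_records[name] = theirs
                pairing = overlap_compare.overlap_datasets(transcripts, theirs)
                report = overlap_compare.category_report(
                    pairing, anns, total_intergenic, dataset_name=name
                )
                rows.append([name, report.intronic, report.overlapped, report.utr_related,
                             report.intergenic,
                             report.intergenic_percent if report.intergenic_percent is not None else ".",
                             report.total, report.reciprocal_count])
            _write_tsv(
                out / "overlap_report.tsv", cfg,
                ["dataset", "intronic", "overlapped", "utr_related", "intergenic",
                 "intergenic_percent", "total", "reciprocal"],
                rows,
            )
            venn = overlap_compare.venn_counts(transcripts, dataset_records)
            _write_tsv(
                out / "overlap_venn.tsv", cfg,
                ["datasets", "count"],
                [["+".join(sorted(k)), v] for k, v in
                 sorted(venn.counts.items(), key=lambda kv: (len(kv[0]), sorted(kv[0])))],
            )
            summary["overlap"] = {
                r[0]: {"total": r[6], "intergenic": r[4], "intergenic_percent": r[5]}
                for r in rows
            }
        except Exception as exc:
            raise StageError(stage, exc) from exc

    if cfg.go_annotation:
        stage = "enrichment"
        try:
            annotation = enrichment.parse_go_annotation(cfg.go_annotation)
            gene_by_id = {g.gene_id: g for g in genes}
            summary["enrichment"] = {}
            for end, plist in prox.items():
                neighbor_symbols = {
                    gene_by_id[a.neighbor_gene_id].symbol for a in plist
                    if a.neighbor_gene_id in gene_by_id
                }
                gene_list = neighbor_symbols & annotation.universe
                if not gene_list:
                    summary["enrichment"][end] = {"n_terms": 0, "n_significant": 0}
                    continue
                results = enrichment.enrich_terms(gene_list, annotation, cfg=cfg.enrich)
                _write_tsv(
                    out / f"enrichment_{end}.tsv", cfg,
                    ["term", "name", "list_hits", "list_size", "background_hits",
                     "background_size", "ease_p", "bh_q", "significant"],
                    [[r.term, r.name, r.list_hits, r.list_size, r.background_hits,
                      r.background_size, f"{r.ease_p:.6g}", f"{r.bh_q:.6g}",
                      int(r.significant)] for r in results],
                )
                summary["enrichment"][end] = {
                    "n_terms": len(results),
                    "n_significant": sum(r.significant for r in results),
                }
        except Exception as exc:
            raise StageError(stage, exc) from exc

    summary_path = out / "summary.json"
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def _write_tsv(path: Path, cfg: RunConfig, header: list[str], rows: list[list]) -> None:
    with open(path, "w") as fh:
        fh.write(_header(cfg))
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
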