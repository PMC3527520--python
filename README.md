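# lncannot

Positional annotation and comparative analysis of long non-coding RNA
(lncRNA) transcripts against protein-coding gene models.

Transcribed regions without protein-coding capacity make up a large part of
vertebrate transcriptomes, and many long ncRNAs cluster around the 5′ and 3′
ends of protein-coding genes, where they are candidate *cis*-regulators.
`lncannot` implements the analysis chain used to characterize such
catalogs:

1. **Coding screen** — remove putative protein-coding transcripts by local
   alignment against known transcripts (query identity > 90% and coverage
   > 90%) and by a six-frame ORF scan (≥ 100 aa by default).
2. **Positional classification** — each candidate is, strand-agnostically,
   *overlapped* (≥ 1 bp of exon overlap), *intronic* (contained in a gene
   body without exon overlap) or *intergenic*; intergenic transcripts
   within 1 kb of a gene end, or highly similar to an annotated UTR, are
   refined to *UTR-related*, leaving "bona fide" intergenic ncRNAs.
3. **Neighbor genes** — the closest gene by span-to-span gap, the gene end
   it faces (5′/3′, strand-aware), sense/antisense orientation, and strand
   inference for spliced transcripts from splice dinucleotides (GT..AG
   forward, CT..AC reverse; conflicting introns → unknown).
4. **Conservation** — per-interval mean of a per-base conservation score
   (GERP++/phastCons/phyloP-style tracks), compared between classes and
   against length-matched (500–15,000 bp) control fragments sampled from
   un-transcribed genomic space; cumulative-frequency (ECDF) curves and
   one-sided Mann–Whitney tests.
5. **Catalog overlap** — ≥ 1 bp span overlap against external lncRNA
   catalogs, counted once per catalog per transcript, with per-category
   counts, the intergenic percentage and exclusive Venn regions.
6. **GO enrichment** — EASE-score over-representation of neighbor genes of
   gene-proximate (≤ 5 kb) intergenic ncRNAs.  The EASE score is the
   one-sided Fisher exact (hypergeometric tail) p-value with one gene
   removed from the list-hit cell: p = P(X ≥ k−1) for X ~
   Hypergeom(N, K, n); terms pass at gene count > 5 and p < 0.05.
7. **Cross-species conservation** — neighbor genes conserved across
   species, by case-insensitive symbol intersection and by local-alignment
   similarity (identity > 60% and coverage > 60% in every other species).

A seeded synthetic-data generator (`lncannot.synthetic_data`) produces
genomes, gene models, planted ncRNAs of every class (with configurable
gene-proximity bias and sense-strand skew), class-dependent conservation
tracks, GO annotations with a planted term, and homolog-sharing species
trios — so the whole chain runs and is testable at desk scale with no
downloads.

## Worked example

```python
from lncannot import classify, synthetic_data as synth

study = synth.generate_study(synth.SynthConfig(seed=42))
anns = classify.classify_transcripts(study.ncrnas, study.genes)
tr = {t.transcript_id: t for t in study.ncrnas}
anns = classify.subclassify_utr_related(anns, tr, study.genes)
print(classify.category_counts(anns))
```

```
{'intergenic': 48, 'intronic': 121, 'overlapped': 24, 'utr_related': 7}
```

The 200 planted ncRNAs are recovered in their true classes (the generator's
ground truth agrees 100% here): most are intronic, a fifth intergenic, a
few exon-overlapping, and a handful within 1 kb of a gene end (UTR-related).
Running `analysis/04_conservation.py` on the same study prints

```
group means, descending: {'coding': 3.0, 'utr_related': 1.52, 'intergenic': 1.0, 'intronic': 0.5, 'control': -0.0}
recovered ordering: coding > utr_related > intergenic > intronic > control
```

i.e. coding exons are the most conserved, ncRNA classes fall in between,
and un-transcribed control fragments sit at background — the ordering the
class-dependent track was built with.

The numbered scripts under `analysis/` run the stages in sequence on the
seed-42 study (simulation, coding screen, classification, conservation,
catalog overlap, GO enrichment, cross-species conservation) and write
their tables under `results/`.  A `ncrna` command-line entry point exposes
the same stages on user files (`ncrna simulate`, `ncrna classify`,
`ncrna screen`, `ncrna enrich`, `ncrna run --config run.json`,
`ncrna io validate`).

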