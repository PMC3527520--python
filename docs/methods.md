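# Methods

This note records the models, conventions, and design choices behind
`lncannot`, and what the synthetic-data tests do and do not demonstrate.

## Coordinates and formats

All intervals inside the package are 0-based half-open `[start, end)`.
Conversion from 1-based conventions happens only at the parse/write
boundary: GFF3 (1-based inclusive) and wiggle (1-based) are converted on
read; BED is native.  Gene models may come from GFF3 (explicit
`five_prime_UTR`/`three_prime_UTR` child features) or BED12 (thick region
taken as CDS, blocks minus thick as UTRs), so RefSeq-style annotations are
representable from either source.  Overlapping bedGraph records are not an
error: the last record wins and a warning is logged, since real UCSC
exports contain duplicates and determinism is preserved.  Written BED12 is
sorted by (chromosome, start, id) so that equal inputs produce
byte-identical files.

## Positional classification

Category assignment is strand-agnostic.  A transcript is *overlapped* when
any block shares ≥ 1 bp with any exon; there is deliberately no upper
bound, so a transcript spanning a whole gene is also "overlapped".
*Intronic* means the span is contained in some gene's span without exon
overlap — containment within a single intron is not required, and for
nested genes the first containing gene by start coordinate is the
deterministic host.  Everything else is *intergenic*, refined to
*UTR-related* when the span-to-span distance to the nearest gene is
≤ 1 kb (`utr_distance_bp`) or the best local alignment against a supplied
UTR sequence exceeds 90% identity and 50% coverage (defaults; the
published pipelines say only "high sequence similarity", so both are
configuration, not claims).

Neighbor distance is measured between gene span and transcript span (gap,
0 if abutting), not between midpoints or block edges.  Equidistant genes
tie-break by smaller start, then lexicographic gene id.  The gene end
facing the transcript is 5′ when the transcript lies on the transcription
start side of the gene, strand-aware.  Gene-proximate selection takes
stringent intergenic annotations (UTR-related excluded) with distance
≤ 5 kb, split by gene end.  The positional histogram uses half-open 1-kb
bins from 0 to 50 kb plus an overflow bin by default; the binning is a
presentation choice and an argument.

Strand inference for spliced transcripts reads the first and last two
intron bases: GT..AG votes "+", CT..AC votes "−", introns shorter than
4 bp or with non-canonical motifs abstain, and only a unanimous non-empty
vote decides; anything else is unknown.  Orientation relative to the
neighbor gene is sense/antisense by strand equality, unknown when the
transcript strand is unknown.

## Coding screen

The similarity screen is an exact local-alignment contract rather than a
BLAST wrapper: candidate sets at desk scale make exact dynamic programming
affordable and keep the pipeline free of external binaries.  Scoring is
match +1, mismatch −1, gap open −2, gap extend −1 (a length-L gap costs
open + (L−1)·extend), all configurable; N never counts as a match.
Identity is the percent of aligned columns (gaps included) whose residues
match; coverage is the percent of the query spanned by the aligned region
— subject-side coverage is not reported.  A candidate is removed when some
reference exceeds both thresholds (default 90/90) or its longest six-frame
ORF reaches the amino-acid threshold.  The 100-aa ORF default is the
conventional lncRNA cutoff; the cited screening pipelines do not print
their exact value, so it is configuration.  ORFs are ATG…stop with the
stop not counted, searched in all six frames with ties broken in frame
order +1, +2, +3, −1, −2, −3; protein-space comparison is approximated by
nucleotide comparison against reference transcripts (a translated-search
mode is out of scope).

## Conservation scoring

The per-interval score is the sum of covered per-base scores over the
transcript's exonic bases divided by the number of covered bases.
Uncovered bases are excluded from numerator *and* denominator: scoring
them 0 would conflate missing alignment data with neutrality.  The covered
fraction is reported, and group comparisons drop intervals with covered
fraction < 0.2 (configurable); intervals with no covered base are flagged
and excluded with a logged count.

Control fragments are sampled from the complement of all supplied
transcribed intervals (gene spans plus candidate transcripts plus any
extra evidence): a gap is chosen with probability proportional to its
length, the fragment length is uniform on [500, 15000] bp truncated to the
gap, and placement is uniform inside the gap.  Sampling is a bounded,
seeded rejection scheme — identical seeds give byte-identical control
BEDs.  When genome sequence is available, fragments that are more than
50% N are rejected (configurable).

ECDFs are standard right-continuous empirical CDFs.  The published
analyses compare groups by plotting cumulative frequencies; the one-sided
Mann–Whitney test attached to each group pair is the minimal formal
counterpart of "more conserved than" and is an extension, labeled as such.

## Catalog overlap

Overlap is span-based, strand-agnostic, ≥ 1 bp (the GenomicRanges-style
default; no threshold is stated in the source analyses).  Each of our
transcripts is counted once per catalog regardless of hit multiplicity;
the reciprocal count is the number of external records hit at least once.
The intergenic percentage divides by the total number of intergenic
ncRNAs, rounded half-to-even at two decimals.  Venn regions are exact
exclusive-subset counts over membership vectors of our transcripts
(supported up to five catalogs).

## EASE enrichment

EASE is the one-sided Fisher exact enrichment p-value with the list-hit
cell decremented by one while keeping margins: p = P(X ≥ k−1) for
X ~ Hypergeom(N, K, n), with p = 1 for k ≤ 1.  This is conservative
relative to the classical Fisher p (property-tested), and single-hit
terms can never appear enriched.  The catalog thresholds are gene count
> 5 and raw p < 0.05; no multiple-testing correction is applied to the
flags (fidelity to the original thresholds), but a Benjamini–Hochberg
column is always emitted.  The background universe defaults to all
annotated genes and is stated in every report; offline re-derivation of a
web service's exact category sets is not attempted.  Cross-species common
terms are those significant in every species, ordered by the first
species' p-value.

## Cross-species neighbor conservation

Symbol matching is exact after case-folding; no ortholog database is
consulted.  Sequence conservation takes, per query gene, the best-scoring
local alignment against each other species' neighbor set (score prescreen,
one traceback) and requires identity > 60% and coverage > 60% — measured
on the query sequence, since the source analyses do not say which side —
in **every** other species (an any-species mode is configuration).
Reciprocal-best-hit filtering is not required; one-directional best hits
with the all-species requirement are used and documented.

## Synthetic data generator

The generator emulates the structure of an EST-derived lncRNA catalog:

- **Genome/genes** — 3 chromosomes × 500 kb with 10 genes each, 3–6 exons
  of 100–400 bp, introns 500–3,000 bp, 60-bp terminal UTRs, canonical
  splice motifs, and ≥ 16 kb between gene spans so distal intergenic
  placement is possible.
- **ncRNAs** — 200 by default, 200–2,000 bp, class proportions following
  the human catalog mix (intergenic 0.22 / intronic 0.62 / overlapped
  0.12 / UTR-related 0.04).  Intergenic ncRNAs are placed within
  (1, 5] kb of a random gene end with probability `p_prox` = 0.6, else
  > 5 kb from every gene; UTR-related within 1 kb.  The proximate/distal
  decision is drawn once per transcript *outside* the placement retry
  loop — retrying it would bias the realized fraction away from `p_prox`
  because the two placements reject at different rates.  Gene-proximate
  strands are sense with probability 0.7 at 3′ ends and 0.45 at 5′ ends
  (the catalog's qualitative skew); spliced ncRNAs (half by default)
  receive canonical splice motifs written into the genome so strand
  inference has signal, and a `noncanonical_fraction` knob exercises the
  unknown-strand path.
- **Track** — per-base Normal(class mean, 0.5) scores with class means
  coding 3.0 > UTR-related 1.5 > intergenic 1.0 > intronic 0.5 >
  background 0.0.  These are generator conventions chosen to reproduce
  the qualitative conservation ordering of real catalogs, not measured
  values.  10% of bases are uncovered by default.
- **Trio** — 30 genes per species, 500 bp each; 30% are homolog groups
  copied with point mutations at 15% (85% identity) retaining symbols,
  the rest independent with species-unique symbols.
- **GO** — 400-gene universe, 30 terms at base rate 0.08, one term
  planted at 5× among a 40-gene list.
- **Screen candidates** — coding-like sequences carry a planted 120-codon
  ORF; noncoding-like sequences contain neither ATG nor CAT substrings,
  so no start codon exists on either strand.

Everything derives from `numpy.random.default_rng([seed, stage])`, so each
stage is independently reproducible and emitted files are byte-identical
across runs.  Sizes default to values that keep an end-to-end run around a
second on one CPU.

What the generator does *not* emulate: repeat content, sequencing error,
EST library artifacts (chimerism, truncation), alternative isoforms,
overlapping gene models, and assembly gaps.  Passing tests therefore
demonstrate correctness of the annotation logic and recoverability of
planted signal under clean conditions, not robustness to the noise
sources of real EST data.

## Numerical choices

Percentages are rounded half-to-even (two decimals for table percentages,
integer for the reciprocal-overlap fractions).  One published zebrafish
table cell (105 of 4,464 printed as 2.36%) is inconsistent with its own
counts under any standard rounding; the computation here yields 2.35 and
the discrepancy is documented rather than silently corrected.  Mean-score
comparisons treat exactly-tied groups through the normal-approximation
Mann–Whitney path of scipy.  The EASE tail uses `scipy.stats.hypergeom.sf`;
the test suite checks it against an explicit binomial-coefficient
summation to 1e−10 relative.  Alignment stats under co-optimal local
alignments follow Biopython's first-reported traceback; tests assert
score equality against an independent DP oracle and pin identity/coverage
only where the optimum is unique.

## Problem sizes

The default test and acceptance runs use the generator defaults above,
with 600 planted ncRNAs for label-recovery checks, 2,000 planted
intergenic ncRNAs for the proximity-bias and sense-skew recovery (three
binomial standard deviations), 1,000 random transcripts for the per-base
classification oracle, 30-gene trios for homolog recovery, and 100–200
annotation replicates for GO detection and null calibration.

## Known limitations

- Neighbor assignment records a single closest gene; multi-neighbor
  association and enhancer/promoter sub-typing are out of scope.
- The conservation stage consumes score tracks; computing conservation
  from multiple alignments is out of scope.
- bigWig input is not parsed; text bedGraph/wiggle is the contract.
- Translated (protein-space) similarity search is not implemented.
- GO term-graph propagation is applied only if a term graph is supplied.
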