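# Methods

This note records the model assumptions, parameter choices and numerical
conventions behind `methdomain`, and what the simulator does and does not
emulate.

## Domain model and segmentation

The methylome is modelled as a partition of each chromosome into blocks of
concordant CpG methylation: hypermethylated (HyperD) and hypomethylated
(HypoD) domains, with promoters/CGIs and regions of pre-existing methylation
treated as carve-outs rather than domain boundaries.  Segmentation operates
on *covered* CpGs (any read), in three stages:

1. **Probes.**  `window_n_cpgs` = 50 consecutive covered CpGs, advanced by
   `step_n_cpgs` = 10 (preset `10_5` gives the finer 10/5 variant).  A probe's
   genomic extent is `[first member CpG, last member CpG + 1)` — no invented
   flanks.  Its level is the unweighted mean of per-CpG methylation over
   member CpGs with ≥ `min_reads_per_cpg` = 5 reads, defined only when
   ≥ `min_scored_cpgs` = 3 qualify.  Chromosome tails shorter than one probe
   yield no probe, and probes never bridge chromosomes.
2. **Seeds and raw domains.**  Probes strictly >75 % (hyper) or strictly
   <25 % (hypo) are class seeds; overlapping or bookended same-class seeds
   are unioned.  Where opposite-class runs overlap, the shared span is cut at
   `floor((s+e)/2)`, left part to the left run; when one run contains
   another, the containing run's remainder past the contained run survives
   as its own piece.  Strictness of the cuts is configurable
   (`strict_cuts=False` gives ≥75/≤25) because descriptive summaries
   elsewhere in the analysis use the inclusive form; the segmentation default
   is strict.
3. **Refinement.**  Exactly four passes, in order: merge same-class
   neighbours with gap < 2000 bp (strict, gap measured `next.start −
   prev.end`); delete opposite-class domains < 1000 bp lying between two
   same-class domains and span the merge across them; remove domains
   < 2000 bp; merge again.  The cascade is idempotent (property-tested), and
   each pass runs per chromosome, so chromosome order is irrelevant.

**Numerical exactness at the cuts.**  A probe mean can fall exactly on a cut
(the per-CpG values are small-denominator rationals).  Means within 1e-6 of
a cut are recomputed in exact rational arithmetic so that strict threshold
comparisons never depend on float summation order; the test-suite oracle
computes all probe means rationally.

## Exclusion masks

* **Promoter mask** — 2 kbp downstream of each gene's most upstream TSS, in
  the direction of transcription, merged across genes.
* **Pre-methylation mask** — 1-kbp genome tiles scored per control methylome
  (mean over CpGs with ≥3 reads, needing ≥3 such CpGs); a tile is masked at
  ≥50 % in *any* control (union semantics, since any pre-existing methylation
  makes de novo attribution ambiguous).
* **CGI mask** — the CGI input track, merged.

Masks are subtracted *after* refinement.  Fragments keep the parent domain's
class and id as `parent_id` (flagged `split_by_mask`), and sub-2-kbp
fragments survive; fully masked domains are dropped but logged.  This keeps
both readouts available: domain counts pre-mask via parents, and masked
intervals for transcription correlation.

## CpG category partition

Every CpG in the methylome is assigned to exactly one category, in
precedence order: hyper domain, hypo domain, promoter/CGI mask, intermediate
methylation (25–75 % at ≥5 reads), pre-methylated control mask, other.  The
fractions sum to one by construction and the partition is property-tested.

## Transcription overlap

Contigs are maximal runs with read depth ≥3 on one strand in one dataset
(sweep over interval endpoints; starts processed before ends at equal
coordinates so bookended reads do not open spurious gaps), unioned across
datasets per strand.  Domain overlap is strand-agnostic (DNA methylation is
strand-symmetric), contig construction strand-aware.

HyperD explanation uses cumulative evidence: expressed reference genes
(FPKM > 0.001) ⊂ +assembly ⊂ +contigs ⊂ +partially methylated control
regions.  The assigned tier is the first whose coverage exceeds 0.5;
"untranscribed" flags assembly+contig coverage < 0.05.  HypoDs covered >0.5
by the assembly are attributed to weak transcription when the majority of
their transcribed bases come from genes with FPKM < 0.5, else to alternative
downstream promoters when 2-kbp windows at non-most-upstream transcript
TSSs cover >0.5, else left unexplained-transcribed.

Gene bodies are scored with 3 CpGs at ≥3 reads.  The FPKM threshold for
unmethylated gene bodies is read off 0.1-wide FPKM bins as the upper edge of
the highest bin where unmethylated (<25 %) gene bodies outnumber methylated
(>75 %) ones.  Escapee detection screens genes (FPKM > 1, ≥10 kbp, body
<25 %) and confirms with 10-kbp windows stepped by 5 kbp (a trailing window
anchored at the gene end): every scored window must stay <25 % and ≥80 % of
windows must be scorable.  The window/step values are our concretisation of
a running-window screen; they are parameters, not fixed constants.

Enrichment contrasts use Pearson's chi-squared on the 2×2 table without
continuity correction (counts in these comparisons are large; a warning flag
is set when any expected cell is <5 or the table is degenerate).

## Curation rules

Mono-exonic curation applies, in order: (a) drop unstranded transcripts;
(b) drop mono-exonic transcripts fully inside a same-strand intron of a
multi-exonic transcript of another gene; (c) merge mono-exonic transcripts
starting within 2 kbp downstream of a multi-exonic transcript's 3′ end into
that transcript, iterated to fixpoint so fragment arrays chain in; (d) drop
mono-exonic genes whose depth-normalised read count does not exceed the
CDF-gap threshold computed against random size-matched intergenic regions.
The CDF-gap threshold evaluates both empirical CDFs on the pooled value
grid and takes the argmax of `CDF(intergenic) − CDF(transcripts)`, ties
toward the smallest value.

Classification against the reference uses simplified Cuffcompare semantics
with precedence `=`, `c`, `j`, `o`, `i`, `x`, `u`; a gene is novel when no
member transcript scores a reference code.  Novel-gene exclusions: proximity
to same-strand reference genes or known ncRNAs within ±1 kbp (multi-exonic)
or ±5 kbp (mono-exonic), measured between closest span edges (span-to-span,
not TSS-to-span); and, for mono-exonic genes, ≥50 % exonic coverage by a
single TE element (the coverage fraction is configurable; the rule itself —
"expressed independent repetitive elements" — gives no number).  Novel
upstream TSSs require a same-strand start upstream of the reference gene's
most upstream TSS, in an exon sharing no base with that gene's reference
exons, outside every CGI within ±100 bp of any reference TSS.  TSSs are
CGI-associated within ±100 bp of a CGI, else TE-associated on single-base
same-strand overlap (family recorded), else other.  TE-family TSS
expectations come from seeded Monte-Carlo placement of the observed TSS
total over intergenic space, with the analytic occupancy expectation and a
two-sided binomial p value reported alongside.

## Simulator

`synthetic_data` emulates the statistical structure the analysis assumes:

* **Methylome** — CpG positions as a geometric-gap (Poisson) process at
  1/100 bp; per-CpG methylation probability Beta-distributed around the
  domain target (concentration 50, giving the strongly bimodal per-CpG
  distribution), coverage Poisson (default mean 15), methylated counts
  binomial.  The default genome is 2 × 10 Mbp with alternating domains of
  ≥10 kbp (exponential tail, mean ≈50 kbp) at 90 %/10 % — large enough for
  ~400 domains.  Controls are mostly unmethylated with planted pre-methylated
  regions.
* **Coupled mode** — hyper blocks derive from gene spans with a coupling
  probability; extra intergenic hyper blocks (lengths resampled from the
  gene-span length distribution, so the coupling rate holds in base pairs as
  well as counts) make the transcribed fraction of hyper blocks equal the
  coupling rate.
* **Annotation** — genes are placed on evenly spaced anchors whose spacing
  exceeds every curation-rule margin with ≥2× slack, so planted novel genes
  and upstream TSSs are unambiguous; confounders deliberately violate one
  rule each (proximity to reference or ncRNA, TE-covered mono-exonic,
  upstream start inside the reference first exon), making precision
  measurable.  CGIs are placed at promoters with probability 0.7; TEs occupy
  unused anchors.
* **Reads** — per gene, Poisson counts with mean FPKM × exonic kbp ×
  depth/10⁶, positions uniform within exons, strand inherited; FPKM is
  recomputed from counts against the library depth.

What the simulator does *not* emulate: sequence composition (CpG density is
homogeneous, no CGI-like CpG clustering), bisulfite conversion error, mapping
bias, fragment-length structure in RNA reads, isoform-level expression, or
chromosome-scale covariates (replication timing, compartments).  Passing
tests therefore demonstrate correctness of the rules and robust recovery
under the assumed noise model, not performance on real libraries.

## Problem sizes and determinism

Tests and the acceptance script run on the default 2 × 10 Mbp simulated
genome (~200k CpGs, ~400 domains), 300-gene expression panels and
500-chromosome oracle batches; these sizes give stable statistics (Jaccard
recovery ≈0.99, binomial noise well inside tolerances) at a few seconds of
runtime.  Every random draw flows from an explicit seed; reruns are
byte-identical, and the pipeline's JSON/TSV writers use fixed column orders
and sorted keys to keep outputs diffable.

## Known limitations

* The mono-exonic read-count filter re-derives its threshold from whatever
  population it is given; re-curating an already-curated annotation can, for
  pathological count distributions, tighten the threshold further (the
  shipped rule set is stable on realistic, well-separated inputs, and this
  is covered by a stability test).
* Cuffcompare semantics are simplified: containment (`c`) requires the
  intron chain to be a contiguous subchain; fuzzy splice-site matching is
  not implemented.
* `intragenic_with_alt_tss` CGI classification uses the same ±100 bp margin
  as TSS association, chosen for symmetry; the margin is a parameter.
* Escapee confirmation windows (10 kbp/5 kbp, all-scored-windows rule, 80 %
  scorable) are a design choice; alternatives (e.g. allowing one failing
  window) are easy to express but not implemented.
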