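# methdomain

Segmentation of an oocyte-style DNA methylome into large hyper- and
hypomethylated domains, and quantification of how much of that methylome is
accounted for by transcription.

## The problem

In growing mouse oocytes, de novo DNA methylation is laid down during
follicular growth and ends up organised in large genomic blocks: gene bodies
of actively transcribed genes become hypermethylated (likely via
H3K36me3-stimulated DNMT3A/3L activity), while untranscribed and weakly
transcribed sequence stays unmethylated.  Testing that model genome-wide
requires (i) calling the domains from per-CpG bisulfite counts, (ii) a
carefully curated transcriptome — de novo assemblies of deep oocyte RNA-Seq
contain thousands of artefactual mono-exonic fragments alongside genuinely
novel genes and upstream promoters (many TE-derived, particularly MaLR and
ERVK) — and (iii) measuring how completely transcription units cover the
hypermethylated space, and how CpG islands and imprinted gDMRs sit relative
to the gene set.

This package implements that analysis chain for methylome/transcriptome
pairs, with a seeded simulator that generates every input with planted truth
so the whole pipeline is testable at desk scale.

## The method

**Domain calling.** Probes of 50 consecutive covered CpGs (stepped by 10) are
scored by mean per-CpG methylation over CpGs with ≥5 reads (≥3 such CpGs
required).  Probes >75 % seed hypermethylated domains (HyperDs), probes <25 %
seed hypomethylated domains (HypoDs); overlapping same-class probes are
unioned and hyper/hypo overlaps are split at the midpoint.  Refinement then
merges same-class neighbours <2 kbp apart, absorbs opposite-class islands
<1 kbp, removes domains <2 kbp and merges again.  Promoters (2 kbp downstream
of each gene's most upstream TSS), CpG islands, and 1-kbp regions already
≥50 % methylated in control methylomes (non-growing oocytes, DNMT3A/3L
deficient) are subtracted afterwards, with parent-domain lineage preserved.

**Transcription overlap.** Each domain's length fraction covered by
cumulative evidence tiers — expressed reference genes (FPKM > 0.001), the
assembly, read contigs (≥3 same-strand reads in ≥1 dataset), partially
methylated control regions — assigns it to the first tier exceeding 50 %;
domains <5 % covered are untranscribed.  HypoDs are attributed to weak
transcription (gene FPKM < 0.5), alternative downstream promoters, or left
unexplained.  Gene bodies are scored (3 CpGs / ≥3 reads) against FPKM bins to
locate the expression level below which gene bodies stay unmethylated, and
expressed, large, unmethylated genes are confirmed as methylation escapees by
a 10-kbp/5-kbp running-window screen.

**Curation and features.** Assembly curation removes unstranded and intronic
mono-exonic fragments, merges 3′ fragment arrays into their host transcripts,
and filters mono-exonic genes by a read-count threshold set at the maximum
vertical gap between the FPKM CDFs of assembled transcripts and random
size-matched intergenic regions.  Transcripts are classified against the
reference with simplified Cuffcompare codes (`=`, `c`, `j`, `o` reference /
`i`, `u`, `x` novel); novel genes and novel upstream TSSs are called under
proximity, repeat and CGI rules; CGIs and igDMRs are classified by position
(TSS-associated, intragenic ± alternative TSS, intergenic) and methylation
status (≥75 % / ≤25 %, 10 CpGs at ≥5 reads).

## Worked example

```python
from methdomain import (
    MethylomeSpec, simulate_methylome, SegmentationParams,
    make_windows, raw_domains, refine_domains, domain_stats,
)

spec = MethylomeSpec(chrom_lengths={"chr1": 2_000_000}, seed=42)
methylome, truth = simulate_methylome(spec)
params = SegmentationParams()          # 50-CpG probes, 10-CpG step
windows = make_windows(methylome, params)
domains = refine_domains(raw_domains(windows, params), params)
stats, summary = domain_stats(domains, methylome)
```

prints (via the obvious `print` calls):

```
simulated 20043 CpGs, 46 planted domains
windows: 2000, domains: 46
hyper  n= 23  median length 45.5 kbp  mean methylation 89.6 %
hypo   n= 23  median length 27.1 kbp  mean methylation 10.5 %
         id class  start    end  mean_meth
 hypo_00001  hypo     27 103650  10.461468
hyper_00001 hyper 103816 208437  89.956396
 hypo_00002  hypo 208437 230572  11.437683
hyper_00002 hyper 230572 243063  89.222214
```

The caller recovers all 46 planted domains; hyper domains average ~90 %
methylation and hypo domains ~10 %, matching the simulation targets, and the
domain boundaries land within about one probe step of the planted change
points.

The same stages are available from the shell:

```sh
methdomain simulate --out sim/ --seed 1
methdomain call --meth sim/fgo.cov --annotation sim/oocyte.gtf \
    --cgi sim/cgi.bed --preset 50_10 --out domains.bed
methdomain explain --domains domains.bed --gtf sim/oocyte.gtf \
    --reads sim/reads.tsv --out explain.tsv
methdomain all --config pipeline.yaml
```

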