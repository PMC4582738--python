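"""CpG-island and igDMR classification against the oocyte gene set.

CGIs are partitioned by position relative to an annotation (TSS-associated,
intragenic with an alternative downstream TSS, plain intragenic, intergenic),
scored for methylation status, and placed in transcriptional context
(read-contig overlap, position immediately downstream of genes).  Imprinted
germline DMRs are classified against the reference and oocyte annotations
independently, plus the methylation domain containing them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .domain_caller import DomainSet
from .genomic_io import (
    AnnotationSet,
    FeatureTrack,
    GenomicInterval,
    MethylomeTable,
    covered_length,
)
from .transcription_overlap import ContigTrack
from .domain_caller import Domain

LOCATION_CLASSES = (
    "tss_associated",
    "intragenic_with_alt_tss",
    "intragenic",
    "intergenic",
)


@dataclass
class CGIRecord:
    interval: GenomicInterval
    location_class: str | None = None
    meth_status: str | None = None  # hyper/hypo/intermediate/unscored
    mean_meth: float | None = None
    n_scored_cpgs: int = 0
    overlapped_by_contig: bool = False
    within_1kbp_downstream_of_gene: bool = False


@dataclass
class IgDMRRecord:
    name: str
    interval: GenomicInterval
    location: dict[str, str] = field(default_factory=dict)  # annotation label -> class
    domain_class: str | None = None


# ---------------------------------------------------------------------------
# Location
# ---------------------------------------------------------------------------

def classify_cgi_location(
    cgi_track: FeatureTrack,
    annotation: AnnotationSet,
    tss_margin: int = 100,
) -> list[CGIRecord]:
    """Assign each CGI to exactly one positional class.

    TSS-associated when it overlaps any gene's most upstream TSS within
    ``tss_margin`` bp; otherwise intragenic-with-alternative-TSS when,
    inside a gene it overlaps, it also overlaps a transcript TSS other than
    the gene's most upstream one (same margin); otherwise intragenic on any
    gene-span overlap; otherwise intergenic.
    """
    genes = annotation.gene_list()
    by_chrom: dict[str, list] = {}
    for g in genes:
        alt_tsss = sorted(
            {t.tss for t in g.transcripts if t.tss != g.most_upstream_tss}
        )
        by_chrom.setdefault(g.chrom, []).append(
            (g.start, g.end, g.most_upstream_tss, alt_tsss)
        )
    records = []
    for iv in cgi_track.intervals():
        rec = CGIRecord(interval=iv)
        cls = "intergenic"
        for start, end, tss, alt_tsss in by_chrom.get(iv.chrom, ()):
            if iv.start <= tss + tss_margin and tss - tss_margin < iv.end:
                cls = "tss_associated"
                break
            if iv.start < end and start < iv.end:
                if cls == "intergenic":
                    cls = "intragenic"
                if any(
                    iv.start <= t + tss_margin and t - tss_margin < iv.end
                    for t in alt_tsss
                ):
                    cls = "intragenic_with_alt_tss"
        rec.location_class = cls
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# Methylation status
# ---------------------------------------------------------------------------

def cgi_meth_status(
    records: list[CGIRecord],
    methylome: MethylomeTable,
    min_reads: int = 5,
    min_cpgs: int = 10,
    hyper_cut: float = 75.0,
    hypo_cut: float = 25.0,
) -> list[CGIRecord]:
    """Score CGI methylation: mean over CpGs at adequate coverage.

    A CGI needs at least ``min_cpgs`` CpGs with ``min_reads`` reads to be
    scored; thresholds are inclusive (hyper at or above ``hyper_cut``, hypo
    at or below ``hypo_cut``).
    """
    for rec in records:
        iv = rec.interval
        pos, nm, nu = methylome.arrays(iv.chrom)
        lo, hi = np.searchsorted(pos, [iv.start, iv.end])
        m, u = nm[lo:hi], nu[lo:hi]
        cov = m + u
        ok = cov >= min_reads
        rec.n_scored_cpgs = int(ok.sum())
        if rec.n_scored_cpgs < min_cpgs:
            rec.meth_status = "unscored"
            rec.mean_meth = None
            continue
        mean = float((100.0 * m[ok] / cov[ok]).mean())
        rec.mean_meth = mean
        if mean >= hyper_cut:
            rec.meth_status = "hyper"
        elif mean <= hypo_cut:
            rec.meth_status = "hypo"
        else:
            rec.meth_status = "intermediate"
    return records


# ---------------------------------------------------------------------------
# Transcription context
# ---------------------------------------------------------------------------

def cgi_transcription_context(
    records: list[CGIRecord],
    annotation: AnnotationSet,
    contigs: ContigTrack | None,
    downstream_extent: int = 1000,
) -> tuple[list[CGIRecord], dict]:
    """Flag CGIs by contig overlap and 3'-downstream gene proximity.

    The summary contrasts methylated vs unmethylated intergenic CGIs on
    contig overlap (2x2 chi-squared); empty when either group is absent.
    """
    contig_iv = contigs.collapsed_per_chrom() if contigs is not None else {}
    down_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for g in annotation.gene_list():
        if g.strand == "-":
            s, e = max(0, g.start - downstream_extent), g.start
        else:
            s, e = g.end, g.end + downstream_extent
        if e > s:
            down_by_chrom.setdefault(g.chrom, []).append((s, e))
    for rec in records:
        iv = rec.interval
        merged = contig_iv.get(iv.chrom)
        rec.overlapped_by_contig = bool(
            merged is not None and covered_length(iv.start, iv.end, merged) > 0
        )
        rec.within_1kbp_downstream_of_gene = any(
            iv.start < e and s < iv.end
            for s, e in down_by_chrom.get(iv.chrom, ())
        )
    meth = [
        r for r in records
        if r.location_class == "intergenic" and r.meth_status == "hyper"
    ]
    unmeth = [
        r for r in records
        if r.location_class == "intergenic" and r.meth_status == "hypo"
    ]
    summary: dict = {
        "n_intergenic_meth": len(meth),
        "n_intergenic_unmeth": len(unmeth),
    }
    if meth and unmeth:
        summary["meth_contig_frac"] = float(
            np.mean([r.overlapped_by_contig for r in meth])
        )
        summary["unmeth_contig_frac"] = float(
            np.mean([r.overlapped_by_contig for r in unmeth])
        )
        summary["meth_downstream_frac"] = float(
            np.mean([r.within_1kbp_downstream_of_gene for r in meth])
        )
        counts = [
            [
                sum(r.overlapped_by_contig for r in grp),
                sum(not r.overlapped_by_contig for r in grp),
            ]
            for grp in (meth, unmeth)
        ]
        table = np.array(counts, dtype=float)
        if (table.sum(axis=0) == 0).any():
            summary["chi2"], summary["p"] = 0.0, 1.0
        else:
            from scipy import stats

            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
            summary["chi2"], summary["p"] = float(chi2), float(p)
        summary["counts"] = counts
    else:
        summary["note"] = "one or both intergenic CGI groups empty"
    return records, summary


# ---------------------------------------------------------------------------
# igDMRs
# ---------------------------------------------------------------------------

def classify_igdmrs(
    igdmr_track: FeatureTrack,
    reference: AnnotationSet,
    oocyte: AnnotationSet,
    domains: DomainSet | None = None,
    tss_margin: int = 100,
) -> list[IgDMRRecord]:
    """Locate each igDMR relative to both annotations and the domain map."""
    annos = {"reference": reference, "oocyte": oocyte}
    per_anno: dict[str, list[CGIRecord]] = {
        label: classify_cgi_location(igdmr_track, anno, tss_margin)
        for label, anno in annos.items()
    }
    dom_by_chrom: dict[str, list[Domain]] = (
        domains.per_chrom() if domains is not None else {}
    )
    records = []
    for i, r in enumerate(igdmr_track.df.itertuples()):
        iv = GenomicInterval(r.chrom, int(r.start), int(r.end), r.strand)
        rec = IgDMRRecord(name=str(r.name), interval=iv)
        for label in annos:
            rec.location[label] = per_anno[label][i].location_class
        best_cov = 0
        for d in dom_by_chrom.get(iv.chrom, ()):
            cov = max(0, min(d.end, iv.end) - max(d.start, iv.start))
            if cov > best_cov:
                best_cov = cov
                rec.domain_class = d.cls
        records.append(rec)
    return records


def cgi_records_frame(records: list[CGIRecord]) -> pd.DataFrame:
    """Tabular view of CGI records for report output."""
    return pd.DataFrame(
        [
            {
                "chrom": r.interval.chrom,
                "start": r.interval.start,
                "end": r.interval.end,
                "location_class": r.location_class,
                "meth_status": r.meth_status,
                "mean_meth": r.mean_meth,
                "n_scored_cpgs": r.n_scored_cpgs,
                "overlapped_by_contig": r.overlapped_by_contig,
                "within_1kbp_downstream_of_gene": r.within_1kbp_downstream_of_gene,
            }
            for r in records
        ]
    )
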