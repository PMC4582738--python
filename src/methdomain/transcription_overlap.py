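"""Quantifying transcription over methylation domains.

Hypermethylated domains are expected to coincide with active transcription
units; hypomethylated domains with untranscribed or weakly transcribed
sequence.  This module measures that coincidence: read-contig construction,
per-domain overlap fractions against cumulative evidence tiers, the
explanation cascades for the two domain classes, the expression threshold
below which gene bodies tend to stay unmethylated, detection of expressed
genes that escape methylation, and chi-squared feature-enrichment contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .domain_caller import HYPER, HYPO, Domain, DomainSet
from .genomic_io import (
    AnnotationSet,
    FeatureTrack,
    GeneModel,
    MethylomeTable,
    covered_length,
    merge_intervals,
)

HYPERD_TIERS = (
    "reference_expressed",
    "assembly",
    "assembly_plus_contigs",
    "plus_partial_meth",
    "unexplained",
)

HYPOD_TIERS = (
    "low_fpkm_gene",
    "alt_downstream_promoter",
    "unexplained_transcribed",
    "untranscribed",
)


@dataclass
class DomainExplanation:
    domain_id: str
    cls: str
    length: int
    fractions: dict[str, float]
    tier: str
    untranscribed: bool = False


@dataclass
class EscapeeGene:
    gene_id: str
    fpkm: float
    length: int
    gene_body_meth: float
    n_windows: int
    n_scored_windows: int
    max_window_meth: float
    confirmed: bool


class ContigTrack:
    """Stranded intervals of contiguous transcription evidence."""

    def __init__(self, plus: FeatureTrack, minus: FeatureTrack) -> None:
        self.plus = plus
        self.minus = minus

    def stranded(self, strand: str) -> FeatureTrack:
        return self.plus if strand == "+" else self.minus

    def collapsed_per_chrom(self) -> dict[str, np.ndarray]:
        """Strand-collapsed merged intervals for DNAme overlap analysis."""
        out: dict[str, list[np.ndarray]] = {}
        for track in (self.plus, self.minus):
            for chrom, iv in track.per_chrom().items():
                out.setdefault(chrom, []).append(iv)
        return {c: merge_intervals(np.concatenate(ivs)) for c, ivs in out.items()}

    def __len__(self) -> int:
        return len(self.plus) + len(self.minus)


# ---------------------------------------------------------------------------
# Contigs
# ---------------------------------------------------------------------------

def build_contigs(
    read_intervals: pd.DataFrame, min_depth: int = 3
) -> ContigTrack:
    """Call contigs: maximal runs covered by ``min_depth`` same-strand reads.

    ``read_intervals`` must have columns ``chrom, start, end, strand,
    dataset``.  Depth is computed per dataset and strand by a sweep over
    interval endpoints; the final track is the union over datasets, keeping
    strand.
    """
    required = {"chrom", "start", "end", "strand", "dataset"}
    missing = required - set(read_intervals.columns)
    if missing:
        raise ValueError(f"read intervals missing columns {sorted(missing)}")
    by_strand: dict[str, list[tuple[str, int, int]]] = {"+": [], "-": []}
    for (dataset, strand, chrom), sub in read_intervals.groupby(
        ["dataset", "strand", "chrom"], sort=True
    ):
        starts = np.sort(sub["start"].to_numpy())
        ends = np.sort(sub["end"].to_numpy())
        edges = np.concatenate([starts, ends])
        deltas = np.concatenate(
            [np.ones(len(starts), dtype=np.int64), -np.ones(len(ends), dtype=np.int64)]
        )
        order = np.argsort(edges, kind="mergesort")
        # at equal coordinates process starts before ends so bookended reads
        # do not create spurious zero-depth gaps
        key = edges[order] * 2 + (deltas[order] < 0)
        order = order[np.argsort(key, kind="mergesort")]
        edges, deltas = edges[order], deltas[order]
        depth = np.cumsum(deltas)
        run_start = None
        for i in range(len(edges)):
            if depth[i] >= min_depth and run_start is None:
                run_start = edges[i]
            elif depth[i] < min_depth and run_start is not None:
                if edges[i] > run_start:
                    by_strand[strand].append((chrom, int(run_start), int(edges[i])))
                run_start = None
    tracks = {}
    for strand in ("+", "-"):
        rows = []
        per_chrom: dict[str, list] = {}
        for chrom, s, e in by_strand[strand]:
            per_chrom.setdefault(chrom, []).append([s, e])
        for chrom, iv in per_chrom.items():
            for s, e in merge_intervals(np.array(iv, dtype=np.int64)):
                rows.append((chrom, int(s), int(e), strand))
        tracks[strand] = FeatureTrack(
            "contig",
            pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"]),
        )
    return ContigTrack(tracks["+"], tracks["-"])


# ---------------------------------------------------------------------------
# Overlap
# ---------------------------------------------------------------------------

def overlap_fraction(
    domain: Domain, merged_by_chrom: dict[str, np.ndarray]
) -> float:
    """Fraction of the domain's length covered by merged intervals."""
    if domain.length <= 0:
        raise ValueError(f"zero-length domain {domain.id}")
    iv = merged_by_chrom.get(domain.chrom)
    if iv is None:
        return 0.0
    return covered_length(domain.start, domain.end, iv) / domain.length


def _annotation_cover(annotation: AnnotationSet, gene_filter=None) -> dict[str, np.ndarray]:
    """Merged genomic spans of (optionally filtered) genes."""
    per_chrom: dict[str, list] = {}
    for gene in annotation.gene_list():
        if gene_filter is not None and not gene_filter(gene):
            continue
        per_chrom.setdefault(gene.chrom, []).append([gene.start, gene.end])
    return {
        c: merge_intervals(np.array(iv, dtype=np.int64))
        for c, iv in per_chrom.items()
    }


def _union_cover(*covers: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    out: dict[str, list[np.ndarray]] = {}
    for cover in covers:
        for chrom, iv in cover.items():
            if len(iv):
                out.setdefault(chrom, []).append(iv)
    return {c: merge_intervals(np.concatenate(ivs)) for c, ivs in out.items()}


# ---------------------------------------------------------------------------
# Explanation cascades
# ---------------------------------------------------------------------------

def explain_hyperds(
    domains: DomainSet,
    reference: AnnotationSet,
    assembly: AnnotationSet,
    contigs: ContigTrack | None = None,
    partial_meth_regions: FeatureTrack | None = None,
    stage: str = "default",
    ref_min_fpkm: float = 0.001,
    explain_cut: float = 0.5,
    untranscribed_cut: float = 0.05,
) -> tuple[list[DomainExplanation], dict]:
    """Assign each hypermethylated domain to its first explaining tier.

    Evidence tiers are cumulative: expressed reference genes (FPKM above
    ``ref_min_fpkm``), plus the transcriptome assembly, plus read contigs,
    plus regions of partial methylation in control methylomes.  A domain is
    explained by the first tier covering more than ``explain_cut`` of its
    length; a domain whose assembly+contig coverage stays below
    ``untranscribed_cut`` is additionally flagged untranscribed.
    """
    ref_cover = _annotation_cover(
        reference, lambda g: g.fpkm(stage) > ref_min_fpkm
    )
    asm_cover = _annotation_cover(assembly)
    tiers: list[tuple[str, dict[str, np.ndarray]]] = [
        ("reference_expressed", ref_cover),
        ("assembly", _union_cover(ref_cover, asm_cover)),
    ]
    if contigs is not None:
        with_contigs = _union_cover(tiers[-1][1], contigs.collapsed_per_chrom())
    else:
        with_contigs = tiers[-1][1]
    tiers.append(("assembly_plus_contigs", with_contigs))
    if partial_meth_regions is not None:
        with_partial = _union_cover(with_contigs, partial_meth_regions.merged_per_chrom())
    else:
        with_partial = with_contigs
    tiers.append(("plus_partial_meth", with_partial))

    explanations = []
    for d in domains.by_class(HYPER):
        fractions = {name: overlap_fraction(d, cover) for name, cover in tiers}
        tier = "unexplained"
        for name, _ in tiers:
            if fractions[name] > explain_cut:
                tier = name
                break
        explanations.append(
            DomainExplanation(
                domain_id=d.id,
                cls=HYPER,
                length=d.length,
                fractions=fractions,
                tier=tier,
                untranscribed=fractions["assembly_plus_contigs"] < untranscribed_cut,
            )
        )
    summary = _tier_summary(explanations, HYPERD_TIERS, "assembly_plus_contigs")
    summary["untranscribed_fraction"] = (
        float(np.mean([e.untranscribed for e in explanations]))
        if explanations
        else 0.0
    )
    return explanations, summary


def explain_hypods(
    domains: DomainSet,
    assembly: AnnotationSet,
    stage: str = "default",
    alt_tss_track: FeatureTrack | None = None,
    low_fpkm: float = 0.5,
    transcribed_cut: float = 0.5,
) -> tuple[list[DomainExplanation], dict]:
    """Explain hypomethylated domains that nevertheless lie in transcription.

    A domain overlapped by the assembly for more than ``transcribed_cut`` of
    its length is transcribed; it is attributed to weak transcription when the
    majority of its transcribed bases come from genes below ``low_fpkm``, or
    to an alternative downstream promoter when alt-TSS windows cover more than
    half of it; otherwise it remains unexplained-transcribed.  Everything else
    is untranscribed.
    """
    asm_cover = _annotation_cover(assembly)
    low_cover = _annotation_cover(
        assembly, lambda g: g.fpkm(stage) < low_fpkm
    )
    alt_cover = (
        alt_tss_track.merged_per_chrom() if alt_tss_track is not None else {}
    )
    explanations = []
    for d in domains.by_class(HYPO):
        frac_asm = overlap_fraction(d, asm_cover)
        frac_low = overlap_fraction(d, low_cover)
        frac_alt = overlap_fraction(d, alt_cover)
        fractions = {
            "assembly": frac_asm,
            "low_fpkm": frac_low,
            "alt_tss": frac_alt,
        }
        if frac_asm > transcribed_cut:
            if frac_low > frac_asm / 2:
                tier = "low_fpkm_gene"
            elif frac_alt > 0.5:
                tier = "alt_downstream_promoter"
            else:
                tier = "unexplained_transcribed"
        else:
            tier = "untranscribed"
        explanations.append(
            DomainExplanation(
                domain_id=d.id, cls=HYPO, length=d.length,
                fractions=fractions, tier=tier,
                untranscribed=(tier == "untranscribed"),
            )
        )
    summary = _tier_summary(explanations, HYPOD_TIERS, "assembly")
    return explanations, summary


def _tier_summary(
    explanations: list[DomainExplanation],
    tier_names: tuple[str, ...],
    weight_key: str,
) -> dict:
    n = len(explanations)
    tier_frac = {
        t: (sum(e.tier == t for e in explanations) / n if n else 0.0)
        for t in tier_names
    }
    total_len = sum(e.length for e in explanations)
    weighted = (
        sum(e.length * e.fractions[weight_key] for e in explanations) / total_len
        if total_len
        else 0.0
    )
    return {
        "n_domains": n,
        "tier_fractions": tier_frac,
        "length_weighted_overlap": float(weighted),
    }


def alt_tss_windows(
    assembly: AnnotationSet, extent: int = 2000
) -> FeatureTrack:
    """2-kbp downstream windows of non-most-upstream transcript TSSs."""
    rows = []
    for gene in assembly.gene_list():
        gene_tss = gene.most_upstream_tss
        for t in gene.transcripts:
            if t.tss == gene_tss:
                continue
            if t.strand == "-":
                s, e = max(0, t.tss - extent + 1), t.tss + 1
            else:
                s, e = t.tss, t.tss + extent
            rows.append((gene.chrom, s, e))
    return FeatureTrack(
        "mask", pd.DataFrame(rows, columns=["chrom", "start", "end"])
    ).normalized()


# ---------------------------------------------------------------------------
# Gene-body methylation
# ---------------------------------------------------------------------------

def gene_body_meth(
    gene_or_span: GeneModel | tuple[str, int, int],
    methylome: MethylomeTable,
    min_reads: int = 3,
    min_cpgs: int = 3,
) -> float | None:
    """Mean CpG methylation over a gene body (or raw span).

    Requires ``min_cpgs`` CpGs covered by ``min_reads`` reads; returns None
    when the region cannot be scored.
    """
    if isinstance(gene_or_span, GeneModel):
        chrom, start, end = gene_or_span.chrom, gene_or_span.start, gene_or_span.end
    else:
        chrom, start, end = gene_or_span
    pos, nm, nu = methylome.arrays(chrom)
    lo, hi = np.searchsorted(pos, [start, end])
    m, u = nm[lo:hi], nu[lo:hi]
    cov = m + u
    ok = cov >= min_reads
    if int(ok.sum()) < min_cpgs:
        return None
    return float((100.0 * m[ok] / cov[ok]).mean())


def fpkm_meth_relation(
    genes: list[GeneModel],
    methylome: MethylomeTable,
    stage: str = "default",
    bin_width: float = 0.1,
    unmeth_cut: float = 25.0,
    meth_cut: float = 75.0,
    max_fpkm: float | None = None,
) -> dict:
    """Proportion of unmethylated vs methylated gene bodies per FPKM bin.

    Gene-body methylation uses the 3-CpG / 3-read scoring rule.  The reported
    threshold is the upper edge of the last (highest) FPKM bin in which
    unmethylated gene bodies outnumber methylated ones.
    """
    rows = []
    n_unscored = 0
    for g in genes:
        meth = gene_body_meth(g, methylome)
        if meth is None:
            n_unscored += 1
            continue
        rows.append((g.fpkm(stage), meth))
    if not rows:
        raise ValueError("no scorable genes")
    df = pd.DataFrame(rows, columns=["fpkm", "meth"])
    if max_fpkm is not None:
        df = df[df["fpkm"] < max_fpkm]
    bins = (df["fpkm"] / bin_width).astype(int)
    per_bin = []
    for b in sorted(bins.unique()):
        sub = df[bins == b]
        n_unmeth = int((sub["meth"] < unmeth_cut).sum())
        n_meth = int((sub["meth"] > meth_cut).sum())
        per_bin.append(
            {
                "bin_low": b * bin_width,
                "bin_high": (b + 1) * bin_width,
                "n_genes": int(len(sub)),
                "n_unmeth": n_unmeth,
                "n_meth": n_meth,
                "frac_unmeth": n_unmeth / len(sub),
                "frac_meth": n_meth / len(sub),
            }
        )
    threshold = None
    for row in per_bin:
        if row["n_unmeth"] > row["n_meth"]:
            threshold = row["bin_high"]
    return {
        "bins": pd.DataFrame(per_bin),
        "threshold": threshold,
        "n_scored": int(len(df)),
        "n_unscored": n_unscored,
    }


def detect_escapees(
    genes: list[GeneModel],
    methylome: MethylomeTable,
    stage: str = "default",
    min_fpkm: float = 1.0,
    min_len: int = 10_000,
    max_meth: float = 25.0,
    window: int = 10_000,
    step: int = 5_000,
    min_scored_frac: float = 0.8,
) -> list[EscapeeGene]:
    """Find expressed, large genes whose entire body escapes methylation.

    Stage 1 screens by expression (FPKM above ``min_fpkm``), size and overall
    gene-body methylation below ``max_meth``.  Stage 2 tiles the gene with
    running windows scored by the gene-body rule; a candidate is confirmed
    when every scored window stays below ``max_meth`` and at least
    ``min_scored_frac`` of windows are scorable.
    """
    out = []
    for g in genes:
        fpkm = g.fpkm(stage)
        if fpkm <= min_fpkm or g.length < min_len:
            continue
        body = gene_body_meth(g, methylome)
        if body is None or body >= max_meth:
            continue
        starts = list(range(g.start, g.end - window + 1, step))
        if not starts:
            starts = [g.start]
        if starts[-1] + window < g.end:
            starts.append(g.end - window)
        scored = []
        for s in starts:
            w = gene_body_meth((g.chrom, s, min(s + window, g.end)), methylome)
            if w is not None:
                scored.append(w)
        n_win = len(starts)
        confirmed = (
            len(scored) >= min_scored_frac * n_win
            and all(w < max_meth for w in scored)
        )
        out.append(
            EscapeeGene(
                gene_id=g.id,
                fpkm=fpkm,
                length=g.length,
                gene_body_meth=body,
                n_windows=n_win,
                n_scored_windows=len(scored),
                max_window_meth=float(max(scored)) if scored else float("nan"),
                confirmed=confirmed,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

def feature_enrichment(
    group_a: list[Domain],
    group_b: list[Domain],
    feature_track: FeatureTrack,
    min_overlap: float = 0.5,
) -> dict:
    """Chi-squared contrast of feature overlap between two domain groups.

    Each domain counts as overlapped when the feature track covers more than
    ``min_overlap`` of its length.  The statistic is Pearson's chi-squared on
    the 2x2 table without continuity correction (1 df); a warning flag is set
    when any expected cell falls below 5 or the table is degenerate.
    """
    if not group_a or not group_b:
        raise ValueError("both domain groups must be non-empty")
    cover = feature_track.merged_per_chrom()
    counts = []
    for group in (group_a, group_b):
        hit = sum(overlap_fraction(d, cover) > min_overlap for d in group)
        counts.append([hit, len(group) - hit])
    table = np.array(counts, dtype=np.float64)
    warning = False
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        chi2, p = 0.0, 1.0
        warning = True
    else:
        chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
        warning = bool((expected < 5).any())
    return {
        "counts": [[int(c) for c in row] for row in counts],
        "chi2": float(chi2),
        "p": float(p),
        "warning": warning,
    }
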