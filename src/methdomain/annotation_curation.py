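"""Curation of a raw transcriptome assembly and TSS characterisation.

De novo assemblies of deep oocyte RNA-Seq are rich in artefacts, especially
among mono-exonic fragments.  This module implements the rule set that turns
a raw assembly into the curated oocyte gene set: the empirical expression
threshold separating assembled transcripts from random intergenic background
(maximum vertical gap between the two FPKM CDFs), strand/intron/3'-array
filters for mono-exonic transcripts, simplified Cuffcompare-style
classification against a reference annotation, novel-gene calling with
proximity and repeat exclusions, discovery of novel upstream TSSs, and
classification of TSSs by CpG-island and transposable-element context.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_io import (
    AnnotationSet,
    FeatureTrack,
    GeneModel,
    TranscriptModel,
    covered_length,
    merge_intervals,
)

REFERENCE_CODES = ("=", "c", "j", "o")
NOVEL_CODES = ("i", "x", "u")


@dataclass
class ThresholdResult:
    """Result of the CDF-gap expression-threshold procedure."""

    threshold: float
    cdf_gap: float
    grid: np.ndarray
    warning: bool = False


@dataclass
class TSSRecord:
    gene_id: str
    transcript_id: str
    chrom: str
    position: int
    strand: str
    tss_class: str | None = None   # CGI_associated / TE_associated / other
    te_family: str | None = None
    relation: str | None = None    # reference_tss / novel_upstream / downstream_alternative
    distance: int | None = None


@dataclass
class NovelGeneCall:
    gene_id: str
    mono_exonic: bool
    exclusion_reasons: set[str] = field(default_factory=set)

    @property
    def accepted(self) -> bool:
        return not self.exclusion_reasons


# ---------------------------------------------------------------------------
# Expression threshold (CDF gap)
# ---------------------------------------------------------------------------

def rabt_threshold(
    transcript_fpkms: Sequence[float], intergenic_fpkms: Sequence[float]
) -> ThresholdResult:
    """Threshold separating assembled transcripts from intergenic background.

    Both empirical CDFs are evaluated on the pooled value grid; the threshold
    is the grid point maximising ``CDF(intergenic) - CDF(transcripts)``, ties
    broken toward the smallest value.  Transcripts with FPKM at or below the
    threshold are considered non-transcribed.
    """
    tx = np.sort(np.asarray(transcript_fpkms, dtype=np.float64))
    ig = np.sort(np.asarray(intergenic_fpkms, dtype=np.float64))
    if len(tx) == 0 or len(ig) == 0:
        raise ValueError("both samples must be non-empty")
    grid = np.unique(np.concatenate([tx, ig]))
    f_tx = np.searchsorted(tx, grid, side="right") / len(tx)
    f_ig = np.searchsorted(ig, grid, side="right") / len(ig)
    gap = f_ig - f_tx
    idx = int(np.argmax(gap))  # first maximum = smallest grid value
    return ThresholdResult(
        threshold=float(grid[idx]),
        cdf_gap=float(gap[idx]),
        grid=grid,
        warning=len(grid) == 1,
    )


def sample_size_matched_intergenic(
    genome: Mapping[str, int],
    annotation: AnnotationSet,
    sizes: Sequence[int],
    n_per_size: int,
    seed: int,
    buffer: int = 1000,
) -> FeatureTrack:
    """Place random intervals of the requested sizes outside annotated genes.

    Genes are padded by ``buffer`` bp; each requested size is placed
    ``n_per_size`` times uniformly over all valid positions (gaps large
    enough to hold it).  Reproducible under ``seed``; raises when a size
    cannot be placed anywhere.
    """
    rng = np.random.default_rng(seed)
    gaps: list[tuple[str, int, int]] = []
    gene_iv: dict[str, list] = {}
    for g in annotation.gene_list():
        gene_iv.setdefault(g.chrom, []).append(
            [max(0, g.start - buffer), g.end + buffer]
        )
    for chrom in sorted(genome):
        length = genome[chrom]
        iv = gene_iv.get(chrom)
        merged = (
            merge_intervals(np.array(iv, dtype=np.int64))
            if iv
            else np.empty((0, 2), dtype=np.int64)
        )
        cur = 0
        for s, e in merged:
            if s > cur:
                gaps.append((chrom, cur, min(int(s), length)))
            cur = max(cur, int(e))
        if cur < length:
            gaps.append((chrom, cur, length))
    rows = []
    for size in sizes:
        valid = [(c, s, e) for c, s, e in gaps if e - s >= size]
        if not valid:
            raise ValueError(f"cannot place intergenic interval of size {size}")
        weights = np.array([e - s - size + 1 for _, s, e in valid], dtype=np.float64)
        probs = weights / weights.sum()
        picks = rng.choice(len(valid), size=n_per_size, p=probs)
        for k in picks:
            chrom, gs, ge = valid[k]
            offset = int(rng.integers(0, ge - gs - size + 1))
            rows.append((chrom, gs + offset, gs + offset + size))
    return FeatureTrack(
        "intergenic", pd.DataFrame(rows, columns=["chrom", "start", "end"])
    )


# ---------------------------------------------------------------------------
# Mono-exonic curation
# ---------------------------------------------------------------------------

def curate_monoexonic(
    annotation: AnnotationSet,
    read_support: Mapping[str, object],
    merge_window: int = 2000,
) -> tuple[AnnotationSet, dict]:
    """Apply the mono-exonic curation rules, in order.

    (a) drop unstranded mono-exonic transcripts; (b) drop mono-exonic
    transcripts fully inside an intron of a same-strand multi-exonic
    transcript of another gene; (c) merge mono-exonic transcripts lying
    within ``merge_window`` bp downstream of a multi-exonic transcript's 3'
    end (iterated to fixpoint, so arrays of fragments chain into the host);
    (d) drop mono-exonic genes whose depth-normalised read count does not
    exceed the threshold derived from random intergenic counts via the
    CDF-gap procedure.

    ``read_support`` must provide ``transcript_counts`` (per-transcript
    normalised counts) and ``intergenic_counts`` (normalised counts of random
    size-matched intergenic regions).
    """
    report = {"no_strand": 0, "intronic": 0, "merged_3prime": 0, "low_count": 0}
    transcripts = {t.id: t for t in annotation.transcript_list()}

    # (a) unstranded mono-exonic transcripts
    for tid in list(transcripts):
        t = transcripts[tid]
        if t.mono_exonic and t.strand == ".":
            del transcripts[tid]
            report["no_strand"] += 1

    # (b) intronic same-strand mono-exonic transcripts
    introns: dict[tuple[str, str], list[tuple[int, int, str]]] = {}
    for t in transcripts.values():
        if not t.mono_exonic:
            for s, e in t.introns():
                introns.setdefault((t.chrom, t.strand), []).append((s, e, t.gene_id))
    for tid in list(transcripts):
        t = transcripts[tid]
        if not t.mono_exonic:
            continue
        for s, e, gid in introns.get((t.chrom, t.strand), ()):
            if gid != t.gene_id and t.start >= s and t.end <= e:
                del transcripts[tid]
                report["intronic"] += 1
                break

    # (c) 3' merging, iterated to fixpoint
    changed = True
    while changed:
        changed = False
        hosts = [t for t in transcripts.values() if not t.mono_exonic]
        for tid in sorted(
            t.id for t in transcripts.values() if t.mono_exonic
        ):
            mono = transcripts[tid]
            best: tuple[int, str] | None = None
            for host in hosts:
                if host.chrom != mono.chrom or host.strand != mono.strand:
                    continue
                if host.strand == "+":
                    gap = mono.start - host.end
                else:
                    gap = host.start - mono.end
                if 0 <= gap <= merge_window:
                    if best is None or (gap, host.id) < best:
                        best = (gap, host.id)
            if best is not None:
                host = transcripts[best[1]]
                host.exons = sorted(host.exons + [mono.exons[0]])
                for stage, value in mono.fpkm.items():
                    host.fpkm[stage] = host.fpkm.get(stage, 0.0) + value
                del transcripts[tid]
                report["merged_3prime"] += 1
                changed = True
        # hosts' 3' ends moved; loop again until no mono merges

    # (d) read-count filter on mono-exonic genes
    tentative = AnnotationSet(transcripts.values())
    mono_genes = [g for g in tentative.gene_list() if g.mono_exonic]
    if mono_genes:
        counts = read_support["transcript_counts"]
        intergenic = list(read_support["intergenic_counts"])
        gene_counts = {}
        for g in mono_genes:
            total = 0.0
            for t in g.transcripts:
                if t.id not in counts:
                    raise ValueError(f"missing read support for transcript {t.id}")
                total += float(counts[t.id])
            gene_counts[g.id] = total
        thr = rabt_threshold(list(gene_counts.values()), intergenic)
        report["count_threshold"] = thr.threshold
        for g in mono_genes:
            if gene_counts[g.id] <= thr.threshold:
                for t in g.transcripts:
                    del transcripts[t.id]
                report["low_count"] += 1
    else:
        report["count_threshold"] = None
    return AnnotationSet(transcripts.values()), report


def reconcile_annotations(
    primary: AnnotationSet,
    patches: Sequence[AnnotationSet],
    fpkm_table: Mapping[str, float],
    threshold: float,
) -> AnnotationSet:
    """Restore transcripts missing from the primary annotation.

    A transcript present in a patch set but absent from the primary one is
    re-integrated when its (re-quantified) FPKM exceeds the threshold.
    """
    transcripts = {t.id: t for t in primary.transcript_list()}
    for patch in patches:
        for t in patch.transcript_list():
            if t.id in transcripts:
                continue
            fpkm = fpkm_table.get(t.id, 0.0)
            if fpkm > threshold:
                restored = TranscriptModel(
                    id=t.id, gene_id=t.gene_id, chrom=t.chrom,
                    strand=t.strand, exons=list(t.exons),
                    category=t.category, fpkm=dict(t.fpkm),
                )
                restored.fpkm.setdefault("default", fpkm)
                transcripts[t.id] = restored
    return AnnotationSet(transcripts.values())


# ---------------------------------------------------------------------------
# Classification against the reference
# ---------------------------------------------------------------------------

def _exonic_overlap(a: TranscriptModel, b: TranscriptModel) -> int:
    total = 0
    for s1, e1 in a.exons:
        for s2, e2 in b.exons:
            total += max(0, min(e1, e2) - max(s1, s2))
    return total


def _classify_pair(t: TranscriptModel, r: TranscriptModel) -> str | None:
    """Best class code of transcript ``t`` against reference transcript ``r``."""
    same_strand = t.strand == r.strand
    exonic = _exonic_overlap(t, r)
    t_introns, r_introns = t.introns(), r.introns()
    if same_strand:
        if t_introns and t_introns == r_introns:
            return "="
        if not t_introns and not r_introns and t.exons == r.exons:
            return "="
        # containment
        if exonic > 0 and t.start >= r.start and t.end <= r.end:
            if not t_introns:
                if any(t.start >= s and t.end <= e for s, e in r.exons):
                    return "c"
            elif _is_contiguous_subchain(t_introns, r_introns):
                return "c"
        if t_introns and set(t_introns) & set(r_introns):
            return "j"
        if exonic > 0:
            return "o"
    for s, e in r.introns():
        if t.start >= s and t.end <= e:
            return "i"
    if not same_strand and exonic > 0:
        return "x"
    return None


def _is_contiguous_subchain(
    sub: list[tuple[int, int]], chain: list[tuple[int, int]]
) -> bool:
    n, m = len(sub), len(chain)
    return any(chain[i : i + n] == sub for i in range(m - n + 1))


_CODE_RANK = {"=": 0, "c": 1, "j": 2, "o": 3, "i": 4, "x": 5, "u": 6}


def classify_vs_reference(
    oocyte: AnnotationSet, reference: AnnotationSet
) -> dict[str, tuple[str, str | None]]:
    """Simplified Cuffcompare classification of every oocyte transcript.

    Returns ``transcript_id -> (code, reference_gene_id)`` where the
    reference gene is that of the best-matching reference transcript (None
    for code ``u``).  Codes ``=``, ``c``, ``j``, ``o`` mark transcripts of
    reference genes; ``i``, ``x``, ``u`` mark novel transcripts.
    """
    ref_by_chrom: dict[str, list[TranscriptModel]] = {}
    for r in reference.transcript_list():
        ref_by_chrom.setdefault(r.chrom, []).append(r)
    for lst in ref_by_chrom.values():
        lst.sort(key=lambda r: r.start)
    out: dict[str, tuple[str, str | None]] = {}
    for t in oocyte.transcript_list():
        best_code, best_ref = "u", None
        for r in ref_by_chrom.get(t.chrom, ()):
            if r.start >= t.end:
                break
            if r.end <= t.start:
                continue
            code = _classify_pair(t, r)
            if code is not None and _CODE_RANK[code] < _CODE_RANK[best_code]:
                best_code, best_ref = code, r.gene_id
                if best_code == "=":
                    break
        out[t.id] = (best_code, best_ref)
    return out


def gene_category(
    annotation: AnnotationSet, categories: Mapping[str, tuple[str, str | None]]
) -> dict[str, str]:
    """Gene-level label: ``novel`` when no member transcript matches the
    reference, else ``reference``."""
    out = {}
    for g in annotation.gene_list():
        codes = {categories[t.id][0] for t in g.transcripts}
        out[g.id] = "novel" if codes <= set(NOVEL_CODES) else "reference"
    return out


# ---------------------------------------------------------------------------
# Novel genes
# ---------------------------------------------------------------------------

def _span_gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Gap between two spans; 0 when they overlap."""
    if a_start < b_end and b_start < a_end:
        return 0
    return max(b_start - a_end, a_start - b_end)


def call_novel_genes(
    oocyte: AnnotationSet,
    reference: AnnotationSet,
    noncode_track: FeatureTrack | None,
    te_track: FeatureTrack | None,
    categories: Mapping[str, tuple[str, str | None]] | None = None,
    multi_margin: int = 1000,
    mono_margin: int = 5000,
    repeat_cover: float = 0.5,
) -> list[NovelGeneCall]:
    """Call high-confidence novel genes among unmatched assembly genes.

    Candidate genes (no transcript matching the reference) are excluded when
    they lie within the proximity margin of a same-strand reference gene or
    known ncRNA (1 kbp for multi-exonic, 5 kbp for mono-exonic genes,
    measured between closest span edges), or — for mono-exonic genes — when a
    single transposable element covers at least ``repeat_cover`` of the
    exonic span.
    """
    if categories is None:
        categories = classify_vs_reference(oocyte, reference)
    gene_cat = gene_category(oocyte, categories)
    ref_spans: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for g in reference.gene_list():
        ref_spans.setdefault((g.chrom, g.strand), []).append((g.start, g.end))
    nc_spans: dict[tuple[str, str], list[tuple[int, int]]] = {}
    if noncode_track is not None:
        for r in noncode_track.df.itertuples():
            nc_spans.setdefault((r.chrom, r.strand), []).append(
                (int(r.start), int(r.end))
            )
    te_by_chrom = {}
    if te_track is not None:
        for chrom, sub in te_track.df.groupby("chrom", sort=True):
            te_by_chrom[str(chrom)] = sub[["start", "end"]].to_numpy()
    calls = []
    for g in oocyte.gene_list():
        if gene_cat[g.id] != "novel":
            continue
        margin = mono_margin if g.mono_exonic else multi_margin
        call = NovelGeneCall(gene_id=g.id, mono_exonic=g.mono_exonic)
        for spans, reason in ((ref_spans, "near_reference"), (nc_spans, "near_noncode")):
            for s, e in spans.get((g.chrom, g.strand), ()):
                if _span_gap(g.start, g.end, s, e) <= margin:
                    call.exclusion_reasons.add(reason)
                    break
        if g.mono_exonic and g.chrom in te_by_chrom:
            exonic = np.array(
                sorted(
                    {(s, e) for t in g.transcripts for s, e in t.exons}
                ),
                dtype=np.int64,
            )
            exonic = merge_intervals(exonic)
            exonic_len = int((exonic[:, 1] - exonic[:, 0]).sum())
            for s, e in te_by_chrom[g.chrom]:
                cov = covered_length(int(s), int(e), exonic)
                if cov >= repeat_cover * exonic_len:
                    call.exclusion_reasons.add("repeat_monoexonic")
                    break
        calls.append(call)
    return calls


# ---------------------------------------------------------------------------
# Novel upstream TSSs
# ---------------------------------------------------------------------------

def find_novel_upstream_tss(
    oocyte: AnnotationSet,
    reference: AnnotationSet,
    cgi_track: FeatureTrack | None,
    categories: Mapping[str, tuple[str, str | None]] | None = None,
    cgi_margin: int = 100,
) -> tuple[list[TSSRecord], dict]:
    """Reference genes gaining an upstream TSS in the oocyte assembly.

    A gene qualifies when one of its assembly transcripts starts upstream of
    the reference most-upstream TSS on the same strand, in an exon sharing no
    base with any reference exon of that gene, and outside every CGI
    associated with a reference TSS (within ``cgi_margin`` bp).  One record
    per gene (the most upstream qualifying start) with the distance to the
    reference TSS; the summary reports the count and median distance.
    """
    if categories is None:
        categories = classify_vs_reference(oocyte, reference)
    # CGIs associated with any reference most-upstream TSS
    ref_tss_cgis: dict[str, list[tuple[int, int]]] = {}
    if cgi_track is not None:
        cgi_by_chrom = cgi_track.per_chrom()
        for g in reference.gene_list():
            iv = cgi_by_chrom.get(g.chrom)
            if iv is None:
                continue
            tss = g.most_upstream_tss
            for s, e in iv:
                if s <= tss + cgi_margin and tss - cgi_margin < e:
                    ref_tss_cgis.setdefault(g.chrom, []).append((int(s), int(e)))
    ref_exons: dict[str, list[tuple[int, int]]] = {}
    for g in reference.gene_list():
        ref_exons[g.id] = sorted(
            {(s, e) for t in g.transcripts for s, e in t.exons}
        )
    best: dict[str, TSSRecord] = {}
    for t in oocyte.transcript_list():
        code, ref_gid = categories.get(t.id, ("u", None))
        if code not in REFERENCE_CODES or ref_gid is None:
            continue
        ref_gene = reference.genes[ref_gid]
        if t.strand != ref_gene.strand:
            continue
        ref_tss = ref_gene.most_upstream_tss
        tss = t.tss
        upstream = tss < ref_tss if t.strand == "+" else tss > ref_tss
        if not upstream:
            continue
        first_exon = t.exons[0] if t.strand == "+" else t.exons[-1]
        if any(
            first_exon[0] < e and s < first_exon[1]
            for s, e in ref_exons[ref_gid]
        ):
            continue
        if any(
            s <= tss < e for s, e in ref_tss_cgis.get(t.chrom, ())
        ):
            continue
        rec = TSSRecord(
            gene_id=ref_gid,
            transcript_id=t.id,
            chrom=t.chrom,
            position=tss,
            strand=t.strand,
            relation="novel_upstream",
            distance=abs(tss - ref_tss),
        )
        cur = best.get(ref_gid)
        if cur is None or rec.distance > cur.distance:
            best[ref_gid] = rec
    records = [best[g] for g in sorted(best)]
    distances = [r.distance for r in records]
    summary = {
        "n_genes": len(records),
        "median_distance": float(np.median(distances)) if distances else None,
    }
    return records, summary


# ---------------------------------------------------------------------------
# TSS classification and TE expectation
# ---------------------------------------------------------------------------

def classify_tss(
    tss_records: Iterable[TSSRecord],
    cgi_track: FeatureTrack | None,
    te_track: FeatureTrack | None,
    cgi_margin: int = 100,
) -> list[TSSRecord]:
    """Classify TSSs as CGI-associated, TE-associated or other.

    The CGI test applies first, on a window of ``cgi_margin`` bp around the
    first transcribed base; the TE test requires single-base overlap with an
    element on the same strand and records its family.
    """
    cgi_by_chrom = cgi_track.per_chrom() if cgi_track is not None else {}
    te_df = te_track.df if te_track is not None else None
    records = list(tss_records)
    for rec in records:
        rec.tss_class = "other"
        rec.te_family = None
        iv = cgi_by_chrom.get(rec.chrom)
        if iv is not None and len(iv):
            s = iv[:, 0] <= rec.position + cgi_margin
            e = iv[:, 1] > rec.position - cgi_margin
            if bool((s & e).any()):
                rec.tss_class = "CGI_associated"
                continue
        if te_df is not None:
            hits = te_df[
                (te_df["chrom"] == rec.chrom)
                & (te_df["start"] <= rec.position)
                & (te_df["end"] > rec.position)
                & (te_df["strand"] == rec.strand)
            ]
            if len(hits):
                rec.tss_class = "TE_associated"
                rec.te_family = str(hits.iloc[0]["name"])
    return records


def gene_tss_records(annotation: AnnotationSet) -> list[TSSRecord]:
    """One TSS record per gene at its most upstream start."""
    return [
        TSSRecord(
            gene_id=g.id,
            transcript_id=g.transcripts[0].id,
            chrom=g.chrom,
            position=g.most_upstream_tss,
            strand=g.strand,
            relation="reference_tss",
        )
        for g in annotation.gene_list()
    ]


def te_tss_expectation(
    te_track: FeatureTrack,
    intergenic_track: FeatureTrack,
    observed_counts: Mapping[str, int],
    seed: int,
    n_draws: int = 100,
) -> pd.DataFrame:
    """Observed vs expected TSS counts per TE family under random placement.

    Expectation is from uniform placement of the observed total number of
    TSSs over intergenic space, Monte-Carlo averaged over ``n_draws`` seeded
    draws; the analytic expectation (total x occupancy fraction) and a
    two-sided binomial p value are reported alongside.  Families absent from
    the track are skipped.
    """
    rng = np.random.default_rng(seed)
    inter = intergenic_track.merged_per_chrom()
    chroms = sorted(inter)
    lengths = np.array(
        [(inter[c][:, 1] - inter[c][:, 0]).sum() for c in chroms], dtype=np.int64
    )
    total_bp = int(lengths.sum())
    if total_bp == 0:
        raise ValueError("intergenic track is empty")
    n_total = int(sum(observed_counts.values()))
    # family occupancy inside intergenic space
    fam_iv: dict[str, dict[str, np.ndarray]] = {}
    for fam, sub in te_track.df.groupby("name", sort=True):
        fam_iv[str(fam)] = {
            str(c): merge_intervals(s[["start", "end"]].to_numpy())
            for c, s in sub.groupby("chrom", sort=True)
        }
    rows = []
    for fam, observed in sorted(observed_counts.items()):
        if fam not in fam_iv:
            rows.append(
                {"family": fam, "skipped": True, "observed": observed}
            )
            continue
        occ = 0
        restricted: dict[str, np.ndarray] = {}
        for chrom in chroms:
            fam_merged = fam_iv[fam].get(chrom)
            if fam_merged is None:
                continue
            pieces = []
            for s, e in inter[chrom]:
                for fs, fe in fam_merged:
                    lo, hi = max(int(s), int(fs)), min(int(e), int(fe))
                    if hi > lo:
                        pieces.append([lo, hi])
            if pieces:
                restricted[chrom] = merge_intervals(np.array(pieces, dtype=np.int64))
                occ += int(
                    (restricted[chrom][:, 1] - restricted[chrom][:, 0]).sum()
                )
        frac = occ / total_bp
        # Monte-Carlo placement
        hits = np.zeros(n_draws)
        chrom_probs = lengths / total_bp
        for d in range(n_draws):
            counts = rng.multinomial(n_total, chrom_probs)
            h = 0
            for ci, chrom in enumerate(chroms):
                k = int(counts[ci])
                if k == 0 or chrom not in restricted:
                    continue
                # uniform offsets in the concatenated intergenic space
                gaps = inter[chrom]
                gap_lens = gaps[:, 1] - gaps[:, 0]
                cum = np.concatenate(([0], np.cumsum(gap_lens)))
                offs = rng.integers(0, cum[-1], size=k)
                gi = np.searchsorted(cum, offs, side="right") - 1
                pos = gaps[gi, 0] + (offs - cum[gi])
                merged = restricted[chrom]
                idx = np.searchsorted(merged[:, 0], pos, side="right") - 1
                ok = idx >= 0
                h += int((pos[ok] < merged[idx[ok], 1]).sum())
            hits[d] = h
        expected_mc = float(hits.mean())
        expected = n_total * frac
        p = (
            stats.binomtest(observed, n_total, frac).pvalue
            if 0 < frac < 1
            else (1.0 if observed == 0 else 0.0)
        )
        rows.append(
            {
                "family": fam,
                "skipped": False,
                "observed": observed,
                "occupancy_frac": frac,
                "expected": expected,
                "expected_mc": expected_mc,
                "ratio": observed / expected if expected > 0 else np.inf,
                "p": float(p),
            }
        )
    return pd.DataFrame(rows)
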