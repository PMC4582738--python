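"""Segmentation of a methylome into hyper- and hypomethylated domains.

The oocyte methylome is strongly bimodal: most CpGs are either close to fully
methylated or close to unmethylated, and like states cluster into large
genomic blocks.  This module turns per-CpG counts into those blocks:

1. sliding probes of ``window_n_cpgs`` consecutive covered CpGs, advanced by
   ``step_n_cpgs`` CpGs, scored by mean per-CpG methylation;
2. probes above ``hyper_cut`` / below ``hypo_cut`` merged into raw domains,
   with overlaps between opposite classes split at the midpoint;
3. a refinement cascade (gap merging, absorption of sub-kilobase opposite
   islands, removal of sub-minimum domains, a final gap merge);
4. exclusion masking (CGIs, promoter regions, pre-methylated control regions)
   with parent-domain lineage preserved across splits.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .genomic_io import (
    AnnotationSet,
    FeatureTrack,
    MethylomeTable,
    merge_intervals,
)

HYPER = "hyper"
HYPO = "hypo"


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable parameters of the domain caller.

    The defaults are the primary analysis conditions (50-CpG probes stepped by
    10 CpGs); ``preset("10_5")`` gives the finer alternative probe size used
    as a robustness check.
    """

    window_n_cpgs: int = 50
    step_n_cpgs: int = 10
    min_reads_per_cpg: int = 5
    min_scored_cpgs: int = 3
    hyper_cut: float = 75.0
    hypo_cut: float = 25.0
    merge_gap: int = 2000
    opposite_absorb_max: int = 1000
    min_domain_len: int = 2000
    #: seed selection is strict (>hyper_cut, <hypo_cut) by default; set False
    #: to use inclusive comparisons instead.
    strict_cuts: bool = True

    def __post_init__(self) -> None:
        if self.step_n_cpgs > self.window_n_cpgs:
            raise ValueError("step must not exceed window size")
        if self.hypo_cut >= self.hyper_cut:
            raise ValueError("hypo_cut must be below hyper_cut")
        for name in ("window_n_cpgs", "step_n_cpgs", "merge_gap",
                     "opposite_absorb_max", "min_domain_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def preset(cls, name: str) -> "SegmentationParams":
        if name in ("50_10", "paper_50_10"):
            return cls()
        if name in ("10_5", "paper_10_5"):
            return cls(window_n_cpgs=10, step_n_cpgs=5)
        raise ValueError(f"unknown preset {name!r}")


@dataclass(frozen=True)
class MethWindow:
    """A probe over ``member_cpg_count`` consecutive covered CpGs."""

    chrom: str
    start: int  # first member CpG
    end: int    # last member CpG + 1
    member_cpg_count: int
    scored_cpg_count: int
    meth_pct: float | None  # None when too few CpGs pass the read filter


@dataclass
class Domain:
    """A contiguous block of concordant methylation state."""

    id: str
    parent_id: str
    cls: str  # HYPER or HYPO
    chrom: str
    start: int
    end: int
    merged_over_gap: bool = False
    absorbed_opposite: bool = False
    split_by_mask: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


class DomainSet:
    """Sorted, pairwise non-overlapping domains."""

    def __init__(self, domains: Iterable[Domain]) -> None:
        self.domains = sorted(domains, key=lambda d: (d.chrom, d.start, d.end))
        prev: Domain | None = None
        for d in self.domains:
            if prev is not None and prev.chrom == d.chrom and d.start < prev.end:
                raise ValueError(
                    f"overlapping domains {prev.id} and {d.id}"
                )
            prev = d

    def __iter__(self) -> Iterator[Domain]:
        return iter(self.domains)

    def __len__(self) -> int:
        return len(self.domains)

    def by_class(self, cls: str) -> list[Domain]:
        return [d for d in self.domains if d.cls == cls]

    def per_chrom(self) -> dict[str, list[Domain]]:
        out: dict[str, list[Domain]] = {}
        for d in self.domains:
            out.setdefault(d.chrom, []).append(d)
        return out

    def merged_per_chrom(self, cls: str | None = None) -> dict[str, np.ndarray]:
        out: dict[str, list[list[int]]] = {}
        for d in self.domains:
            if cls is None or d.cls == cls:
                out.setdefault(d.chrom, []).append([d.start, d.end])
        return {
            c: merge_intervals(np.array(iv, dtype=np.int64))
            for c, iv in out.items()
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "id": d.id,
                    "parent_id": d.parent_id,
                    "class": d.cls,
                    "chrom": d.chrom,
                    "start": d.start,
                    "end": d.end,
                    "length": d.length,
                    "merged_over_gap": d.merged_over_gap,
                    "absorbed_opposite": d.absorbed_opposite,
                    "split_by_mask": d.split_by_mask,
                }
                for d in self.domains
            ]
        )


# ---------------------------------------------------------------------------
# Windowing
# ---------------------------------------------------------------------------

def make_windows(
    methylome: MethylomeTable, params: SegmentationParams = SegmentationParams()
) -> list[MethWindow]:
    """Build sliding probes over covered CpGs, per chromosome.

    Probes are anchored on CpGs with data (any coverage); the methylation
    level of a probe is the mean per-CpG methylation over member CpGs passing
    the ``min_reads_per_cpg`` filter, and is undefined when fewer than
    ``min_scored_cpgs`` such CpGs are present.  Trailing stretches shorter
    than one full probe yield no probe.
    """
    from fractions import Fraction

    win, step = params.window_n_cpgs, params.step_n_cpgs
    windows: list[MethWindow] = []
    for chrom in methylome.chroms():
        pos, nm, nu = methylome.arrays(chrom)
        cov = nm + nu
        has_data = cov >= 1
        pos, nm, cov = pos[has_data], nm[has_data], cov[has_data]
        n = len(pos)
        if n < win:
            continue
        scored = cov >= params.min_reads_per_cpg
        pct = np.zeros(n, dtype=np.float64)
        pct[scored] = 100.0 * nm[scored] / cov[scored]
        csum_scored = np.concatenate(([0], np.cumsum(scored)))
        csum_pct = np.concatenate(([0.0], np.cumsum(pct * scored)))
        starts = np.arange(0, n - win + 1, step)
        for a in starts:
            b = a + win
            k = int(csum_scored[b] - csum_scored[a])
            if k >= params.min_scored_cpgs:
                meth = float((csum_pct[b] - csum_pct[a]) / k)
                # window means sitting numerically on a classification cut
                # are recomputed exactly, so strict threshold comparisons do
                # not depend on float summation order
                if (
                    abs(meth - params.hyper_cut) < 1e-6
                    or abs(meth - params.hypo_cut) < 1e-6
                ):
                    sl = slice(a, b)
                    exact = sum(
                        Fraction(100 * int(m), int(c))
                        for m, c, s in zip(nm[sl], cov[sl], scored[sl])
                        if s
                    ) / k
                    meth = float(exact)
            else:
                meth = None
            windows.append(
                MethWindow(
                    chrom=chrom,
                    start=int(pos[a]),
                    end=int(pos[b - 1]) + 1,
                    member_cpg_count=win,
                    scored_cpg_count=k,
                    meth_pct=meth,
                )
            )
    return windows


# ---------------------------------------------------------------------------
# Raw domain formation
# ---------------------------------------------------------------------------

def _class_runs(
    windows: Sequence[MethWindow], params: SegmentationParams
) -> dict[str, list[list]]:
    """Union overlapping/bookended seed windows per chromosome and class."""
    runs: dict[str, dict[str, list]] = {}
    for w in windows:
        if w.meth_pct is None:
            continue
        if params.strict_cuts:
            if w.meth_pct > params.hyper_cut:
                cls = HYPER
            elif w.meth_pct < params.hypo_cut:
                cls = HYPO
            else:
                continue
        else:
            if w.meth_pct >= params.hyper_cut:
                cls = HYPER
            elif w.meth_pct <= params.hypo_cut:
                cls = HYPO
            else:
                continue
        runs.setdefault(w.chrom, {}).setdefault(cls, []).append(
            [w.start, w.end]
        )
    out: dict[str, list[list]] = {}
    for chrom, by_cls in runs.items():
        merged = []
        for cls, iv in by_cls.items():
            for s, e in merge_intervals(np.array(iv, dtype=np.int64)):
                merged.append([int(s), int(e), cls])
        merged.sort(key=lambda r: (r[0], r[1]))
        out[chrom] = merged
    return out


def raw_domains(
    windows: Sequence[MethWindow], params: SegmentationParams = SegmentationParams()
) -> DomainSet:
    """Merge seed windows into non-overlapping raw domains.

    Where a hypermethylated run overlaps a hypomethylated run, the shared span
    is cut at its (floor) midpoint, the left part going to the left domain.
    If a run is fully contained in an opposite-class run, the containing run's
    remainder past the contained run survives as a separate piece.
    """
    per_chrom = _class_runs(windows, params)
    domains: list[Domain] = []
    for chrom, runs in per_chrom.items():
        out: list[list] = []
        pending = list(runs)
        i = 0
        while i < len(pending):
            cur = list(pending[i])
            i += 1
            while out and out[-1][1] > cur[0]:
                prev = out[-1]
                if prev[2] == cur[2]:
                    cur[0] = min(cur[0], prev[0])
                    cur[1] = max(cur[1], prev[1])
                    out.pop()
                    continue
                shared_s, shared_e = cur[0], min(prev[1], cur[1])
                mid = (shared_s + shared_e) // 2
                if prev[1] > cur[1]:
                    # containment: emit the tail of prev after cur later
                    tail = [cur[1], prev[1], prev[2]]
                    j = i
                    while j < len(pending) and (
                        pending[j][0], pending[j][1]
                    ) < (tail[0], tail[1]):
                        j += 1
                    pending.insert(j, tail)
                prev[1] = mid
                cur[0] = mid
                if prev[0] >= prev[1]:
                    out.pop()
                if cur[0] >= cur[1]:
                    break
            if cur[0] < cur[1]:
                out.append(cur)
        for s, e, cls in out:
            domains.append(
                Domain(
                    id="", parent_id="", cls=cls, chrom=chrom, start=s, end=e
                )
            )
    return _assign_ids(domains)


def _assign_ids(domains: list[Domain]) -> DomainSet:
    domains = sorted(domains, key=lambda d: (d.chrom, d.start, d.end))
    counters = {HYPER: 0, HYPO: 0}
    for d in domains:
        counters[d.cls] += 1
        d.id = f"{d.cls}_{counters[d.cls]:05d}"
        d.parent_id = d.id
    return DomainSet(domains)


# ---------------------------------------------------------------------------
# Refinement cascade
# ---------------------------------------------------------------------------

def _merge_gap_pass(doms: list[Domain], gap: int) -> list[Domain]:
    out: list[Domain] = []
    for d in doms:
        if (
            out
            and out[-1].cls == d.cls
            and d.start - out[-1].end < gap
        ):
            prev = out[-1]
            merged_flag = prev.merged_over_gap or d.merged_over_gap or (
                d.start > prev.end
            )
            out[-1] = replace(
                prev,
                end=max(prev.end, d.end),
                merged_over_gap=merged_flag,
                absorbed_opposite=prev.absorbed_opposite or d.absorbed_opposite,
            )
        else:
            out.append(d)
    return out


def _absorb_pass(doms: list[Domain], max_len: int) -> list[Domain]:
    changed = True
    doms = list(doms)
    while changed:
        changed = False
        for i in range(1, len(doms) - 1):
            mid = doms[i]
            left, right = doms[i - 1], doms[i + 1]
            if (
                mid.length < max_len
                and left.cls == right.cls
                and mid.cls != left.cls
            ):
                merged = replace(
                    left,
                    end=right.end,
                    absorbed_opposite=True,
                    merged_over_gap=left.merged_over_gap
                    or right.merged_over_gap,
                )
                doms[i - 1 : i + 2] = [merged]
                changed = True
                break
    return doms


def refine_domains(
    raw: DomainSet, params: SegmentationParams = SegmentationParams()
) -> DomainSet:
    """Apply the four-pass refinement cascade, per chromosome.

    Passes, in order: (1) merge same-class neighbours separated by less than
    ``merge_gap``; (2) absorb opposite-class domains shorter than
    ``opposite_absorb_max`` lying between two same-class domains, deleting the
    small domain and incorporating its span; (3) remove domains shorter than
    ``min_domain_len``; (4) repeat the gap merge.  The cascade is idempotent.
    """
    refined: list[Domain] = []
    for chrom, doms in raw.per_chrom().items():
        doms = _merge_gap_pass(doms, params.merge_gap)
        doms = _absorb_pass(doms, params.opposite_absorb_max)
        doms = [d for d in doms if d.length >= params.min_domain_len]
        doms = _merge_gap_pass(doms, params.merge_gap)
        refined.extend(doms)
    return _assign_ids(refined)


def call_domains(
    methylome: MethylomeTable, params: SegmentationParams = SegmentationParams()
) -> DomainSet:
    """Windowing, raw merge and refinement in one call (no masking)."""
    return refine_domains(raw_domains(make_windows(methylome, params), params), params)


# ---------------------------------------------------------------------------
# Exclusion masks
# ---------------------------------------------------------------------------

def premethylated_mask(
    control_methylomes: Sequence[MethylomeTable],
    window: int = 1000,
    min_reads: int = 3,
    min_cpgs: int = 3,
    cutoff: float = 50.0,
) -> FeatureTrack:
    """Mask of regions already methylated in any control methylome.

    The genome is tiled with ``window``-bp bins; a bin is scored in a control
    when it holds at least ``min_cpgs`` CpGs covered by at least ``min_reads``
    reads, and masked when its mean methylation reaches ``cutoff`` percent in
    ANY control.  Adjacent masked bins are merged.
    """
    if not control_methylomes:
        raise ValueError("at least one control methylome required")
    masked: dict[str, set[int]] = {}
    for control in control_methylomes:
        for chrom in control.chroms():
            pos, nm, nu = control.arrays(chrom)
            cov = nm + nu
            ok = cov >= min_reads
            if not ok.any():
                continue
            bins = pos[ok] // window
            pct = 100.0 * nm[ok] / cov[ok]
            n_bins = int(bins.max()) + 1
            counts = np.bincount(bins, minlength=n_bins)
            sums = np.bincount(bins, weights=pct, minlength=n_bins)
            with np.errstate(invalid="ignore", divide="ignore"):
                means = sums / counts
            hit = np.nonzero((counts >= min_cpgs) & (means >= cutoff))[0]
            masked.setdefault(chrom, set()).update(int(b) for b in hit)
    rows = []
    for chrom, bins in masked.items():
        iv = np.array(
            [[b * window, (b + 1) * window] for b in sorted(bins)],
            dtype=np.int64,
        )
        for s, e in merge_intervals(iv):
            rows.append((chrom, int(s), int(e)))
    return FeatureTrack(
        "mask", pd.DataFrame(rows, columns=["chrom", "start", "end"])
    )


def tss_mask(annotation: AnnotationSet, extent: int = 2000) -> FeatureTrack:
    """Promoter mask: ``extent`` bp downstream of each gene's most upstream
    TSS, extended in the direction of transcription, merged."""
    rows = []
    for gene in annotation.gene_list():
        tss = gene.most_upstream_tss
        if gene.strand == "-":
            start, end = max(0, tss - extent + 1), tss + 1
        else:
            start, end = tss, tss + extent
        rows.append((gene.chrom, start, end))
    track = FeatureTrack(
        "mask", pd.DataFrame(rows, columns=["chrom", "start", "end"])
    )
    return track.normalized()


def apply_masks(
    domains: DomainSet, masks: Sequence[FeatureTrack]
) -> tuple[DomainSet, list[str]]:
    """Subtract mask spans from every domain, preserving parent lineage.

    Fragments keep the parent's class and ``parent_id``; fragments shorter
    than the minimum domain length survive, flagged ``split_by_mask``.
    Domains fully covered by masks are dropped; their ids are returned as the
    second element.
    """
    combined: dict[str, list] = {}
    for mask in masks:
        for chrom, iv in mask.per_chrom().items():
            combined.setdefault(chrom, []).append(iv)
    merged = {
        chrom: merge_intervals(np.concatenate(ivs))
        for chrom, ivs in combined.items()
    }
    out: list[Domain] = []
    dropped: list[str] = []
    for d in domains:
        mask_iv = merged.get(d.chrom)
        if mask_iv is None:
            out.append(replace(d, parent_id=d.id))
            continue
        from .genomic_io import subtract_intervals

        pieces = subtract_intervals(d.start, d.end, mask_iv)
        if not pieces:
            dropped.append(d.id)
            continue
        if len(pieces) == 1 and pieces[0] == (d.start, d.end):
            out.append(replace(d, parent_id=d.id))
            continue
        for k, (s, e) in enumerate(pieces, 1):
            out.append(
                replace(
                    d,
                    id=f"{d.id}.{k}",
                    parent_id=d.id,
                    start=s,
                    end=e,
                    split_by_mask=True,
                )
            )
    return DomainSet(out), dropped


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def _positions_in(pos: np.ndarray, merged: np.ndarray) -> np.ndarray:
    """Boolean membership of positions in merged disjoint intervals."""
    if len(merged) == 0 or len(pos) == 0:
        return np.zeros(len(pos), dtype=bool)
    idx = np.searchsorted(merged[:, 0], pos, side="right") - 1
    ok = idx >= 0
    member = np.zeros(len(pos), dtype=bool)
    member[ok] = pos[ok] < merged[idx[ok], 1]
    return member


def domain_stats(
    domains: DomainSet,
    methylome: MethylomeTable,
    genome_seq: dict[str, str] | None = None,
    min_reads: int = 5,
    hyper_cut: float = 75.0,
    hypo_cut: float = 25.0,
) -> tuple[pd.DataFrame, dict]:
    """Per-domain statistics and a genome-wide summary.

    Per domain: length, mean methylation and the fraction of member CpGs
    methylated/unmethylated (CpGs at ``min_reads`` coverage or more), CpG
    density (CpGs per 100 bp) and GC content when sequence is available.
    Domains without any adequately covered CpG are flagged missing.
    """
    rows = []
    for d in domains:
        pos, nm, nu = methylome.arrays(d.chrom)
        lo, hi = np.searchsorted(pos, [d.start, d.end])
        p, m, u = pos[lo:hi], nm[lo:hi], nu[lo:hi]
        cov = m + u
        ok = cov >= min_reads
        row = {
            "id": d.id,
            "parent_id": d.parent_id,
            "class": d.cls,
            "chrom": d.chrom,
            "start": d.start,
            "end": d.end,
            "length": d.length,
            "n_cpgs": int(len(p)),
            "n_scored_cpgs": int(ok.sum()),
            "mean_meth": np.nan,
            "frac_meth_cpgs": np.nan,
            "frac_unmeth_cpgs": np.nan,
            "cpg_density": np.nan,
            "gc_content": np.nan,
            "missing": not bool(ok.any()),
        }
        if ok.any():
            pct = 100.0 * m[ok] / cov[ok]
            row["mean_meth"] = float(pct.mean())
            row["frac_meth_cpgs"] = float((pct >= hyper_cut).mean())
            row["frac_unmeth_cpgs"] = float((pct <= hypo_cut).mean())
        if genome_seq is not None and d.chrom in genome_seq:
            seq = genome_seq[d.chrom][d.start : d.end]
            if seq:
                row["cpg_density"] = 100.0 * seq.count("CG") / len(seq)
                gc = seq.count("G") + seq.count("C")
                row["gc_content"] = 100.0 * gc / len(seq)
        rows.append(row)
    frame = pd.DataFrame(rows)
    summary: dict = {"n_domains": len(frame)}
    for cls in (HYPER, HYPO):
        sub = frame[frame["class"] == cls] if len(frame) else frame
        summary[cls] = {
            "count": int(len(sub)),
            "mean_length": float(sub["length"].mean()) if len(sub) else 0.0,
            "median_length": float(sub["length"].median()) if len(sub) else 0.0,
            "mean_meth": float(sub["mean_meth"].mean()) if len(sub) else float("nan"),
        }
    return frame, summary


def cpg_category_partition(
    methylome: MethylomeTable,
    domains: DomainSet,
    tss_cgi_mask: FeatureTrack | None = None,
    premeth_mask: FeatureTrack | None = None,
    intermediate: tuple[float, float] = (25.0, 75.0),
    min_reads: int = 5,
) -> dict[str, float]:
    """Assign every genomic CpG to exactly one category.

    Categories, in precedence order: ``hyper`` / ``hypo`` (CpG inside a called
    domain), ``tss_cgi`` (inside the promoter/CGI exclusion mask),
    ``intermediate`` (methylation within the given band at adequate coverage),
    ``control_meth`` (inside the pre-methylated control mask), ``other``.
    Fractions are over all CpGs in the methylome and sum to one.
    """
    hyper_iv = domains.merged_per_chrom(HYPER)
    hypo_iv = domains.merged_per_chrom(HYPO)
    tss_iv = tss_cgi_mask.merged_per_chrom() if tss_cgi_mask is not None else {}
    pre_iv = premeth_mask.merged_per_chrom() if premeth_mask is not None else {}
    counts = {
        "hyper": 0, "hypo": 0, "tss_cgi": 0,
        "intermediate": 0, "control_meth": 0, "other": 0,
    }
    total = 0
    empty = np.empty((0, 2), dtype=np.int64)
    for chrom in methylome.chroms():
        pos, nm, nu = methylome.arrays(chrom)
        total += len(pos)
        unassigned = np.ones(len(pos), dtype=bool)
        cov = nm + nu
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(cov > 0, 100.0 * nm / np.maximum(cov, 1), np.nan)
        is_inter = (
            (cov >= min_reads)
            & (pct >= intermediate[0])
            & (pct <= intermediate[1])
        )
        for key, member in (
            ("hyper", _positions_in(pos, hyper_iv.get(chrom, empty))),
            ("hypo", _positions_in(pos, hypo_iv.get(chrom, empty))),
            ("tss_cgi", _positions_in(pos, tss_iv.get(chrom, empty))),
            ("intermediate", is_inter),
            ("control_meth", _positions_in(pos, pre_iv.get(chrom, empty))),
        ):
            take = unassigned & member
            counts[key] += int(take.sum())
            unassigned &= ~take
        counts["other"] += int(unassigned.sum())
    if total == 0:
        return {k: 0.0 for k in counts}
    return {k: v / total for k, v in counts.items()}
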