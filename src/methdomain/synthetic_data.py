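"""Synthetic methylomes, annotations and read coverage with planted truth.

The generator emulates the statistical structure the analysis assumes: a
genome of CpG positions whose methylation is organised in large bimodal
domains (high around 90 %, low around 10 %), beta-binomial count noise at
sampled read depth, partially/pre-methylated control methylomes, exon
structured gene models with known TSSs, CGI and TE tracks, and stranded read
coverage proportional to expression.  Every generated dataset carries a
:class:`TruthSet` so recovery of domains, novel genes and upstream TSSs can
be measured exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genomic_io import (
    AnnotationSet,
    FeatureTrack,
    MethylomeTable,
    TranscriptModel,
    merge_intervals,
)

DEFAULT_GENOME = {"chr1": 10_000_000, "chr2": 10_000_000}


@dataclass
class MethylomeSpec:
    """Parameters of a simulated methylome."""

    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GENOME)
    )
    cpg_rate: float = 0.01            # CpGs per bp
    positions: Mapping[str, np.ndarray] | None = None
    domain_plan: list[tuple[str, int, int, float]] | None = None
    coverage_mean: float = 15.0       # Poisson mean; 0 = no reads
    fixed_coverage: int | None = None
    beta_concentration: float = 50.0  # per-CpG noise around the domain target
    background_meth: float = 10.0
    seed: int = 0


@dataclass
class AnnotationSpec:
    """Parameters of a simulated annotation with planted features."""

    n_ref_genes: int = 24
    ref_len_range: tuple[int, int] = (20_000, 60_000)
    exon_range: tuple[int, int] = (3, 8)
    exon_len_range: tuple[int, int] = (200, 1500)
    expression_lognorm: tuple[float, float] = (1.0, 1.5)  # (mean, sigma) of log FPKM
    n_novel_multi: int = 8
    n_novel_mono: int = 8
    n_confounder_near_ref: int = 4
    n_confounder_noncode: int = 2
    n_confounder_repeat: int = 3
    n_upstream_tss: int = 6
    upstream_distance_range: tuple[int, int] = (5_000, 20_000)
    novel_gene_margin_slack: float = 2.0  # placement margin as multiple of rule
    cgi_at_promoter_p: float = 0.7
    n_background_te: int = 60
    seed: int = 0


@dataclass
class TruthSet:
    """Planted features emitted alongside simulated data."""

    domains: list[tuple[str, int, int, str]] = field(default_factory=list)
    novel_genes: set[str] = field(default_factory=set)
    excluded_novel_genes: set[str] = field(default_factory=set)
    upstream_tss: dict[str, int] = field(default_factory=dict)  # gene -> distance
    escapees: set[str] = field(default_factory=set)
    coupling: float | None = None
    transcribed_hyper: int = 0
    untranscribed_hyper: int = 0


# ---------------------------------------------------------------------------
# Domain plans
# ---------------------------------------------------------------------------

def random_domain_plan(
    chrom_lengths: Mapping[str, int],
    rng: np.random.Generator,
    min_len: int = 10_000,
    mean_extra: float = 40_000.0,
    hyper_meth: float = 90.0,
    hypo_meth: float = 10.0,
) -> list[tuple[str, int, int, float]]:
    """Alternating hyper/hypo blocks tiling each chromosome.

    Block lengths are ``min_len`` plus an exponential tail, giving domains
    of at least ``min_len`` with a realistic long-tailed size distribution.
    """
    plan = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        pos = 0
        cls = rng.integers(0, 2)
        while pos < length:
            size = int(min_len + rng.exponential(mean_extra))
            end = min(pos + size, length)
            target = hyper_meth if cls else hypo_meth
            plan.append((chrom, pos, end, target))
            pos = end
            cls = 1 - cls
    return plan


def coupled_domain_plan(
    genes: Sequence[tuple[str, int, int]],
    chrom_lengths: Mapping[str, int],
    coupling: float,
    rng: np.random.Generator,
    hyper_meth: float = 90.0,
    hypo_meth: float = 10.0,
    extra_len_range: tuple[int, int] | None = None,
) -> tuple[list[tuple[str, int, int, float]], dict]:
    """Derive hypermethylation from transcription with a coupling rate.

    Each gene span becomes a hypermethylated block with probability
    ``coupling``; additional hypermethylated blocks are placed in intergenic
    space so that the planted fraction of hyper blocks that are transcribed
    equals the coupling rate.  Everything else is hypomethylated.  Extra
    block lengths are resampled from the gene-span length distribution (so
    the coupling rate holds for base pairs as well as block counts) unless an
    explicit ``extra_len_range`` is given.
    """
    if not 0.0 <= coupling <= 1.0:
        raise ValueError("coupling must be a probability")
    hyper: dict[str, list[list[int]]] = {}
    n_transcribed = 0
    for chrom, start, end in genes:
        if rng.random() < coupling:
            hyper.setdefault(chrom, []).append([start, end])
            n_transcribed += 1
    n_extra = (
        int(round(n_transcribed * (1.0 - coupling) / coupling))
        if coupling > 0
        else len(genes)
    )
    gene_iv = {}
    for chrom, start, end in genes:
        gene_iv.setdefault(chrom, []).append([start - 5000, end + 5000])
    chroms = sorted(chrom_lengths)
    gene_lengths = [end - start for _, start, end in genes] or [20_000]
    placed = 0
    tries = 0
    while placed < n_extra and tries < 10_000:
        tries += 1
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        if extra_len_range is None:
            size = int(gene_lengths[int(rng.integers(0, len(gene_lengths)))])
        else:
            size = int(rng.integers(*extra_len_range))
        start = int(rng.integers(0, max(1, chrom_lengths[chrom] - size)))
        end = start + size
        blocked = gene_iv.get(chrom, []) + hyper.get(chrom, [])
        if any(start < e + 5000 and s - 5000 < end for s, e in blocked):
            continue
        hyper.setdefault(chrom, []).append([start, end])
        placed += 1
    plan = []
    for chrom in chroms:
        length = chrom_lengths[chrom]
        iv = hyper.get(chrom, [])
        merged = (
            merge_intervals(np.array(iv, dtype=np.int64))
            if iv
            else np.empty((0, 2), dtype=np.int64)
        )
        cur = 0
        for s, e in merged:
            s, e = int(s), int(min(e, length))
            if s > cur:
                plan.append((chrom, cur, s, hypo_meth))
            plan.append((chrom, s, e, hyper_meth))
            cur = e
        if cur < length:
            plan.append((chrom, cur, length, hypo_meth))
    info = {
        "transcribed_hyper": n_transcribed,
        "untranscribed_hyper": placed,
    }
    return plan, info


# ---------------------------------------------------------------------------
# Methylome simulation
# ---------------------------------------------------------------------------

def simulate_methylome(spec: MethylomeSpec) -> tuple[MethylomeTable, TruthSet]:
    """Simulate a methylome with domain-structured beta-binomial counts.

    CpG positions are a Poisson process at ``cpg_rate`` (or explicit
    positions); per CpG the underlying methylation probability is drawn from
    a beta distribution concentrated around the planted domain target, read
    depth from a Poisson (or fixed) model, and methylated counts binomially.
    Deterministic under ``spec.seed``.
    """
    if spec.cpg_rate <= 0 and spec.positions is None:
        raise ValueError("CpG rate must be positive")
    rng = np.random.default_rng(spec.seed)
    plan = spec.domain_plan
    if plan is None:
        plan = random_domain_plan(spec.chrom_lengths, rng)
    truth = TruthSet(
        domains=[
            (c, s, e, "hyper" if t >= 50 else "hypo") for c, s, e, t in plan
        ]
    )
    plan_by_chrom: dict[str, list[tuple[int, int, float]]] = {}
    for c, s, e, t in plan:
        plan_by_chrom.setdefault(c, []).append((s, e, t))
    frames = []
    for chrom in sorted(spec.chrom_lengths):
        length = spec.chrom_lengths[chrom]
        if spec.positions is not None:
            pos = np.asarray(spec.positions.get(chrom, ()), dtype=np.int64)
        else:
            n_expect = int(length * spec.cpg_rate * 1.2) + 10
            gaps = rng.geometric(spec.cpg_rate, size=n_expect)
            pos = np.cumsum(gaps) - 1
            pos = pos[pos < length]
        if len(pos) == 0:
            continue
        targets = np.full(len(pos), spec.background_meth / 100.0)
        for s, e, t in plan_by_chrom.get(chrom, ()):
            lo, hi = np.searchsorted(pos, [s, e])
            targets[lo:hi] = t / 100.0
        t_clip = np.clip(targets, 1e-3, 1 - 1e-3)
        conc = spec.beta_concentration
        p = rng.beta(conc * t_clip, conc * (1 - t_clip))
        if spec.fixed_coverage is not None:
            cov = np.full(len(pos), spec.fixed_coverage, dtype=np.int64)
        else:
            cov = rng.poisson(spec.coverage_mean, size=len(pos))
        n_meth = rng.binomial(cov, p)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "n_meth": n_meth,
                    "n_unmeth": cov - n_meth,
                }
            )
        )
    if not frames:
        return MethylomeTable("sim"), truth
    table = MethylomeTable.from_frame(pd.concat(frames, ignore_index=True), "sim")
    return table, truth


def simulate_control_methylome(
    base: MethylomeSpec,
    premethylated: Sequence[tuple[str, int, int]] = (),
    control_meth: float = 80.0,
    background: float = 5.0,
    seed_offset: int = 1,
) -> MethylomeTable:
    """A control methylome (pre-methylation stage or de novo deficient).

    Mostly unmethylated, except in the given already-methylated regions —
    the regions the exclusion mask is expected to recover.
    """
    plan = [(c, s, e, control_meth) for c, s, e in premethylated]
    spec = MethylomeSpec(
        chrom_lengths=base.chrom_lengths,
        cpg_rate=base.cpg_rate,
        positions=base.positions,
        domain_plan=plan,
        coverage_mean=base.coverage_mean,
        fixed_coverage=base.fixed_coverage,
        beta_concentration=base.beta_concentration,
        background_meth=background,
        seed=base.seed + seed_offset,
    )
    table, _ = simulate_methylome(spec)
    table.label = "control"
    return table


# ---------------------------------------------------------------------------
# Annotation simulation
# ---------------------------------------------------------------------------

def _make_exons(
    rng: np.random.Generator, start: int, length: int, n_exons: int,
    exon_len_range: tuple[int, int],
) -> list[tuple[int, int]]:
    """Exon chain spanning [start, start+length)."""
    if n_exons == 1:
        return [(start, start + length)]
    lens = rng.integers(*exon_len_range, size=n_exons)
    total_exon = int(lens.sum())
    n_introns = n_exons - 1
    intron_total = max(length - total_exon, n_introns * 100)
    cuts = np.sort(rng.integers(0, intron_total + 1, size=n_introns - 1)) if n_introns > 1 else np.array([], dtype=int)
    intron_lens = np.diff(np.concatenate(([0], cuts, [intron_total]))) + 100
    exons = []
    pos = start
    for i in range(n_exons):
        exons.append((pos, pos + int(lens[i])))
        pos += int(lens[i])
        if i < n_introns:
            pos += int(intron_lens[i])
    return exons


def simulate_annotation(
    spec: AnnotationSpec,
    genome: Mapping[str, int] | None = None,
) -> dict:
    """Simulate reference and oocyte annotations with planted features.

    Returns a dict with ``reference`` and ``oocyte`` :class:`AnnotationSet`
    objects, ``cgi``/``te``/``noncode`` feature tracks, and a ``truth``
    :class:`TruthSet` recording planted novel genes (clean and confounded)
    and planted upstream TSSs.  Confounders deliberately violate one curation
    rule each, so precision of the calling rules is measurable.
    """
    genome = dict(genome or DEFAULT_GENOME)
    rng = np.random.default_rng(spec.seed)
    truth = TruthSet()
    slots: list[tuple[str, int]] = []
    # deterministic gene slots: evenly spaced anchors, spaced so features in
    # neighbouring slots always clear the curation-rule margins with slack
    spacing = spec.ref_len_range[1] + 20_000
    for chrom in sorted(genome):
        for anchor in range(100_000, genome[chrom] - spacing - 100_000, spacing):
            slots.append((chrom, anchor))
    rng.shuffle(slots)
    needed = (
        spec.n_ref_genes + spec.n_novel_multi + spec.n_novel_mono
        + spec.n_confounder_noncode + spec.n_confounder_repeat + 2
    )
    if len(slots) < needed:
        raise ValueError("genome too small for the requested feature density")

    ref_transcripts: list[TranscriptModel] = []
    oo_transcripts: list[TranscriptModel] = []
    cgi_rows, te_rows, nc_rows = [], [], []

    def fpkm() -> float:
        mu, sigma = spec.expression_lognorm
        return float(np.exp(rng.normal(mu, sigma)))

    # --- reference genes, mirrored into the oocyte assembly -----------------
    ref_ids = []
    for i in range(spec.n_ref_genes):
        chrom, anchor = slots.pop()
        length = int(rng.integers(*spec.ref_len_range))
        n_exons = int(rng.integers(*spec.exon_range))
        strand = "+" if rng.random() < 0.5 else "-"
        exons = _make_exons(rng, anchor, length, n_exons, spec.exon_len_range)
        gid = f"ref_g{i:03d}"
        ref_ids.append(gid)
        t_ref = TranscriptModel(
            id=f"ref_t{i:03d}", gene_id=gid, chrom=chrom, strand=strand,
            exons=exons, fpkm={"default": fpkm()},
        )
        ref_transcripts.append(t_ref)
        oo_transcripts.append(
            TranscriptModel(
                id=f"oo_ref_t{i:03d}", gene_id=f"oo_{gid}", chrom=chrom,
                strand=strand, exons=list(exons),
                fpkm={"default": t_ref.fpkm["default"]},
            )
        )
        if rng.random() < spec.cgi_at_promoter_p:
            tss = t_ref.tss
            cgi_rows.append((chrom, max(0, tss - 500), tss + 500, ".", f"cgi_{gid}"))

    # --- planted upstream TSSs on a subset of reference genes ---------------
    upstream_candidates = [
        t for t in ref_transcripts if len(t.exons) >= 3
    ]
    rng.shuffle(upstream_candidates)
    for k, t_ref in enumerate(upstream_candidates[: spec.n_upstream_tss]):
        dist = int(rng.integers(*spec.upstream_distance_range))
        exon_len = 500
        if t_ref.strand == "+":
            new_start = t_ref.tss - dist
            if new_start - exon_len < 0:
                continue
            novel_exon = (new_start, new_start + exon_len)
            exons = [novel_exon] + t_ref.exons[1:]
        else:
            new_start = t_ref.tss + dist
            novel_exon = (new_start - exon_len + 1, new_start + 1)
            exons = t_ref.exons[:-1] + [novel_exon]
        oo_transcripts.append(
            TranscriptModel(
                id=f"oo_up_t{k:03d}", gene_id=f"oo_{t_ref.gene_id}",
                chrom=t_ref.chrom, strand=t_ref.strand, exons=exons,
                fpkm={"default": fpkm()},
            )
        )
        truth.upstream_tss[t_ref.gene_id] = dist

    # one upstream confounder: starts upstream but inside the first exon's
    # extension, violating the separate-exon rule
    if upstream_candidates[spec.n_upstream_tss :]:
        t_ref = upstream_candidates[spec.n_upstream_tss]
        if t_ref.strand == "+":
            s0, e0 = t_ref.exons[0]
            exons = [(s0 - 300, e0)] + t_ref.exons[1:]
        else:
            s0, e0 = t_ref.exons[-1]
            exons = t_ref.exons[:-1] + [(s0, e0 + 300)]
        oo_transcripts.append(
            TranscriptModel(
                id="oo_up_confounder", gene_id=f"oo_{t_ref.gene_id}",
                chrom=t_ref.chrom, strand=t_ref.strand, exons=exons,
                fpkm={"default": fpkm()},
            )
        )

    # --- clean novel genes ---------------------------------------------------
    def plant_novel(idx: int, mono: bool) -> str:
        chrom, anchor = slots.pop()
        gid = f"novel_{'mono' if mono else 'multi'}_{idx:03d}"
        strand = "+" if rng.random() < 0.5 else "-"
        if mono:
            exons = [(anchor, anchor + int(rng.integers(500, 3000)))]
        else:
            exons = _make_exons(
                rng, anchor, int(rng.integers(5000, 15000)),
                int(rng.integers(2, 5)), spec.exon_len_range,
            )
        oo_transcripts.append(
            TranscriptModel(
                id=f"t_{gid}", gene_id=gid, chrom=chrom, strand=strand,
                exons=exons, fpkm={"default": fpkm()},
            )
        )
        return gid

    for i in range(spec.n_novel_multi):
        truth.novel_genes.add(plant_novel(i, mono=False))
    for i in range(spec.n_novel_mono):
        truth.novel_genes.add(plant_novel(i, mono=True))

    # --- confounders: near-reference, near-noncode, repeat-covered ----------
    for i in range(spec.n_confounder_near_ref):
        t_ref = ref_transcripts[int(rng.integers(0, len(ref_transcripts)))]
        mono = bool(rng.integers(0, 2))
        margin = 5000 if mono else 1000
        gap = int(margin * 0.4)
        gid = f"conf_ref_{i:03d}"
        start = t_ref.end + gap
        exons = (
            [(start, start + 800)]
            if mono
            else [(start, start + 400), (start + 1200, start + 1600)]
        )
        oo_transcripts.append(
            TranscriptModel(
                id=f"t_{gid}", gene_id=gid, chrom=t_ref.chrom,
                strand=t_ref.strand, exons=exons, fpkm={"default": fpkm()},
            )
        )
        truth.excluded_novel_genes.add(gid)
    for i in range(spec.n_confounder_noncode):
        chrom, anchor = slots.pop()
        strand = "+" if rng.random() < 0.5 else "-"
        nc_rows.append((chrom, anchor, anchor + 2000, strand, f"nc_{i:03d}"))
        gid = f"conf_nc_{i:03d}"
        start = anchor + 2000 + 1500  # inside the 5-kbp mono margin
        oo_transcripts.append(
            TranscriptModel(
                id=f"t_{gid}", gene_id=gid, chrom=chrom, strand=strand,
                exons=[(start, start + 900)], fpkm={"default": fpkm()},
            )
        )
        truth.excluded_novel_genes.add(gid)
    families = ("MaLR", "ERVK", "L1", "ERVL", "S2")
    for i in range(spec.n_confounder_repeat):
        chrom, anchor = slots.pop()
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"conf_rep_{i:03d}"
        g_len = int(rng.integers(600, 2000))
        oo_transcripts.append(
            TranscriptModel(
                id=f"t_{gid}", gene_id=gid, chrom=chrom, strand=strand,
                exons=[(anchor, anchor + g_len)], fpkm={"default": fpkm()},
            )
        )
        fam = families[int(rng.integers(0, 2))]  # MaLR or ERVK
        te_rows.append((chrom, anchor - 50, anchor + g_len + 50, strand, fam))
        truth.excluded_novel_genes.add(gid)

    # --- background TE landscape, confined to unused slots so elements never
    # interfere with planted genes ------------------------------------------
    for i in range(spec.n_background_te):
        if not slots:
            break
        chrom, anchor = slots.pop()
        fam = families[int(rng.integers(0, len(families)))]
        size = int(rng.integers(300, 6000))
        strand = "+" if rng.random() < 0.5 else "-"
        te_rows.append((chrom, anchor, anchor + size, strand, fam))

    reference = AnnotationSet(ref_transcripts)
    oocyte = AnnotationSet(oo_transcripts)
    tracks = {
        "cgi": FeatureTrack(
            "CGI",
            pd.DataFrame(cgi_rows, columns=FeatureTrack.COLUMNS),
        ),
        "te": FeatureTrack(
            "TE",
            pd.DataFrame(te_rows, columns=FeatureTrack.COLUMNS),
        ),
        "noncode": FeatureTrack(
            "noncode",
            pd.DataFrame(nc_rows, columns=FeatureTrack.COLUMNS),
        ),
    }
    return {
        "reference": reference,
        "oocyte": oocyte,
        "tracks": tracks,
        "truth": truth,
    }


# ---------------------------------------------------------------------------
# Read coverage
# ---------------------------------------------------------------------------

def simulate_read_coverage(
    annotation: AnnotationSet,
    depth: int,
    seed: int,
    datasets: Sequence[str] = ("ds1",),
    stage: str = "default",
    read_len: int = 100,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample stranded read intervals along exonic spans, FPKM-proportional.

    Per dataset, each gene receives a Poisson number of reads with mean
    ``FPKM x exonic_kb x depth / 1e6``; read intervals are uniform within the
    gene's exons (clipped at exon ends).  Returns the read-interval table
    (``chrom start end strand dataset``) and a per-gene FPKM table recomputed
    from the sampled counts.
    """
    rng = np.random.default_rng(seed)
    rows = []
    fpkm_rows = []
    genes = annotation.gene_list()
    for dataset in datasets:
        counts = {}
        for g in genes:
            exonic = merge_intervals(
                np.array(
                    sorted({(s, e) for t in g.transcripts for s, e in t.exons}),
                    dtype=np.int64,
                )
            )
            exlen = int((exonic[:, 1] - exonic[:, 0]).sum())
            lam = g.fpkm(stage) * (exlen / 1e3) * (depth / 1e6)
            n = int(rng.poisson(lam)) if lam > 0 else 0
            counts[g.id] = (n, exlen)
            if n == 0:
                continue
            gap_lens = exonic[:, 1] - exonic[:, 0]
            cum = np.concatenate(([0], np.cumsum(gap_lens)))
            offs = rng.integers(0, cum[-1], size=n)
            gi = np.searchsorted(cum, offs, side="right") - 1
            starts = exonic[gi, 0] + (offs - cum[gi])
            ends = np.minimum(starts + read_len, exonic[gi, 1])
            for s, e in zip(starts, ends):
                if e > s:
                    rows.append((g.chrom, int(s), int(e), g.strand, dataset))
        # FPKM is per million mapped reads of the library; ``depth`` plays the
        # role of the dataset's mapped-read total
        for gid, (n, exlen) in counts.items():
            recomputed = n * 1e9 / (exlen * depth) if depth and exlen else 0.0
            fpkm_rows.append(
                {"gene_id": gid, "dataset": dataset, "n_reads": n,
                 "exonic_length": exlen, "fpkm": recomputed}
            )
    reads = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "strand", "dataset"]
    )
    return reads, pd.DataFrame(fpkm_rows)
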