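"""End-to-end orchestration: simulate -> call -> mask -> explain -> cgi.

A single :class:`PipelineConfig` drives every stage in dependency order and
writes a deterministic report bundle (TSV tables, a JSON summary with every
headline statistic, and a plain-text log).  Reruns with an identical config
are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import cgi_analysis as cgi
from . import domain_caller as dc
from . import synthetic_data as sim
from . import transcription_overlap as tx
from .genomic_io import (
    AnnotationSet,
    FeatureTrack,
    MethylomeTable,
    read_cpg_table,
    read_feature_bed,
    read_gtf,
    write_cpg_table,
    write_domains,
    write_feature_bed,
    write_gtf,
)

logger = logging.getLogger("methdomain")


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 0
    preset: str = "paper_50_10"
    simulate: bool = True
    # input paths, required when simulate is off
    meth_path: str | None = None
    control_paths: Sequence[str] = field(default_factory=list)
    oocyte_gtf: str | None = None
    reference_gtf: str | None = None
    cgi_bed: str | None = None
    reads_tsv: str | None = None
    # simulation sizes
    genome: dict[str, int] = field(
        default_factory=lambda: {"chr1": 2_000_000, "chr2": 2_000_000}
    )
    coupling: float = 0.9
    read_depth: int = 300_000
    # analysis thresholds
    low_fpkm: float = 0.5
    segmentation_overrides: dict = field(default_factory=dict)

    def params(self) -> dc.SegmentationParams:
        base = dc.SegmentationParams.preset(self.preset)
        if self.segmentation_overrides:
            from dataclasses import replace

            base = replace(base, **self.segmentation_overrides)
        return base

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if not self.simulate:
            for name in ("meth_path", "oocyte_gtf"):
                value = getattr(self, name)
                if value is None:
                    raise ConfigError(f"{name} is required when simulate=false")
                if not Path(value).exists():
                    raise ConfigError(f"{name}: no such file {value}")
            for p in self.control_paths:
                if not Path(p).exists():
                    raise ConfigError(f"control methylome missing: {p}")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle under ``config.out_dir``.

    Returns the JSON summary as a dict.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run(config, out)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, out: Path) -> dict:
    params = config.params()
    summary: dict = {"seed": config.seed, "preset": config.preset}

    # ---- stage 0: inputs ---------------------------------------------------
    if config.simulate:
        anno_spec = sim.AnnotationSpec(
            seed=config.seed,
            n_ref_genes=10, n_novel_multi=4, n_novel_mono=4,
            n_confounder_near_ref=2, n_confounder_noncode=1,
            n_confounder_repeat=2, n_upstream_tss=3, n_background_te=8,
        )
        world = sim.simulate_annotation(anno_spec, config.genome)
        oocyte, reference = world["oocyte"], world["reference"]
        tracks, truth = world["tracks"], world["truth"]
        gene_spans = [
            (g.chrom, g.start, g.end) for g in oocyte.gene_list()
        ]
        rng = np.random.default_rng(config.seed + 1)
        plan, coupling_info = sim.coupled_domain_plan(
            gene_spans, config.genome, config.coupling, rng
        )
        mspec = sim.MethylomeSpec(
            chrom_lengths=config.genome, domain_plan=plan, seed=config.seed + 2
        )
        methylome, _ = sim.simulate_methylome(mspec)
        control = sim.simulate_control_methylome(mspec)
        controls = [control]
        reads, fpkm_table = sim.simulate_read_coverage(
            oocyte, config.read_depth, config.seed + 3, datasets=("ds1", "ds2")
        )
        cgi_track = tracks["cgi"]
        write_cpg_table(methylome, out / "fgo.cov")
        write_cpg_table(control, out / "control.cov")
        write_gtf(oocyte, out / "oocyte.gtf")
        write_gtf(reference, out / "reference.gtf")
        write_feature_bed(cgi_track, out / "cgi.bed")
        reads.to_csv(out / "reads.tsv", sep="\t", index=False)
        summary["simulation"] = {
            "n_genes": len(oocyte),
            "coupling": config.coupling,
            **coupling_info,
        }
        logger.info("simulated %d genes, %d CpGs", len(oocyte), len(methylome))
    else:
        methylome = read_cpg_table(config.meth_path)
        controls = [read_cpg_table(p) for p in config.control_paths]
        oocyte = read_gtf(config.oocyte_gtf)
        reference = read_gtf(config.reference_gtf) if config.reference_gtf else oocyte
        cgi_track = (
            read_feature_bed(config.cgi_bed, "CGI")
            if config.cgi_bed
            else FeatureTrack("CGI")
        )
        reads = None
        if config.reads_tsv:
            reads = pd.read_csv(config.reads_tsv, sep="\t")

    # ---- stage 1: domain calling ------------------------------------------
    windows = dc.make_windows(methylome, params)
    logger.info("windows: %d", len(windows))
    raw = dc.raw_domains(windows, params)
    logger.info("raw domains: %d", len(raw))
    refined = dc.refine_domains(raw, params)
    logger.info("refined domains: %d", len(refined))
    tss_track = dc.tss_mask(oocyte)
    masks = [tss_track, cgi_track.normalized()]
    if controls:
        masks.append(dc.premethylated_mask(controls))
    masked, dropped = dc.apply_masks(refined, masks)
    logger.info("masked domains: %d (%d dropped)", len(masked), len(dropped))
    stats_frame, dom_summary = dc.domain_stats(masked, methylome)
    write_domains(masked, out / "domains.bed", stats_frame)
    summary["domains"] = dom_summary
    summary["domains"]["n_dropped_by_mask"] = len(dropped)
    tss_cgi = FeatureTrack(
        "mask", pd.concat([tss_track.df, cgi_track.df], ignore_index=True)
    ).normalized()
    partition = dc.cpg_category_partition(
        methylome, masked, tss_cgi,
        dc.premethylated_mask(controls) if controls else None,
    )
    summary["cpg_partition"] = partition

    # ---- stage 2: transcription overlap ------------------------------------
    contigs = tx.build_contigs(reads) if reads is not None and len(reads) else None
    hyper_expl, hyper_summary = tx.explain_hyperds(
        masked, reference, oocyte, contigs
    )
    alt_windows = tx.alt_tss_windows(oocyte)
    hypo_expl, hypo_summary = tx.explain_hypods(
        masked, oocyte, alt_tss_track=alt_windows, low_fpkm=config.low_fpkm
    )
    summary["hyperd_tiers"] = hyper_summary
    summary["hypod_tiers"] = hypo_summary
    escapees = tx.detect_escapees(oocyte.gene_list(), methylome)
    summary["escapees"] = {
        "n_candidates": len(escapees),
        "n_confirmed": sum(e.confirmed for e in escapees),
    }

    # ---- stage 3: CGIs ------------------------------------------------------
    cgi_records = cgi.classify_cgi_location(cgi_track, oocyte)
    cgi_records = cgi.cgi_meth_status(cgi_records, methylome)
    cgi_records, cgi_summary = cgi.cgi_transcription_context(
        cgi_records, oocyte, contigs
    )
    class_counts = {c: 0 for c in cgi.LOCATION_CLASSES}
    status_counts: dict[str, int] = {}
    for rec in cgi_records:
        class_counts[rec.location_class] += 1
        status_counts[rec.meth_status] = status_counts.get(rec.meth_status, 0) + 1
    summary["cgi"] = {
        "location_counts": class_counts,
        "meth_status_counts": status_counts,
        "context": cgi_summary,
    }
    cgi.cgi_records_frame(cgi_records).to_csv(
        out / "cgi_report.tsv", sep="\t", index=False
    )

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    logger.info("summary written")
    return summary
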