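"""Contigs, overlap fractions, explanation cascades, escapees, enrichment."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from methdomain import domain_caller as dc
from methdomain import transcription_overlap as tx
from methdomain import genomic_io as gio
from conftest import make_methylome, uniform_methylome
from _naive import naive_overlap_fraction


def reads_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "dataset"])


def _dom(cls, start, end, chrom="chr1", did=None):
    did = did or f"{cls}_{start}"
    return dc.Domain(did, did, cls, chrom, start, end)


class TestBuildContigs:
    def test_two_stacked_reads_make_no_contig(self):
        reads = reads_frame([("chr1", 100, 200, "+", "a")] * 2)
        assert len(tx.build_contigs(reads)) == 0

    def test_three_overlapping_reads_contig_is_depth3_run(self):
        reads = reads_frame(
            [
                ("chr1", 100, 200, "+", "a"),
                ("chr1", 150, 250, "+", "a"),
                ("chr1", 180, 300, "+", "a"),
            ]
        )
        track = tx.build_contigs(reads)
        assert [(r.start, r.end) for r in track.plus.df.itertuples()] == [(180, 200)]

    def test_strands_do_not_pool(self):
        reads = reads_frame(
            [
                ("chr1", 100, 200, "+", "a"),
                ("chr1", 100, 200, "+", "a"),
                ("chr1", 100, 200, "-", "a"),
            ]
        )
        assert len(tx.build_contigs(reads)) == 0

    def test_single_dataset_depth_enters_union(self):
        rows = [("chr1", 100, 200, "+", "a")] * 3
        rows += [("chr1", 100, 200, "+", "b")]  # depth 1 in b
        track = tx.build_contigs(reads_frame(rows))
        assert [(r.start, r.end) for r in track.plus.df.itertuples()] == [(100, 200)]

    def test_datasets_do_not_pool_depth(self):
        rows = [
            ("chr1", 100, 200, "+", "a"),
            ("chr1", 100, 200, "+", "b"),
            ("chr1", 100, 200, "+", "c"),
        ]
        assert len(tx.build_contigs(reads_frame(rows))) == 0


class TestOverlapFraction:
    def test_examples(self):
        d = _dom("hyper", 0, 1000)
        cover = {"chr1": gio.merge_intervals(np.array([[0, 400], [300, 700]]))}
        assert tx.overlap_fraction(d, cover) == pytest.approx(0.7)
        assert tx.overlap_fraction(d, {}) == 0.0
        full = {"chr1": np.array([[0, 2000]])}
        assert tx.overlap_fraction(d, full) == 1.0

    def test_matches_per_base_count(self, rng):
        for _ in range(30):
            n = int(rng.integers(1, 8))
            iv = np.sort(rng.integers(0, 5000, size=(n, 2)), axis=1)
            iv = iv[iv[:, 0] < iv[:, 1]]
            if not len(iv):
                continue
            start = int(rng.integers(0, 2500))
            end = start + int(rng.integers(100, 2500))
            d = _dom("hyper", start, end)
            got = tx.overlap_fraction(d, {"chr1": gio.merge_intervals(iv)})
            want = naive_overlap_fraction(start, end, [tuple(x) for x in iv])
            assert got == pytest.approx(want)


def _gtf_anno(transcripts):
    return gio.AnnotationSet(transcripts)


def _tmodel(tid, gid, exons, strand="+", fpkm=5.0, chrom="chr1"):
    return gio.TranscriptModel(
        tid, gid, chrom, strand, exons, fpkm={"default": fpkm}
    )


class TestExplainHyperds:
    def setup_method(self):
        self.reference = _gtf_anno(
            [_tmodel("rt1", "rg1", [(0, 20_000)], fpkm=3.0)]
        )
        self.assembly = _gtf_anno(
            [
                _tmodel("at1", "ag1", [(0, 20_000)], fpkm=3.0),
                _tmodel("at2", "ag2", [(40_000, 43_000)], fpkm=1.0),
            ]
        )

    def test_domain_inside_expressed_reference_gene(self):
        doms = dc.DomainSet([_dom("hyper", 2000, 12_000)])
        expl, _ = tx.explain_hyperds(doms, self.reference, self.assembly)
        assert expl[0].tier == "reference_expressed"
        assert expl[0].fractions["reference_expressed"] == 1.0

    def test_contigs_lift_domain_over_threshold(self):
        # assembly covers 3/10 of the domain, contigs bring it to 6/10
        doms = dc.DomainSet([_dom("hyper", 40_000, 50_000)])
        reads = reads_frame(
            [("chr1", 43_000, 46_000, "+", "a")] * 3
        )
        contigs = tx.build_contigs(reads)
        expl, _ = tx.explain_hyperds(
            doms, self.reference, self.assembly, contigs
        )
        assert expl[0].fractions["assembly"] == pytest.approx(0.3)
        assert expl[0].fractions["assembly_plus_contigs"] == pytest.approx(0.6)
        assert expl[0].tier == "assembly_plus_contigs"

    def test_uncovered_domain_unexplained_and_untranscribed(self):
        doms = dc.DomainSet([_dom("hyper", 100_000, 130_000)])
        expl, summary = tx.explain_hyperds(doms, self.reference, self.assembly)
        assert expl[0].tier == "unexplained"
        assert expl[0].untranscribed
        assert summary["untranscribed_fraction"] == 1.0

    def test_fractions_monotone_along_cascade(self, rng):
        doms = dc.DomainSet(
            [_dom("hyper", int(s), int(s) + 8000) for s in range(0, 150_000, 20_000)]
        )
        reads = reads_frame(
            [
                ("chr1", int(s), int(s) + 2000, "+", "a")
                for s in rng.integers(0, 150_000, size=30)
                for _ in range(3)
            ]
        )
        partial = gio.FeatureTrack.from_intervals(
            "mask", [gio.GenomicInterval("chr1", 60_000, 90_000)]
        )
        expl, _ = tx.explain_hyperds(
            doms, self.reference, self.assembly, tx.build_contigs(reads), partial
        )
        order = ["reference_expressed", "assembly", "assembly_plus_contigs",
                 "plus_partial_meth"]
        for e in expl:
            fr = [e.fractions[k] for k in order]
            assert fr == sorted(fr)
        # tier assignment is a partition
        assert all(e.tier in tx.HYPERD_TIERS for e in expl)


class TestExplainHypods:
    def test_low_fpkm_gene_attribution(self):
        assembly = _gtf_anno([_tmodel("t1", "g1", [(0, 30_000)], fpkm=0.2)])
        doms = dc.DomainSet([_dom("hypo", 5000, 15_000)])
        expl, _ = tx.explain_hypods(doms, assembly)
        assert expl[0].tier == "low_fpkm_gene"

    def test_alt_downstream_promoter(self):
        assembly = _gtf_anno(
            [
                _tmodel("t1", "g1", [(0, 2000), (10_000, 30_000)], fpkm=5.0),
                _tmodel("t2", "g1", [(12_000, 30_000)], fpkm=5.0),
            ]
        )
        alt = tx.alt_tss_windows(assembly)
        assert [(r.start, r.end) for r in alt.df.itertuples()] == [(12_000, 14_000)]
        doms = dc.DomainSet([_dom("hypo", 12_000, 14_000)])
        expl, _ = tx.explain_hypods(doms, assembly, alt_tss_track=alt)
        assert expl[0].tier == "alt_downstream_promoter"

    def test_untranscribed_domain(self):
        assembly = _gtf_anno([_tmodel("t1", "g1", [(0, 1000)], fpkm=5.0)])
        doms = dc.DomainSet([_dom("hypo", 50_000, 60_000)])
        expl, summary = tx.explain_hypods(doms, assembly)
        assert expl[0].tier == "untranscribed"
        assert summary["tier_fractions"]["untranscribed"] == 1.0

    def test_highly_expressed_overlap_is_unexplained_transcribed(self):
        assembly = _gtf_anno([_tmodel("t1", "g1", [(0, 30_000)], fpkm=9.0)])
        doms = dc.DomainSet([_dom("hypo", 5000, 15_000)])
        expl, _ = tx.explain_hypods(doms, assembly)
        assert expl[0].tier == "unexplained_transcribed"


class TestFpkmMethRelation:
    def _genes(self, spec):
        """spec: list of (fpkm, meth_pct); builds genes + methylome."""
        genes, rows = [], []
        for i, (fpkm, meth) in enumerate(spec):
            start = i * 10_000
            t = _tmodel(f"t{i}", f"g{i}", [(start, start + 5000)], fpkm=fpkm)
            genes.append(gio.GeneModel(f"g{i}", "chr1", "+", [t]))
            n_meth = int(round(10 * meth / 100))
            rows += [
                ("chr1", start + k * 100, n_meth, 10 - n_meth) for k in range(5)
            ]
        return genes, make_methylome(rows)

    def test_constructed_crossover_at_half(self):
        spec = [(f / 100, 5.0) for f in range(5, 50, 5)]     # unmeth below 0.5
        spec += [(f / 100, 95.0) for f in range(55, 200, 10)]  # meth above
        genes, meth = self._genes(spec)
        result = tx.fpkm_meth_relation(genes, meth)
        assert result["threshold"] == pytest.approx(0.5)

    def test_all_unmethylated_threshold_is_last_bin_edge(self):
        genes, meth = self._genes([(0.05, 5.0), (1.23, 5.0)])
        result = tx.fpkm_meth_relation(genes, meth)
        assert result["threshold"] == pytest.approx(1.3)

    def test_no_scorable_genes_raises(self):
        genes, _ = self._genes([(1.0, 5.0)])
        empty = make_methylome([("chrZ", 5, 1, 0)])
        with pytest.raises(ValueError, match="no scorable genes"):
            tx.fpkm_meth_relation(genes, empty)


class TestDetectEscapees:
    def _gene(self, length=20_000, fpkm=5.0):
        t = _tmodel("t1", "g1", [(0, length)], fpkm=fpkm)
        return gio.GeneModel("g1", "chr1", "+", [t])

    def test_uniformly_unmethylated_gene_confirmed(self):
        meth = uniform_methylome("chr1", range(0, 20_000, 100), 5.0)
        (esc,) = tx.detect_escapees([self._gene()], meth)
        assert esc.confirmed

    def test_internal_methylated_block_rejected_by_windows(self):
        # 30-kbp gene, 6-kbp block at 90 %: average ~19.6 % passes stage 1
        rows = []
        for p in range(0, 30_000, 100):
            meth = 90.0 if 12_000 <= p < 18_000 else 2.0
            m = int(round(10 * meth / 100))
            rows.append(("chr1", p, m, 10 - m))
        meth_table = make_methylome(rows)
        (esc,) = tx.detect_escapees([self._gene(length=30_000)], meth_table)
        assert esc.gene_body_meth < 25.0
        assert not esc.confirmed
        assert esc.max_window_meth > 25.0

    def test_low_fpkm_gene_never_screened(self):
        meth = uniform_methylome("chr1", range(0, 20_000, 100), 5.0)
        assert tx.detect_escapees([self._gene(fpkm=0.4)], meth) == []


class TestFeatureEnrichment:
    def _groups(self, n_hit_a, n_a, n_hit_b, n_b):
        group_a = [_dom("hyper", i * 10_000, i * 10_000 + 1000, did=f"a{i}")
                   for i in range(n_a)]
        group_b = [_dom("hypo", 10_000_000 + i * 10_000,
                        10_000_000 + i * 10_000 + 1000, did=f"b{i}")
                   for i in range(n_b)]
        feats = [
            gio.GenomicInterval("chr1", d.start, d.end)
            for d in group_a[:n_hit_a] + group_b[:n_hit_b]
        ]
        track = gio.FeatureTrack.from_intervals("TE", feats)
        return group_a, group_b, track

    def test_printed_style_counts_match_closed_form(self):
        a, b, track = self._groups(90, 100, 10, 100)
        result = tx.feature_enrichment(a, b, track)
        assert result["counts"] == [[90, 10], [10, 90]]
        assert result["chi2"] == pytest.approx(128.0)
        assert not result["warning"]

    def test_identical_groups_give_zero_statistic(self):
        a, b, track = self._groups(50, 100, 50, 100)
        result = tx.feature_enrichment(a, b, track)
        assert result["chi2"] == 0.0
        assert result["p"] == 1.0

    def test_empty_group_raises(self):
        a, _, track = self._groups(5, 10, 0, 0)
        with pytest.raises(ValueError):
            tx.feature_enrichment(a, [], track)

    def test_small_expected_cells_flagged(self):
        a, b, track = self._groups(1, 4, 0, 4)
        assert tx.feature_enrichment(a, b, track)["warning"]
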