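"""Assembly curation rules, classification, novel genes and TSSs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from methdomain import annotation_curation as cur
from methdomain import genomic_io as gio
from _naive import naive_cdf_gap_threshold, naive_classify


def _t(tid, gid, exons, strand="+", fpkm=5.0, chrom="chr1"):
    return gio.TranscriptModel(tid, gid, chrom, strand, exons, fpkm={"default": fpkm})


class TestRabtThreshold:
    def test_separated_masses(self):
        result = cur.rabt_threshold([10.0] * 20, [0.01] * 20)
        assert result.threshold == 0.01
        assert result.cdf_gap == 1.0

    def test_identical_samples_gap_zero(self):
        result = cur.rabt_threshold([1.0, 2.0], [1.0, 2.0])
        assert result.cdf_gap == 0.0

    def test_all_values_identical_warns(self):
        result = cur.rabt_threshold([3.0, 3.0], [3.0])
        assert result.threshold == 3.0
        assert result.warning

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            cur.rabt_threshold([], [1.0])

    def test_interleaved_toy_matches_brute_force(self):
        tx_v, ig_v = [0.0, 1.0, 2.0, 3.0], [0.5, 1.5]
        result = cur.rabt_threshold(tx_v, ig_v)
        want_t, want_gap = naive_cdf_gap_threshold(tx_v, ig_v)
        assert result.threshold == want_t
        assert result.cdf_gap == pytest.approx(want_gap)

    def test_random_trials_match_brute_force(self, rng):
        for _ in range(40):
            tx_v = list(np.round(rng.lognormal(0, 1.5, size=rng.integers(2, 60)), 2))
            ig_v = list(np.round(rng.lognormal(-2, 1.0, size=rng.integers(2, 60)), 2))
            result = cur.rabt_threshold(tx_v, ig_v)
            want_t, want_gap = naive_cdf_gap_threshold(tx_v, ig_v)
            assert result.threshold == want_t
            assert result.cdf_gap == pytest.approx(want_gap)


class TestIntergenicSampling:
    def _anno(self):
        return gio.AnnotationSet([_t("t1", "g1", [(40_000, 60_000)])])

    def test_deterministic_under_seed(self):
        genome = {"chr1": 200_000}
        a = cur.sample_size_matched_intergenic(genome, self._anno(), [500, 1000], 5, 7)
        b = cur.sample_size_matched_intergenic(genome, self._anno(), [500, 1000], 5, 7)
        pd.testing.assert_frame_equal(a.df, b.df)

    def test_sizes_match_exactly_and_avoid_genes(self):
        genome = {"chr1": 200_000}
        track = cur.sample_size_matched_intergenic(
            genome, self._anno(), [500, 1000, 2000], 4, 3
        )
        lengths = sorted(track.df["end"] - track.df["start"])
        assert lengths == [500] * 4 + [1000] * 4 + [2000] * 4
        for r in track.df.itertuples():
            assert r.end <= 39_000 or r.start >= 61_000  # 1-kbp buffer

    def test_saturated_genome_raises_with_size(self):
        genome = {"chr1": 50_000}
        anno = gio.AnnotationSet([_t("t1", "g1", [(0, 50_000)])])
        with pytest.raises(ValueError, match="size 100"):
            cur.sample_size_matched_intergenic(genome, anno, [100], 1, 0)


class TestCurateMonoexonic:
    def _support(self, counts, intergenic=(0.1, 0.1, 0.2)):
        return {"transcript_counts": counts, "intergenic_counts": list(intergenic)}

    def test_unstranded_mono_removed(self):
        anno = gio.AnnotationSet(
            [_t("t1", "g1", [(0, 1000)], strand="."), _t("t2", "g2", [(5000, 6000)])]
        )
        out, report = cur.curate_monoexonic(anno, self._support({"t2": 9.0}))
        assert report["no_strand"] == 1
        assert set(out.transcripts) == {"t2"}

    def test_intronic_same_strand_removed_opposite_kept(self):
        host = _t("h", "gh", [(0, 1000), (20_000, 21_000)])
        same = _t("ts", "gs", [(5000, 6000)], strand="+")
        opp = _t("to", "go", [(8000, 9000)], strand="-")
        anno = gio.AnnotationSet([host, same, opp])
        out, report = cur.curate_monoexonic(
            anno, self._support({"h": 9.0, "to": 9.0})
        )
        assert report["intronic"] == 1
        assert set(out.transcripts) == {"h", "to"}

    def test_mono_merged_into_upstream_3prime_host(self):
        host = _t("h", "gh", [(0, 1000), (5000, 6000)])
        mono = _t("m", "gm", [(7500, 8200)], strand="+")  # 1.5 kbp past 3' end
        anno = gio.AnnotationSet([host, mono])
        out, report = cur.curate_monoexonic(anno, self._support({"h": 9.0}))
        assert report["merged_3prime"] == 1
        assert out.transcripts["h"].exons == [(0, 1000), (5000, 6000), (7500, 8200)]
        assert "m" not in out.transcripts

    def test_merge_chains_to_fixpoint(self):
        host = _t("h", "gh", [(0, 1000), (5000, 6000)])
        m1 = _t("m1", "g1", [(7000, 7400)], strand="+")
        m2 = _t("m2", "g2", [(8600, 9000)], strand="+")  # within 2 kbp of m1's end
        anno = gio.AnnotationSet([host, m1, m2])
        out, report = cur.curate_monoexonic(anno, self._support({"h": 9.0}))
        assert report["merged_3prime"] == 2
        assert out.transcripts["h"].end == 9000

    def test_low_count_mono_gene_dropped(self):
        keep = _t("hi", "ghi", [(0, 900)], fpkm=9.0)
        drop = _t("lo", "glo", [(50_000, 50_900)], fpkm=0.01)
        anno = gio.AnnotationSet([keep, drop])
        support = self._support(
            {"hi": 50.0, "lo": 0.05}, intergenic=[0.05, 0.1, 0.1, 0.2]
        )
        out, report = cur.curate_monoexonic(anno, support)
        assert report["low_count"] == 1
        assert set(out.transcripts) == {"hi"}

    def test_missing_read_support_raises(self):
        anno = gio.AnnotationSet([_t("m", "gm", [(0, 900)])])
        with pytest.raises(ValueError, match="read support"):
            cur.curate_monoexonic(anno, self._support({}))

    def test_pipeline_applied_twice_is_stable(self):
        host = _t("h", "gh", [(0, 1000), (5000, 6000)])
        keep = _t("hi", "ghi", [(100_000, 100_900)], fpkm=9.0)
        mono = _t("m", "gm", [(7500, 8200)], strand="+")
        noise = _t("lo", "glo", [(50_000, 50_400)], fpkm=0.01)
        anno = gio.AnnotationSet([host, keep, mono, noise])
        support = self._support(
            {"h": 40.0, "hi": 50.0, "lo": 0.05},
            intergenic=[0.05, 0.08, 0.1, 0.2],
        )
        once, _ = cur.curate_monoexonic(anno, support)
        twice, report = cur.curate_monoexonic(once, support)
        assert set(once.transcripts) == set(twice.transcripts)
        assert report["no_strand"] == report["intronic"] == report["merged_3prime"] == 0


class TestClassifyVsReference:
    def setup_method(self):
        self.ref = gio.AnnotationSet(
            [
                _t("r1", "rg1", [(0, 1000), (5000, 6000), (9000, 10_000)]),
                _t("r2", "rg2", [(50_000, 52_000)], strand="-"),
            ]
        )

    def _code(self, t):
        return cur.classify_vs_reference(gio.AnnotationSet([t]), self.ref)[t.id]

    def test_identical_intron_chain_is_equal(self):
        t = _t("q", "qg", [(100, 1000), (5000, 6000), (9000, 9500)])
        assert self._code(t) == ("=", "rg1")

    def test_contained_mono_in_exon_is_c(self):
        t = _t("q", "qg", [(200, 800)])
        assert self._code(t) == ("c", "rg1")

    def test_shared_junction_is_j(self):
        t = _t("q", "qg", [(400, 1000), (5000, 5400), (7000, 7500)])
        assert self._code(t) == ("j", "rg1")

    def test_intronic_mono_is_i(self):
        t = _t("q", "qg", [(2000, 3000)])
        assert self._code(t) == ("i", "rg1")

    def test_opposite_strand_overlap_is_x(self):
        t = _t("q", "qg", [(50_500, 51_000)], strand="+")
        assert self._code(t) == ("x", "rg2")

    def test_no_overlap_is_u(self):
        t = _t("q", "qg", [(200_000, 201_000)])
        assert self._code(t) == ("u", None)

    def test_agrees_with_naive_comparator_on_random_annotations(self, rng):
        refs = []
        for i in range(12):
            anchor = int(rng.integers(0, 80_000))
            n = int(rng.integers(1, 4))
            cuts = np.sort(rng.choice(20_000, size=2 * n, replace=False)) + anchor
            refs.append(
                _t(
                    f"r{i}", f"rg{i}",
                    [(int(cuts[2 * k]), int(cuts[2 * k + 1])) for k in range(n)],
                    strand="+" if rng.random() < 0.5 else "-",
                )
            )
        reference = gio.AnnotationSet(refs)
        queries = []
        for i in range(40):
            anchor = int(rng.integers(0, 90_000))
            n = int(rng.integers(1, 4))
            cuts = np.sort(rng.choice(15_000, size=2 * n, replace=False)) + anchor
            queries.append(
                _t(
                    f"q{i}", f"qg{i}",
                    [(int(cuts[2 * k]), int(cuts[2 * k + 1])) for k in range(n)],
                    strand="+" if rng.random() < 0.5 else "-",
                )
            )
        got = cur.classify_vs_reference(gio.AnnotationSet(queries), reference)
        for q in queries:
            assert got[q.id][0] == naive_classify(q, refs), q.id


class TestCallNovelGenes:
    def setup_method(self):
        self.ref = gio.AnnotationSet([_t("r1", "rg1", [(0, 10_000)])])

    def _call(self, transcripts, te=None):
        oocyte = gio.AnnotationSet(transcripts)
        return {
            c.gene_id: c
            for c in cur.call_novel_genes(oocyte, self.ref, None, te)
        }

    def test_multi_near_same_strand_reference_excluded(self):
        t = _t("q", "qg", [(10_800, 11_200), (12_000, 12_400)])  # 800 bp gap
        calls = self._call([t])
        assert calls["qg"].exclusion_reasons == {"near_reference"}

    def test_same_distance_opposite_strand_accepted(self):
        t = _t("q", "qg", [(10_800, 11_200), (12_000, 12_400)], strand="-")
        assert self._call([t])["qg"].accepted

    def test_mono_uses_5kbp_margin(self):
        t = _t("q", "qg", [(14_000, 14_800)])  # 4 kbp away: inside mono margin
        assert not self._call([t])["qg"].accepted
        t2 = _t("q2", "qg2", [(16_000, 16_800)])  # 6 kbp away: outside
        assert self._call([t2])["qg2"].accepted

    def test_mono_coextensive_with_te_excluded(self):
        t = _t("q", "qg", [(50_000, 51_000)])
        te = gio.FeatureTrack(
            "TE",
            pd.DataFrame(
                [("chr1", 49_950, 51_050, "+", "MaLR")],
                columns=gio.FeatureTrack.COLUMNS,
            ),
        )
        calls = self._call([t], te)
        assert calls["qg"].exclusion_reasons == {"repeat_monoexonic"}

    def test_reference_matched_genes_not_candidates(self):
        t = _t("q", "qg", [(100, 9000)])  # 'o' overlap with rg1
        assert "qg" not in self._call([t])


class TestNovelUpstreamTSS:
    def setup_method(self):
        self.ref = gio.AnnotationSet(
            [_t("r1", "rg1", [(20_000, 21_000), (25_000, 26_000), (29_000, 30_000)])]
        )
        self.cgi = gio.FeatureTrack.from_intervals(
            "CGI", [gio.GenomicInterval("chr1", 19_900, 20_100)]
        )

    def test_qualifying_transcript_recovered_with_distance(self):
        t = _t("q", "qg", [(15_000, 15_500), (25_000, 26_000), (29_000, 30_000)])
        records, summary = cur.find_novel_upstream_tss(
            gio.AnnotationSet([t]), self.ref, self.cgi
        )
        assert [r.gene_id for r in records] == ["rg1"]
        assert records[0].distance == 5000
        assert summary["median_distance"] == 5000

    def test_start_inside_reference_first_exon_rejected(self):
        t = _t("q", "qg", [(19_500, 21_000), (25_000, 26_000), (29_000, 30_000)])
        records, _ = cur.find_novel_upstream_tss(
            gio.AnnotationSet([t]), self.ref, self.cgi
        )
        assert records == []

    def test_start_inside_reference_tss_cgi_rejected(self):
        t = _t("q", "qg", [(19_950, 19_990), (25_000, 26_000), (29_000, 30_000)])
        records, _ = cur.find_novel_upstream_tss(
            gio.AnnotationSet([t]), self.ref, self.cgi
        )
        assert records == []


class TestClassifyTSS:
    def _rec(self, pos, strand="+"):
        return cur.TSSRecord("g", "t", "chr1", pos, strand)

    def setup_method(self):
        self.cgi = gio.FeatureTrack.from_intervals(
            "CGI", [gio.GenomicInterval("chr1", 1000, 1500)]
        )
        self.te = gio.FeatureTrack(
            "TE",
            pd.DataFrame(
                [("chr1", 5000, 6000, "+", "MaLR")],
                columns=gio.FeatureTrack.COLUMNS,
            ),
        )

    def test_tss_near_cgi_edge(self):
        (rec,) = cur.classify_tss([self._rec(1550)], self.cgi, self.te)
        assert rec.tss_class == "CGI_associated"  # 50 bp from the edge

    def test_tss_in_te_same_strand(self):
        (rec,) = cur.classify_tss([self._rec(5500)], self.cgi, self.te)
        assert (rec.tss_class, rec.te_family) == ("TE_associated", "MaLR")

    def test_tss_in_te_opposite_strand_is_other(self):
        (rec,) = cur.classify_tss([self._rec(5500, "-")], self.cgi, self.te)
        assert rec.tss_class == "other"


class TestTeTssExpectation:
    def _setup(self):
        inter = gio.FeatureTrack.from_intervals(
            "intergenic", [gio.GenomicInterval("chr1", 0, 100_000)]
        )
        te = gio.FeatureTrack(
            "TE",
            pd.DataFrame(
                [("chr1", 10_000, 20_000, "+", "MaLR")],
                columns=gio.FeatureTrack.COLUMNS,
            ),
        )
        return inter, te

    def test_observed_matching_occupancy_gives_ratio_one(self):
        inter, te = self._setup()
        out = cur.te_tss_expectation(
            te, inter, {"MaLR": 100, "none": 900}, seed=3, n_draws=50
        )
        row = out[out["family"] == "MaLR"].iloc[0]
        assert row["ratio"] == pytest.approx(1.0)
        assert row["expected_mc"] == pytest.approx(100, rel=0.1)
        assert row["p"] > 0.5

    def test_threefold_enrichment_is_significant(self):
        inter, te = self._setup()
        out = cur.te_tss_expectation(
            te, inter, {"MaLR": 300, "none": 700}, seed=3, n_draws=20
        )
        row = out[out["family"] == "MaLR"].iloc[0]
        assert row["ratio"] == pytest.approx(3.0)
        assert row["p"] < 1e-10

    def test_absent_family_skipped(self):
        inter, te = self._setup()
        out = cur.te_tss_expectation(te, inter, {"ERVK": 5}, seed=3, n_draws=5)
        assert bool(out.iloc[0]["skipped"])


class TestReconcile:
    def test_patch_transcripts_restored_above_threshold(self):
        primary = gio.AnnotationSet([_t("a", "ga", [(0, 1000)])])
        patch = gio.AnnotationSet(
            [_t("b", "gb", [(5000, 6000)]), _t("c", "gc", [(9000, 9500)])]
        )
        out = cur.reconcile_annotations(
            primary, [patch], {"b": 2.0, "c": 0.001}, threshold=0.1
        )
        assert set(out.transcripts) == {"a", "b"}
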