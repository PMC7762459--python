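"""Windowed signal tracks, enhancer calls, domains and explanations."""

import numpy as np
import pandas as pd
import pytest

import omicdriver as od
from omicdriver import enhancers as enh


def track(values, start0=0, width=50, chrom="chr1"):
    starts = start0 + np.arange(len(values)) * width
    return pd.DataFrame({"chrom": chrom, "start": starts,
                         "end": starts + width,
                         "value": np.asarray(values, dtype=float)})


class TestQuantileNormalize:
    def test_three_window_worked_example(self):
        # sorted means: [1.5, 3.5, 6.5]
        qa, qb = enh.quantile_normalize([track([1, 5, 3]),
                                         track([2, 4, 8])])
        np.testing.assert_allclose(qa["value"], [1.5, 6.5, 3.5])
        np.testing.assert_allclose(qb["value"], [1.5, 3.5, 6.5])

    def test_identical_tracks_unchanged(self):
        t = track([3, 1, 4, 1, 5])
        qa, qb = enh.quantile_normalize([t, t.copy()])
        np.testing.assert_allclose(qa["value"], t["value"])
        np.testing.assert_allclose(qb["value"], t["value"])

    def test_output_distributions_identical(self, rng):
        tracks = [track(rng.lognormal(1, 1, 200)) for _ in range(4)]
        out = enh.quantile_normalize(tracks)
        ref = np.sort(out[0]["value"].to_numpy())
        for t in out[1:]:
            np.testing.assert_allclose(np.sort(t["value"].to_numpy()), ref,
                                       rtol=1e-12)

    def test_mismatched_grids_raise(self):
        with pytest.raises(ValueError):
            enh.quantile_normalize([track([1, 2]), track([1, 2], start0=25)])


class TestExcludeRegions:
    def test_half_open_overlap_rule(self):
        t = track([1.0], start0=100)      # window [100, 150)
        one_bp = pd.DataFrame({"chrom": ["chr1"], "start": [149],
                               "end": [200], "name": [""]})
        touching = pd.DataFrame({"chrom": ["chr1"], "start": [150],
                                 "end": [200], "name": [""]})
        assert len(enh.exclude_regions(t, blacklist=one_bp)) == 0
        assert len(enh.exclude_regions(t, blacklist=touching)) == 1

    def test_empty_exclusions_identity(self):
        t = track([1, 2, 3])
        out = enh.exclude_regions(t)
        pd.testing.assert_frame_equal(out, t)

    def test_malformed_bed_reports_line(self, tmp_path):
        bad = tmp_path / "bad.bed"
        bad.write_text("chr1\t0\t100\nchr1\toops\t200\n")
        with pytest.raises(ValueError, match="line 2"):
            enh.read_bed(bad)


class TestClassification:
    def test_mark_combinations(self):
        k4 = track([10, 10, 0, 0])
        k27 = track([10, 0, 10, 0])
        calls = enh.classify_enhancers(k4, k27, k4_threshold=5,
                                       k27_threshold=5)
        assert list(calls["cls"]) == ["strong", "weak", "none", "none"]

    def test_default_threshold_top_quartile_of_nonzero(self):
        t = track([0, 1, 2, 3, 4])
        assert enh.mark_threshold(t) == np.quantile([1, 2, 3, 4], 0.75)

    def test_chromatin_state_split(self):
        states = pd.DataFrame({"chrom": "chr1", "start": [0, 100, 200],
                               "end": [100, 200, 300],
                               "name": ["E7", "E15", "E18"]})
        out = enh.chromatin_activity(states)
        assert list(out["activity"]) == ["active", "inactive", "inactive"]
        with pytest.raises(ValueError):
            enh.chromatin_activity(pd.DataFrame(
                {"chrom": ["chr1"], "start": [0], "end": [1],
                 "name": ["E19"]}))


class TestDifferential:
    def test_inclusive_fold_boundary(self):
        tum = track([9, 4])
        nor = track([4, 9])
        out = enh.enhancer_differential(tum, nor, fold=2.0, pseudocount=1.0)
        assert list(out["status"]) == ["gain", "loss"]

    def test_fold_validation(self):
        with pytest.raises(ValueError):
            enh.enhancer_differential(track([1]), track([1]), fold=1.0)

    def test_noise_free_planted_exact_recovery(self):
        tum, nor, truth = od.generate_signal_tracks(
            1000, n_gain=60, n_loss=60, fold=2.5, noise_cv=0.0, seed=0)
        out = enh.enhancer_differential(tum, nor, fold=2.0, pseudocount=0.0)
        assert (out["status"].to_numpy() == truth["status"].to_numpy()).all()

    def test_noisy_fold4_perfect_precision_recall(self):
        tum, nor, truth = od.generate_signal_tracks(
            2000, n_gain=100, n_loss=100, fold=4.0, noise_cv=0.1, seed=1)
        out = enh.enhancer_differential(tum, nor, fold=2.0)
        for status in ("gain", "loss"):
            called = out["status"] == status
            planted = truth["status"] == status
            assert (called & planted).sum() == called.sum() == planted.sum()


class TestMergeAndDomains:
    def test_adjacent_same_class_windows_merge(self):
        calls = track([1, 1, 1, 1])
        calls["cls"] = ["weak", "weak", "strong", "strong"]
        calls["status"] = ["stable"] * 4
        merged = enh.merge_windows(calls)
        assert len(merged) == 2
        assert merged.loc[0, "end"] - merged.loc[0, "start"] == 100

    def test_lone_gene_domain_arithmetic(self):
        genes = pd.DataFrame({"gene": ["A"], "chrom": ["chr1"],
                              "tss": [100_000], "strand": ["+"]})
        d = enh.build_regulatory_domains(genes).iloc[0]
        assert (d["basal_start"], d["basal_end"]) == (95_000, 101_000)
        assert (d["start"], d["end"]) == (75_000, 121_000)

    def test_minus_strand_orientation(self):
        genes = pd.DataFrame({"gene": ["A"], "chrom": ["chr1"],
                              "tss": [100_000], "strand": ["-"]})
        d = enh.build_regulatory_domains(genes).iloc[0]
        assert (d["basal_start"], d["basal_end"]) == (99_000, 105_000)

    def test_neighbors_clip_extension(self):
        genes = pd.DataFrame({"gene": ["A", "B"], "chrom": ["chr1", "chr1"],
                              "tss": [100_000, 110_000],
                              "strand": ["+", "+"]})
        d = enh.build_regulatory_domains(genes).set_index("gene")
        # A's right extension stops at B's basal start (105,000);
        # B's left extension stops at A's basal end (101,000)
        assert d.loc["A", "end"] == 105_000
        assert d.loc["B", "start"] == 101_000
        # basal domains are never invaded
        assert d.loc["A", "basal_end"] == 101_000

    def test_duplicate_gene_ids_raise(self):
        genes = pd.DataFrame({"gene": ["A", "A"], "chrom": ["chr1"] * 2,
                              "tss": [1000, 2000], "strand": ["+", "+"]})
        with pytest.raises(ValueError):
            enh.build_regulatory_domains(genes)

    def test_region_gene_association_requires_overlap(self):
        genes = pd.DataFrame({"gene": ["A"], "chrom": ["chr1"],
                              "tss": [100_000], "strand": ["+"]})
        domains = enh.build_regulatory_domains(genes)
        regions = pd.DataFrame({"chrom": ["chr1", "chr1"],
                                "start": [74_000, 60_000],
                                "end": [75_001, 70_000]})
        pairs = enh.associate_regions_to_genes(regions, domains)
        assert list(pairs["region"]) == [0]   # 1-bp overlap counts


class TestExpressionByClass:
    def test_planted_loss_shift_detected(self, rng):
        n_genes = 120
        genes = [f"g{i}" for i in range(n_genes)]
        tum = pd.Series(8 + 0.3 * rng.standard_normal(n_genes), index=genes)
        nor = tum + 0.1 * rng.standard_normal(n_genes)
        loss_genes = genes[:40]
        tum[loss_genes] -= 1.5
        calls = track(np.ones(3))
        calls["cls"] = ["strong", "strong", "weak"]
        calls["status"] = ["loss", "stable", "stable"]
        region_gene = pd.DataFrame(
            {"region": [0] * 40 + [1] * 40 + [2] * 40, "gene": genes})
        out = enh.expression_by_enhancer_class(tum, nor, region_gene, calls)
        out = out.set_index(["cls", "status"])
        assert out.loc[("strong", "loss"), "p"] < 0.01
        assert out.loc[("strong", "loss"), "mean_shift"] < -1.0
        assert out.loc[("strong", "stable"), "p"] > 0.01

    def test_pairs_partition_once(self):
        calls = track(np.ones(2))
        calls["cls"] = ["strong", "weak"]
        calls["status"] = ["gain", "loss"]
        region_gene = pd.DataFrame({"region": [0, 1], "gene": ["a", "b"]})
        merged = region_gene.merge(calls[["cls", "status"]],
                                   left_on="region", right_index=True)
        assert len(merged) == len(region_gene)


class TestExplainDrivers:
    def test_rule_table(self):
        ev = pd.DataFrame({
            "direction": ["down", "down", "up", "up", "na"],
            "mutated": [False, False, True, False, False],
            "amplified": [False, False, False, False, False],
            "deleted": [True, False, False, False, False],
            "hypermethylated": [False, False, False, False, False],
            "enhancer_gain": [False, False, False, True, False],
            "enhancer_loss": [False, True, False, False, False],
        }, index=["del_down", "enh_down", "mut_up", "enh_up", "nodir"])
        records, summary = enh.explain_driver_expression(ev)
        assert "nodir" not in records.index
        assert records.loc["del_down", "genome_explained"]
        assert not records.loc["del_down", "enhancer_explained"]
        assert records.loc["enh_down", "enhancer_explained"]
        assert not records.loc["enh_down", "genome_explained"]
        assert summary.n == 4
        assert summary.genome_fraction == pytest.approx(2 / 4)
        assert summary.enhancer_fraction == pytest.approx(2 / 4)
        assert summary.overlap_fraction == pytest.approx(0.0)

    def test_fractions_bounded(self, rng):
        n = 30
        ev = pd.DataFrame({
            "direction": rng.choice(["up", "down"], n),
            "mutated": rng.random(n) < 0.3,
            "amplified": rng.random(n) < 0.3,
            "deleted": rng.random(n) < 0.3,
            "hypermethylated": rng.random(n) < 0.3,
            "enhancer_gain": rng.random(n) < 0.3,
            "enhancer_loss": rng.random(n) < 0.3,
        }, index=[f"d{i}" for i in range(n)])
        _, s = enh.explain_driver_expression(ev)
        assert 0 <= s.genome_fraction <= 1
        assert 0 <= s.enhancer_fraction <= 1
        assert s.overlap_fraction <= min(s.genome_fraction,
                                         s.enhancer_fraction)


class TestBedgraphRoundtrip:
    def test_write_read(self, tmp_path):
        t = track([1.5, 2.5, 0.0])
        path = tmp_path / "t.bedgraph"
        enh.write_bedgraph(t, path)
        back = enh.read_bedgraph(path)
        pd.testing.assert_frame_equal(back, t)
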