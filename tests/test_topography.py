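"""Arm ratios, paired region tests, desert detection, track export."""

import numpy as np
import pandas as pd
import pytest

import methtopo as mt
from methtopo import io as mio
from methtopo.topography import track_frames


def small_genome():
    return mt.GenomeTable(
        {"chrA": 1000},
        pd.DataFrame({"chrom": ["chrA"], "start": [490], "end": [510]}),
        pd.DataFrame(
            {"chrom": ["chrA"] * 3, "start": [0, 490, 510],
             "end": [490, 510, 1000], "name": ["p1", "cen", "q1"],
             "stain": ["gneg", "acen", "gpos100"]}
        ),
    )


class TestArmRatios:
    def test_hand_ratio(self, manifest_factory):
        """10 enhancer probes on an arm, 4 commonly hyper -> ratio 0.4."""
        rows = [(f"e{i}", "chrA", 10 + i, ["enhancer"], [], ["A450K"])
                for i in range(10)]
        manifest = manifest_factory(rows)
        common = {"hyper": frozenset(f"e{i}" for i in range(4)), "hypo": frozenset()}
        table = mt.arm_ratios(common, manifest, small_genome(), excluded_arms=())
        row = table[(table.arm == "chrAp") & (table.region == "enhancer")
                    & (table.state == "hyper")].iloc[0]
        assert row.numerator == 4 and row.denominator == 10
        assert row.ratio == pytest.approx(0.4)

    def test_excluded_arm_carries_no_ratio(self, manifest_factory):
        manifest = manifest_factory(
            [("e0", "chrA", 10, ["enhancer"], [], ["A450K"])]
        )
        common = {"hyper": frozenset(["e0"]), "hypo": frozenset()}
        table = mt.arm_ratios(common, manifest, small_genome(),
                              excluded_arms=("chrAp",))
        row = table[(table.arm == "chrAp") & (table.region == "enhancer")
                    & (table.state == "hyper")].iloc[0]
        assert row.excluded and np.isnan(row.ratio)
        assert row.numerator == 1  # counts still recorded

    def test_conservation_across_arms(self, study, result):
        """Arm numerators (incl. excluded arms) sum to the genome-wide count."""
        table = result.arm_ratios
        for region in mt.REGIONS:
            for state in ("hyper", "hypo"):
                block = table[(table.region == region) & (table.state == state)]
                genome_row = result.genome_ratios[
                    (result.genome_ratios.region == region)
                    & (result.genome_ratios.state == state)
                ].iloc[0]
                assert block.numerator.sum() == genome_row.numerator
                assert block.denominator.sum() == genome_row.denominator

    def test_ratios_in_unit_interval(self, result):
        ratios = result.arm_ratios.ratio.dropna()
        assert ((ratios >= 0) & (ratios <= 1)).all()

    def test_planted_arm_enrichment_top_ranked(self, study, result):
        """The arm with the planted affected-fraction multiplier tops the
        hyper gene-body and enhancer ratios."""
        planted = max(study.spec.arm_multipliers,
                      key=study.spec.arm_multipliers.get)
        table = result.arm_ratios
        for region in ("gene_body", "enhancer"):
            block = table[(table.region == region) & (table.state == "hyper")
                          & table.ratio.notna()]
            assert block.sort_values("ratio").iloc[-1].arm == planted

    def test_probe_relabeling_invariance(self, manifest_factory):
        rows = [(f"e{i}", "chrA", 10 + i, ["enhancer"], [], ["A450K"])
                for i in range(10)]
        manifest = manifest_factory(rows)
        common = {"hyper": frozenset(f"e{i}" for i in range(4)), "hypo": frozenset()}
        relabeled = mt.ProbeManifest(
            manifest.df.rename(index=lambda p: p.replace("e", "z"))
        )
        common2 = {"hyper": frozenset(s.replace("e", "z") for s in common["hyper"]),
                   "hypo": frozenset()}
        t1 = mt.arm_ratios(common, manifest, small_genome(), excluded_arms=())
        t2 = mt.arm_ratios(common2, relabeled, small_genome(), excluded_arms=())
        pd.testing.assert_frame_equal(t1, t2)


class TestGenomewideAndArmTests:
    def test_planted_promoter_hypo_dominates(self, result):
        ratios = result.genome_ratios.set_index(["region", "state"])["ratio"]
        assert ratios[("promoter", "hypo")] > ratios[("gene_body", "hypo")]
        assert ratios[("promoter", "hypo")] > ratios[("enhancer", "hypo")]
        tests = result.region_pair_tests
        row = tests[(tests.state == "hypo") & (tests.region_a == "promoter")
                    & (tests.region_b == "gene_body")].iloc[0]
        assert row.p < 0.01

    def test_identical_ratio_vectors_degenerate(self, manifest_factory):
        """Equal per-arm ratios for two regions -> degenerate paired test."""
        rows = []
        for i in range(10):
            rows.append((f"a{i}", "chrA", 10 + i, ["promoter", "gene_body",
                                                   "enhancer"], [], ["A450K"]))
            rows.append((f"b{i}", "chrA", 600 + i, ["promoter", "gene_body",
                                                    "enhancer"], [], ["A450K"]))
        manifest = manifest_factory(rows)
        common = {"hyper": frozenset(["a0", "b0"]), "hypo": frozenset()}
        _, tests = mt.genomewide_region_ratios(common, manifest, small_genome(),
                                               excluded_arms=())
        assert tests["degenerate"].all()
        assert tests["p"].isna().all()

    def test_arm_vs_genome_welch_identifies_planted_arm(self, study, result):
        planted = max(study.spec.arm_multipliers,
                      key=study.spec.arm_multipliers.get)
        tests = result.arm_vs_genome
        block = tests[(tests.region == "gene_body") & (tests.state == "hyper")]
        best = block.sort_values("p").iloc[0]
        assert best.arm == planted
        assert best.q < 0.05

    def test_bootstrap_replicates_seeded(self, study):
        common = {"hyper": frozenset(), "hypo": frozenset()}
        kwargs = dict(n_boot=20, seed=5)
        t1 = mt.arm_vs_genome_test(common, study.manifest, study.genome, **kwargs)
        t2 = mt.arm_vs_genome_test(common, study.manifest, study.genome, **kwargs)
        pd.testing.assert_frame_equal(t1, t2)


class TestDesertBands:
    def test_zero_coverage_band_not_desert(self, manifest_factory):
        manifest = manifest_factory(
            [("p0", "chrA", 10, ["promoter"], [], ["A450K"])]
        )
        common = {"hyper": frozenset(), "hypo": frozenset()}
        report = mt.desert_bands(common, manifest, small_genome(), min_probes=1)
        q1 = report[report.band == "q1"].iloc[0]
        assert q1.coverage == 0 and not q1.desert

    def test_covered_band_with_no_calls_is_desert(self, manifest_factory):
        rows = [(f"p{i}", "chrA", 10 + i, ["promoter"], [], ["A450K"])
                for i in range(100)]
        manifest = manifest_factory(rows)
        common = {"hyper": frozenset(), "hypo": frozenset()}
        report = mt.desert_bands(common, manifest, small_genome(), min_probes=50)
        assert report[report.band == "p1"].iloc[0].desert

    def test_flags_exactly_planted_bands(self, study, result):
        report = result.desert_report
        flagged = {(r.chrom, r.band) for r in report[report.desert].itertuples()}
        assert flagged == set(study.spec.desert_bands)

    def test_monotone_in_min_probes(self, study, result):
        common = result.common_sets
        low = mt.desert_bands(common, result.universe, study.genome, min_probes=20)
        high = mt.desert_bands(common, result.universe, study.genome, min_probes=200)
        low_set = set(low[low.desert].band + low[low.desert].chrom)
        high_set = set(high[high.desert].band + high[high.desert].chrom)
        assert high_set <= low_set


class TestTrackExport:
    def test_values_clipped_sign_preserving(self, manifest_factory, tmp_path):
        manifest = manifest_factory(
            [("h1", "chrA", 100, ["gene_body"], [], ["A450K"]),
             ("h2", "chrA", 50, ["gene_body"], [], ["A450K"]),
             ("l1", "chrA", 700, ["promoter"], [], ["A450K"])]
        )
        common = {"hyper": frozenset(["h1", "h2"]), "hypo": frozenset(["l1"])}
        mean_m = pd.Series({"h1": 8.3, "h2": 2.0, "l1": -9.1})
        frames = track_frames(common, mean_m, manifest, small_genome())
        body = frames["gene_body_hyper"]
        assert list(body.value) == [2.0, 7.0]  # sorted by position; 8.3 clipped
        assert list(body.start) == [49, 99]
        prom = frames["promoter_hypo"]
        assert list(prom.value) == [-7.0]

    def test_bedgraph_round_trip(self, manifest_factory, tmp_path):
        manifest = manifest_factory(
            [("h1", "chrA", 100, ["enhancer"], [], ["A450K"])]
        )
        common = {"hyper": frozenset(["h1"]), "hypo": frozenset()}
        mean_m = pd.Series({"h1": 3.25})
        paths = mt.export_tracks(common, mean_m, manifest, small_genome(), tmp_path)
        back = mio.read_bedgraph(paths["enhancer_hyper"])
        expected = track_frames(common, mean_m, manifest, small_genome())[
            "enhancer_hyper"
        ]
        pd.testing.assert_frame_equal(back, expected)

    def test_unknown_chromosome_rejected(self, manifest_factory):
        manifest = manifest_factory(
            [("h1", "chrZ", 100, ["enhancer"], [], ["A450K"])]
        )
        with pytest.raises(mt.MethtopoError, match="chrZ"):
            track_frames({"hyper": frozenset(), "hypo": frozenset()},
                         pd.Series(dtype=float), manifest, small_genome())
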