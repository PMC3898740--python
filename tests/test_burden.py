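import dataclasses

import numpy as np
import pytest

from burdenvt import (
    BurdenConfig,
    ControlSubset,
    GeneticModel,
    QualificationRule,
    carrier_table,
    merge_cohorts,
    qualify_variants,
    replication_like_cohort,
    run_analysis,
    vt_scan,
)
from burdenvt.burden import AnalysisPlan, SampleChoice
from burdenvt.errors import ConfigError, DegenerateInputError, MergeError
from burdenvt.filters import compute_sample_maf
from burdenvt.model import RegionAnnotation, VariantRecord
from burdenvt.simulate import FixedMaf, SimConfig, simulate_cohort
from tests.conftest import make_cohort

WIDE = QualificationRule(maf_threshold=0.5)


class TestCarrierTable:
    def test_toy_manual_tally(self, toy_cohort):
        q = qualify_variants(toy_cohort, WIDE)
        dom = carrier_table(toy_cohort, q, GeneticModel.DOMINANT)
        assert dom.as_tuple() == (3, 2, 1, 4)
        add = carrier_table(toy_cohort, q, GeneticModel.ADDITIVE)
        assert add.as_tuple() == (5, 5, 1, 9)

    def test_multi_variant_homozygote_counts_once_dominant(self, toy_cohort):
        """ca2 carries m1 het and fs1 hom: 1 carrier dominant, 3 alleles additive."""
        q = {"m1", "fs1"}
        dom = carrier_table(toy_cohort, q, GeneticModel.DOMINANT)
        add = carrier_table(toy_cohort, q, GeneticModel.ADDITIVE)
        assert dom.a == 2  # ca1 (m1) and ca2 (m1+fs1) each count once
        assert add.a == 4  # ca1: 1; ca2: 1 + 2

    def test_empty_qualifying_set(self, toy_cohort):
        t = carrier_table(toy_cohort, set())
        assert t.as_tuple() == (0, 5, 0, 5)

    def test_normal_weight_subset_shrinks_control_margin(self, toy_cohort):
        # co2 (bmi 31) drops; carrier co1 (bmi 24) stays
        t = carrier_table(
            toy_cohort, {"m2"}, control_subset=ControlSubset.NORMAL_WEIGHT
        )
        assert t.as_tuple() == (1, 4, 1, 3)

    def test_degenerate_arm_rejected(self):
        all_cases = make_cohort(
            [("a", "case"), ("b", "case")], [("v", 1, "missense")], []
        )
        with pytest.raises(DegenerateInputError):
            carrier_table(all_cases, {"v"})

    def test_unknown_qualifying_variant_rejected(self, toy_cohort):
        with pytest.raises(ConfigError, match="unknown"):
            carrier_table(toy_cohort, {"ghost"})


class TestVtScan:
    def test_all_variants_below_strictest_threshold(self):
        # one het carrier among 5,000 pooled: MAF 1e-4 < 0.0005 everywhere
        inds = [(f"i{k}", "case" if k < 2500 else "control") for k in range(5000)]
        cohort = make_cohort(inds, [("v", 9, "missense")], [("i0", "v", 1)])
        res = vt_scan(cohort, BurdenConfig())
        tables = {r.table.as_tuple() for r in res.per_threshold}
        assert len(tables) == 1
        assert res.min_p == res.per_threshold[0].fisher_p
        assert res.min_p_threshold == 0.005  # tie broken toward widest

    def test_variant_straddling_thresholds(self):
        """A control-enriched variant at pooled MAF 0.003 qualifies at 0.005
        only; the per-threshold tables therefore differ."""
        n = 1000  # 2N = 2000; 6 copies -> MAF 0.003
        inds = [(f"i{k}", "case" if k < 500 else "control") for k in range(n)]
        gts = [(f"i{900 + j}", "common", 1) for j in range(6)]
        gts += [("i0", "rare", 1)]  # case singleton, MAF 5e-4 < 0.001
        cohort = make_cohort(
            inds, [("common", 10, "missense"), ("rare", 20, "missense")], gts
        )
        res = vt_scan(cohort, BurdenConfig())
        by_t = {r.threshold: r for r in res.per_threshold}
        assert by_t[0.005].n_qualifying == 2
        assert by_t[0.001].n_qualifying == 1
        assert by_t[0.0005].n_qualifying == 0
        assert by_t[0.005].table.c == 6
        assert by_t[0.001].table.as_tuple() == (1, 499, 0, 500)
        assert by_t[0.0005].fisher_p == 1.0

    def test_zero_carriers_min_p_one(self):
        inds = [("a", "case"), ("b", "control")]
        cohort = make_cohort(inds, [("v", 1, "missense")], [])
        res = vt_scan(cohort, BurdenConfig())
        assert res.min_p == 1.0

    def test_min_p_bounded_by_each_threshold(self):
        cohort = simulate_cohort(
            SimConfig(n_cases=300, n_controls=300, n_sites=10, seed=5,
                      maf_spectrum=FixedMaf(0.003), odds_ratio=3.0)
        )
        res = vt_scan(cohort, BurdenConfig())
        for row in res.per_threshold:
            assert res.min_p <= row.fisher_p


class TestMerge:
    def test_published_sizes(self, study_cohort):
        merged = merge_cohorts(study_cohort, replication_like_cohort(seed=2))
        assert merged.n_cases == 2339
        assert merged.n_controls == 2653

    def test_merge_with_empty_is_identity(self, toy_cohort):
        from burdenvt import Cohort

        empty = Cohort([], [], [])
        assert merge_cohorts(toy_cohort, empty) == toy_cohort

    def test_merged_maf_is_recomputed_on_union(self):
        """Shared variant: merged pooled MAF = combined copies over combined 2N."""
        a = make_cohort(
            [(f"a{k}", "case" if k < 4 else "control") for k in range(8)],
            [("v", 5, "missense")], [("a0", "v", 1)],
        )
        b = make_cohort(
            [(f"b{k}", "case" if k < 6 else "control") for k in range(12)],
            [("v", 5, "missense")], [("b1", "v", 2)],
        )
        merged = merge_cohorts(a, b)
        assert compute_sample_maf(merged, "v") == 3 / 40
        assert compute_sample_maf(a, "v") == 1 / 16

    def test_id_collision_rejected(self, toy_cohort):
        with pytest.raises(MergeError, match="collision"):
            merge_cohorts(toy_cohort, toy_cohort)

    def test_conflicting_annotation_rejected(self, toy_cohort):
        other = make_cohort(
            [("z1", "case"), ("z2", "control")],
            [("m1", 999, "missense")],  # same id, different position
            [],
        )
        with pytest.raises(MergeError, match="m1"):
            merge_cohorts(toy_cohort, other)


class TestRunAnalysis:
    CONFIG = BurdenConfig(n_permutations=50, seed=3)

    def test_single_plan_cell(self, study_cohort):
        plan = AnalysisPlan(burden=self.CONFIG)
        report = run_analysis(study_cohort, [plan])
        assert set(report) == {"original/all/whole_gene/dominant"}
        result = report[plan.key()]
        assert result.adjusted_p is not None
        assert result.per_threshold[0].table.a == 45

    def test_normal_weight_cell_shrinks_controls(self, study_cohort):
        plan = AnalysisPlan(
            control_set=ControlSubset.NORMAL_WEIGHT, burden=self.CONFIG
        )
        result = run_analysis(study_cohort, [plan])[plan.key()]
        table = result.per_threshold[0].table
        assert table.c + table.d == 1353
        assert table.a == 45

    def test_region_cell_uses_annotation(self, study_cohort):
        regions = {"kinase": RegionAnnotation("kinase", 634, 938)}
        plan = AnalysisPlan(
            region="kinase", control_set=ControlSubset.NORMAL_WEIGHT,
            burden=self.CONFIG,
        )
        result = run_analysis(study_cohort, [plan], regions)[plan.key()]
        assert result.per_threshold[0].table.as_tuple() == (17, 2084, 3, 1350)

    def test_dominant_carriers_bounded_by_additive_alleles(self):
        for seed in range(3):
            cohort = simulate_cohort(
                SimConfig(n_cases=150, n_controls=150, n_sites=8, seed=seed,
                          maf_spectrum=FixedMaf(0.004), odds_ratio=2.0)
            )
            plans = [
                AnalysisPlan(model=m, burden=self.CONFIG)
                for m in (GeneticModel.DOMINANT, GeneticModel.ADDITIVE)
            ]
            report = run_analysis(cohort, plans)
            dom = report["original/all/whole_gene/dominant"]
            add = report["original/all/whole_gene/additive"]
            for rd, ra in zip(dom.per_threshold, add.per_threshold):
                assert rd.table.a <= ra.table.a

    def test_combined_requires_both_labels(self, toy_cohort):
        plan = AnalysisPlan(sample=SampleChoice.COMBINED, burden=self.CONFIG)
        with pytest.raises(ConfigError, match="both cohort labels"):
            run_analysis(toy_cohort, [plan])

    def test_unknown_region_rejected(self, toy_cohort):
        plan = AnalysisPlan(region="nope", burden=self.CONFIG)
        with pytest.raises(ConfigError, match="nope"):
            run_analysis(toy_cohort, [plan])
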