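import dataclasses
import math

import numpy as np
import pytest

from burdenvt import (
    BurdenConfig,
    QualificationRule,
    carrier_table,
    qualify_variants,
    read_variant_table,
    write_variant_table,
)
from burdenvt.errors import ConfigError
from burdenvt.filters import sample_maf_vector
from burdenvt.model import FuncClass, Status
from burdenvt.simulate import (
    FixedMaf,
    PointMixtureMaf,
    SimConfig,
    UniformMaf,
    calibration_study,
    enriched_maf,
    ksr2_example_cohort,
    simulate_cohort,
)


def case_allele_freq(cohort):
    case = cohort.case_mask()
    return cohort.genotype_matrix()[:, case].sum() / (2 * case.sum())


def test_null_odds_ratio_gives_equal_frequencies():
    """At OR = 1 the mean case allele frequency matches the baseline MAF."""
    q, n, reps = 0.01, 500, 200
    freqs = [
        case_allele_freq(
            simulate_cohort(
                SimConfig(n_cases=n, n_controls=n, n_sites=1,
                          maf_spectrum=FixedMaf(q), odds_ratio=1.0, seed=s)
            )
        )
        for s in range(reps)
    ]
    se = math.sqrt(q * (1 - q) / (2 * n * reps))
    assert abs(np.mean(freqs) - q) <= 3 * se


def test_hwe_control_carrier_count():
    """q = 0.001, 1,000 controls: expected carriers/site = 1000(1 - 0.999^2)."""
    q, n_ctrl, reps = 0.001, 1000, 1000
    p_carrier = 1 - (1 - q) ** 2
    rng = np.random.default_rng(0)
    # replicate the generative law directly: carriers are Binomial(2, q) > 0
    counts = []
    for s in range(reps):
        cohort = simulate_cohort(
            SimConfig(n_cases=1, n_controls=n_ctrl, n_sites=1,
                      maf_spectrum=FixedMaf(q), odds_ratio=1.0, seed=s)
        )
        ctrl = ~cohort.case_mask()
        counts.append((cohort.genotype_matrix()[:, ctrl] > 0).sum())
    expected = n_ctrl * p_carrier
    se = math.sqrt(n_ctrl * p_carrier * (1 - p_carrier) / reps)
    assert expected == pytest.approx(1.999, abs=1e-3)
    assert abs(np.mean(counts) - expected) <= 3 * se


def test_fixed_seed_is_bit_identical(tmp_path):
    cfg = SimConfig(n_cases=60, n_controls=60, n_sites=8, seed=123)
    write_variant_table(simulate_cohort(cfg), tmp_path / "a.tsv")
    write_variant_table(simulate_cohort(cfg), tmp_path / "b.tsv")
    assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()


def test_enrichment_solves_odds_equation():
    q = 0.01
    for orr in (1.0, 2.0, 8.0):
        qp = enriched_maf(q, orr)
        assert qp / (1 - qp) == pytest.approx(orr * q / (1 - q), rel=1e-12)
    with pytest.raises(ConfigError, match=">= 0.5"):
        enriched_maf(0.2, 4.0)


def test_pooled_maf_converges_to_target():
    """Consistency: at n = 50,000 the sample MAF sits within 3 SE of q."""
    q, n = 0.002, 50_000
    cohort = simulate_cohort(
        SimConfig(n_cases=n // 2, n_controls=n // 2, n_sites=2,
                  maf_spectrum=FixedMaf(q), odds_ratio=1.0, seed=17)
    )
    mafs = sample_maf_vector(cohort, np.ones(n, dtype=bool))
    se = math.sqrt(q * (1 - q) / (2 * n))
    assert np.all(np.abs(mafs - q) <= 3 * se)


def test_simulator_output_round_trips(tmp_path):
    cohort = simulate_cohort(SimConfig(n_cases=30, n_controls=30, n_sites=4, seed=3))
    write_variant_table(cohort, tmp_path / "sim")
    assert read_variant_table(tmp_path / "sim") == cohort


class TestStudyFixture:
    def test_marginal_counts_exact(self, study_cohort):
        assert study_cohort.n_cases == 2101
        assert study_cohort.n_controls == 1536
        rule = QualificationRule(maf_threshold=0.005)
        q = qualify_variants(study_cohort, rule)
        t = carrier_table(study_cohort, q)
        assert (t.a, t.c) == (45, 16)
        case_ids = {
            i.individual_id for i in study_cohort.individuals if i.status is Status.CASE
        }
        case_vars = {
            g.variant_id for g in study_cohort.genotypes
            if g.individual_id in case_ids and g.variant_id in q
        }
        ctrl_vars = {
            g.variant_id for g in study_cohort.genotypes
            if g.individual_id not in case_ids and g.variant_id in q
        }
        assert len(case_vars) == 27
        assert len(ctrl_vars) == 7

    def test_compound_carriers_present(self, study_cohort):
        per_ind = {}
        for g in study_cohort.genotypes:
            per_ind.setdefault(g.individual_id, []).append(g)
        hom_double = [
            k for k, gs in per_ind.items()
            if len(gs) == 2 and all(g.allele_count == 2 for g in gs)
        ]
        het_double = [
            k for k, gs in per_ind.items()
            if len(gs) == 2 and all(g.allele_count == 1 for g in gs)
        ]
        assert len(hom_double) >= 1
        assert len(het_double) >= 1

    def test_all_qualifying_mafs_below_half_percent(self, study_cohort):
        mafs = sample_maf_vector(
            study_cohort, np.ones(study_cohort.n_individuals, dtype=bool)
        )
        disruptive = np.array(
            [v.func_class is not FuncClass.SYNONYMOUS for v in study_cohort.variants]
        )
        assert np.all(mafs[disruptive] < 0.005)

    def test_round_trips_through_io(self, study_cohort, tmp_path):
        write_variant_table(study_cohort, tmp_path / "fixture.tsv")
        assert read_variant_table(tmp_path / "fixture.tsv") == study_cohort

    def test_deterministic_rebuild(self, study_cohort):
        assert ksr2_example_cohort() == study_cohort


class TestCalibrationStudy:
    def test_single_rep_degenerate_ci(self):
        sim = SimConfig(n_cases=20, n_controls=20, n_sites=2,
                        maf_spectrum=FixedMaf(0.05))
        burden = BurdenConfig(
            thresholds=(0.2, 0.1), n_permutations=20,
            rule_template=QualificationRule(maf_threshold=0.2),
        )
        table = calibration_study([sim], burden, n_reps=1, seed=0)
        assert set(table.n_reject.unique()) <= {0, 1}
        assert len(table) == 2  # two alphas
        assert ((table.ci_low <= table.rejection_rate)
                & (table.rejection_rate <= table.ci_high)).all()

    def test_deterministic_given_master_seed(self):
        sim = SimConfig(n_cases=30, n_controls=30, n_sites=3,
                        maf_spectrum=FixedMaf(0.05))
        burden = BurdenConfig(
            thresholds=(0.2, 0.1), n_permutations=30,
            rule_template=QualificationRule(maf_threshold=0.2),
        )
        t1 = calibration_study([sim], burden, n_reps=5, seed=4)
        t2 = calibration_study([sim], burden, n_reps=5, seed=4)
        assert t1.equals(t2)

    def test_empty_grid_rejected(self):
        with pytest.raises(ConfigError):
            calibration_study([], BurdenConfig(), n_reps=5)


def test_spectrum_validation():
    with pytest.raises(ConfigError):
        FixedMaf(0.6).draw(np.random.default_rng(0), 3)
    with pytest.raises(ConfigError):
        UniformMaf(0.01, 0.01).draw(np.random.default_rng(0), 3)
    draws = PointMixtureMaf(((0.001, 1.0),)).draw(np.random.default_rng(0), 5)
    assert np.all(draws == 0.001)


def test_class_probs_must_sum_to_one():
    with pytest.raises(ConfigError, match="sum to 1"):
        SimConfig(class_probs={FuncClass.MISSENSE: 0.5})
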