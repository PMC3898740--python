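import dataclasses
import math

import numpy as np
import pytest

from burdenvt import (
    BurdenConfig,
    MafReference,
    QualificationRule,
    exact_permutation_p,
    permutation_adjusted_p,
)
from burdenvt.errors import ConfigError
from burdenvt.simulate import FixedMaf, SimConfig, simulate_cohort
from tests.conftest import make_cohort

#: For tiny cohorts the default MAF ladder excludes everything (a singleton
#: among 8 people has MAF 1/16); use a ladder matched to that scale.
TINY = BurdenConfig(
    thresholds=(0.5, 0.3, 0.2), n_permutations=2000, seed=0,
    rule_template=QualificationRule(maf_threshold=0.5),
)


def enriched_tiny_cohort():
    """4 cases / 4 controls, 2 variants, all qualifying copies in cases."""
    return make_cohort(
        [(f"ca{i}", "case") for i in range(4)] + [(f"co{i}", "control") for i in range(4)],
        [("v1", 10, "missense"), ("v2", 20, "missense")],
        [("ca0", "v1", 1), ("ca1", "v1", 1), ("ca2", "v1", 2), ("ca3", "v2", 1)],
    )


def test_extreme_enrichment_hits_floor():
    """When no permutation beats the observed min-p, adjusted_p = 1/(B+1)."""
    cohort = enriched_tiny_cohort()
    res = permutation_adjusted_p(cohort, dataclasses.replace(TINY, n_permutations=100))
    # every carrier is a case: only the identity split and its mirror image
    # (all carriers relabeled controls, same two-sided table) tie the observed
    assert res.adjusted_p >= 1 / 101
    obs, exact = exact_permutation_p(cohort, TINY)
    assert exact == pytest.approx(2 / math.comb(8, 4))


def test_no_carriers_everything_is_one(toy_cohort):
    cohort = make_cohort(
        [("a", "case"), ("b", "case"), ("c", "control"), ("d", "control")],
        [("v", 1, "missense")],
        [],
    )
    res = permutation_adjusted_p(cohort, dataclasses.replace(TINY, n_permutations=50))
    assert res.min_p == 1.0
    assert res.adjusted_p == 1.0


def test_monte_carlo_matches_exhaustive_enumeration():
    """MC adjusted_p agrees with full enumeration of all C(8,4)=70 splits."""
    cohort = make_cohort(
        [(f"ca{i}", "case") for i in range(4)] + [(f"co{i}", "control") for i in range(4)],
        [("v1", 10, "missense"), ("v2", 20, "missense")],
        [("ca0", "v1", 1), ("ca1", "v1", 1), ("co0", "v2", 1), ("ca2", "v2", 1)],
    )
    B = 20_000
    obs, exact = exact_permutation_p(cohort, TINY)
    mc = permutation_adjusted_p(cohort, dataclasses.replace(TINY, n_permutations=B))
    se = math.sqrt(exact * (1 - exact) / B)
    assert abs(mc.adjusted_p - exact) <= 3 * se + 1 / (B + 1)


def test_adjusted_p_bounds_and_seed_determinism():
    cohort = simulate_cohort(
        SimConfig(n_cases=100, n_controls=100, n_sites=5, seed=9,
                  maf_spectrum=FixedMaf(0.01), odds_ratio=2.0)
    )
    cfg = BurdenConfig(
        thresholds=(0.05, 0.02, 0.01), n_permutations=500, seed=42,
        rule_template=QualificationRule(maf_threshold=0.05),
    )
    r1 = permutation_adjusted_p(cohort, cfg)
    r2 = permutation_adjusted_p(cohort, cfg)
    assert 1 / 501 <= r1.adjusted_p <= 1.0
    assert r1.adjusted_p == r2.adjusted_p  # bit-identical given the seed
    assert r1.min_p == min(row.fisher_p for row in r1.per_threshold)


def test_different_seeds_agree_within_binomial_error():
    cohort = simulate_cohort(
        SimConfig(n_cases=100, n_controls=100, n_sites=5, seed=9,
                  maf_spectrum=FixedMaf(0.01), odds_ratio=2.0)
    )
    B = 2000
    cfg = BurdenConfig(
        thresholds=(0.05, 0.02, 0.01), n_permutations=B,
        rule_template=QualificationRule(maf_threshold=0.05),
    )
    ps = [
        permutation_adjusted_p(cohort, dataclasses.replace(cfg, seed=s)).adjusted_p
        for s in (1, 2)
    ]
    p_bar = float(np.mean(ps))
    se = math.sqrt(p_bar * (1 - p_bar) / B)
    assert abs(ps[0] - ps[1]) <= 3 * math.sqrt(2) * se + 2 / (B + 1)


def test_controls_only_reference_requalifies_per_permutation():
    """The slow path (controls-only MAF) runs, is deterministic, and returns
    a valid p; with all copies in cases, controls-only MAF is 0 at every
    site, so everything qualifies and enrichment is still detected."""
    cohort = enriched_tiny_cohort()
    cfg = dataclasses.replace(
        TINY,
        n_permutations=400,
        rule_template=QualificationRule(
            maf_threshold=0.5, maf_reference=MafReference.CONTROLS_ONLY
        ),
    )
    r1 = permutation_adjusted_p(cohort, cfg)
    r2 = permutation_adjusted_p(cohort, cfg)
    assert r1.adjusted_p == r2.adjusted_p
    assert 1 / 401 <= r1.adjusted_p <= 1.0
    with pytest.raises(ConfigError, match="pooled"):
        exact_permutation_p(cohort, cfg)
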