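"""Burden collapsing, variable-threshold min-p scan, and permutation adjustment.

The test collapses qualifying rare variants into a single 2x2 table per MAF
threshold and applies an exact Fisher test.  Because the best threshold is
chosen after seeing the data ("min-p" over the threshold ladder), the
nominal minimum p-value is optimistically biased; the adjusted p-value is
obtained by re-running the entire threshold scan under random case/control
relabelings and asking how often a permuted scan does at least as well.

Under the pooled MAF reference, sample allele frequencies do not change when
status labels are permuted, so the per-threshold qualifying sets — and hence
the table margins — are fixed across permutations.  Each permutation then
reduces to re-counting carrier units among the permuted cases and looking the
p-value up in a precomputed per-threshold table, which keeps 10,000
permutations on a multi-thousand-individual cohort fast.
"""

from __future__ import annotations

import enum
import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigError, DegenerateInputError, MergeError
from .fisher import fisher_exact_two_sided, fisher_p_all
from .filters import MafReference, QualificationRule, qualify_mask, sample_maf_vector
from .model import Cohort, CohortLabel, DEFAULT_OBESITY_BMI_CUTOFF, RegionAnnotation

DEFAULT_MAF_THRESHOLDS = (0.005, 0.001, 0.0005)
DEFAULT_N_PERMUTATIONS = 10_000


class GeneticModel(str, enum.Enum):
    """DOMINANT counts carrier individuals once each; ADDITIVE counts alleles."""

    DOMINANT = "dominant"
    ADDITIVE = "additive"


class ControlSubset(str, enum.Enum):
    ALL = "all"
    NORMAL_WEIGHT = "normal_weight"


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Case/control x carrier/non-carrier units.

    Units are individuals under the dominant model and alleles under the
    additive model; a + b is the case margin, c + d the control margin.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name, cell in zip("abcd", (self.a, self.b, self.c, self.d)):
            if int(cell) < 0:
                raise DegenerateInputError(f"2x2 cell {name} is negative: {cell}")
            object.__setattr__(self, name, int(cell))

    @property
    def case_units(self) -> int:
        return self.a + self.b

    @property
    def control_units(self) -> int:
        return self.c + self.d

    def fisher_p(self) -> float:
        return fisher_exact_two_sided(self.a, self.b, self.c, self.d)

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class BurdenConfig:
    """Full specification of one burden analysis."""

    thresholds: tuple[float, ...] = DEFAULT_MAF_THRESHOLDS
    model: GeneticModel = GeneticModel.DOMINANT
    rule_template: QualificationRule = field(default_factory=QualificationRule)
    n_permutations: int = DEFAULT_N_PERMUTATIONS
    seed: int = 0
    control_subset: ControlSubset = ControlSubset.ALL
    bmi_cutoff: float = DEFAULT_OBESITY_BMI_CUTOFF

    def __post_init__(self) -> None:
        thresholds = tuple(float(t) for t in self.thresholds)
        if not thresholds:
            raise ConfigError("thresholds must be non-empty")
        if any(not (0.0 < t <= 0.5) for t in thresholds):
            raise ConfigError(f"thresholds must lie in (0, 0.5]: {thresholds}")
        if any(t2 >= t1 for t1, t2 in zip(thresholds, thresholds[1:])):
            raise ConfigError(f"thresholds must be strictly decreasing: {thresholds}")
        object.__setattr__(self, "thresholds", thresholds)
        if int(self.n_permutations) < 1:
            raise ConfigError("n_permutations must be >= 1")
        object.__setattr__(self, "n_permutations", int(self.n_permutations))
        object.__setattr__(self, "model", GeneticModel(self.model))
        object.__setattr__(self, "control_subset", ControlSubset(self.control_subset))

    def rule_at(self, threshold: float) -> QualificationRule:
        return self.rule_template.with_threshold(threshold)


@dataclass(frozen=True)
class PerThresholdResult:
    threshold: float
    n_qualifying: int
    table: ContingencyTable2x2
    fisher_p: float

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "n_qualifying": self.n_qualifying,
            "table": {"a": self.table.a, "b": self.table.b,
                      "c": self.table.c, "d": self.table.d},
            "fisher_p": self.fisher_p,
        }


@dataclass(frozen=True)
class BurdenResult:
    per_threshold: tuple[PerThresholdResult, ...]
    min_p: float
    min_p_threshold: float
    adjusted_p: Optional[float]
    n_permutations_used: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "per_threshold": [r.to_dict() for r in self.per_threshold],
            "min_p": self.min_p,
            "min_p_threshold": self.min_p_threshold,
            "adjusted_p": self.adjusted_p,
            "n_permutations_used": self.n_permutations_used,
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# collapsing


def _unit_vector(cohort: Cohort, qualifying_mask: np.ndarray, model: GeneticModel) -> np.ndarray:
    """Per-individual carrier units for the qualifying variants.

    Dominant: 1 if the individual carries >= 1 qualifying allele (multiple
    qualifying variants or homozygosity still count once).  Additive: total
    qualifying allele count (het contributes 1, hom 2, summed over variants).
    """
    gt = cohort.genotype_matrix()[qualifying_mask, :]
    if model is GeneticModel.DOMINANT:
        return (gt.sum(axis=0, dtype=np.int64) > 0).astype(np.int64)
    return gt.sum(axis=0, dtype=np.int64)


def _margins(cohort: Cohort, model: GeneticModel) -> tuple[int, int]:
    """(case units, control units) for the table margins under the model."""
    if model is GeneticModel.DOMINANT:
        return cohort.n_cases, cohort.n_controls
    return 2 * cohort.n_cases, 2 * cohort.n_controls


def carrier_table(
    cohort: Cohort,
    qualifying: set[str],
    model: GeneticModel = GeneticModel.DOMINANT,
    control_subset: ControlSubset = ControlSubset.ALL,
    bmi_cutoff: float = DEFAULT_OBESITY_BMI_CUTOFF,
) -> ContingencyTable2x2:
    """Collapse the qualifying variants of a cohort into a 2x2 table."""
    model = GeneticModel(model)
    if ControlSubset(control_subset) is ControlSubset.NORMAL_WEIGHT:
        cohort = cohort.normal_weight_control_subset(bmi_cutoff)
    if cohort.n_cases == 0 or cohort.n_controls == 0:
        raise DegenerateInputError(
            f"need >= 1 case and >= 1 control, got {cohort.n_cases}/{cohort.n_controls}"
        )
    unknown = qualifying - set(cohort.variant_ids)
    if unknown:
        raise ConfigError(f"qualifying set names unknown variants: {sorted(unknown)[:5]}")
    qmask = np.array([v.variant_id in qualifying for v in cohort.variants], dtype=bool)
    units = _unit_vector(cohort, qmask, model)
    case = cohort.case_mask()
    a = int(units[case].sum())
    c = int(units[~case].sum())
    case_units, ctrl_units = _margins(cohort, model)
    return ContingencyTable2x2(a, case_units - a, c, ctrl_units - c)


# ---------------------------------------------------------------------------
# the variable-threshold scan


def _analysis_cohort(cohort: Cohort, config: BurdenConfig) -> Cohort:
    if config.control_subset is ControlSubset.NORMAL_WEIGHT:
        cohort = cohort.normal_weight_control_subset(config.bmi_cutoff)
    if cohort.n_cases == 0 or cohort.n_controls == 0:
        raise DegenerateInputError(
            f"need >= 1 case and >= 1 control in analyzed set, "
            f"got {cohort.n_cases}/{cohort.n_controls}"
        )
    return cohort


def _scan_units(cohort: Cohort, config: BurdenConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-threshold qualifying masks and carrier-unit matrix (T x N)."""
    masks = np.stack(
        [qualify_mask(cohort, config.rule_at(t)) for t in config.thresholds]
    )
    units = np.stack(
        [_unit_vector(cohort, m, config.model) for m in masks]
    )
    return masks, units


def _scan_from_units(
    cohort: Cohort, config: BurdenConfig, masks: np.ndarray, units: np.ndarray
) -> BurdenResult:
    case = cohort.case_mask()
    case_units, ctrl_units = _margins(cohort, config.model)
    rows = []
    for t, m, u in zip(config.thresholds, masks, units):
        a = int(u[case].sum())
        c = int(u[~case].sum())
        table = ContingencyTable2x2(a, case_units - a, c, ctrl_units - c)
        rows.append(
            PerThresholdResult(t, int(m.sum()), table, table.fisher_p())
        )
    pvals = [r.fisher_p for r in rows]
    best = int(np.argmin(pvals))  # ties break toward the largest (first) threshold
    return BurdenResult(
        per_threshold=tuple(rows),
        min_p=pvals[best],
        min_p_threshold=config.thresholds[best],
        adjusted_p=None,
        n_permutations_used=0,
        seed=config.seed,
    )


def vt_scan(cohort: Cohort, config: BurdenConfig) -> BurdenResult:
    """Per-threshold Fisher tests and the min-p statistic (no adjustment)."""
    cohort = _analysis_cohort(cohort, config)
    masks, units = _scan_units(cohort, config)
    return _scan_from_units(cohort, config, masks, units)


# ---------------------------------------------------------------------------
# permutation adjustment


def _pooled_lookups(
    cohort: Cohort, config: BurdenConfig, units: np.ndarray
) -> tuple[list[np.ndarray], list[int]]:
    """Per-threshold p-value lookup arrays indexed by (a - a_min).

    Valid only under the pooled MAF reference, where the carrier-unit margin
    K_t is permutation-invariant.
    """
    case_units, ctrl_units = _margins(cohort, config.model)
    lookups, a_mins = [], []
    for u in units:
        k = int(u.sum())
        lookups.append(fisher_p_all(case_units, ctrl_units, k))
        a_mins.append(max(0, k - ctrl_units))
    return lookups, a_mins


def _min_p_for_case_idx(
    units: np.ndarray, case_idx: np.ndarray, lookups: list[np.ndarray], a_mins: list[int]
) -> float:
    best = 1.0
    for u, lk, amin in zip(units, lookups, a_mins):
        a = int(u[case_idx].sum())
        p = lk[a - amin]
        if p < best:
            best = float(p)
    return best


def permutation_adjusted_p(cohort: Cohort, config: BurdenConfig) -> BurdenResult:
    """Min-p statistic with its permutation-based multiplicity adjustment.

    Status labels are shuffled uniformly at random within the analyzed
    individual set, preserving the case/control counts; the full threshold
    scan is recomputed per permutation and

        adjusted_p = (1 + #{permuted min_p <= observed min_p}) / (1 + B).

    The observed statistic is included (the +1 correction), which guarantees
    validity and a floor of 1/(B+1).  Ties count as extreme.  The RNG is
    fully determined by ``config.seed``.
    """
    cohort = _analysis_cohort(cohort, config)
    rng = np.random.default_rng(config.seed)
    B = config.n_permutations
    n = cohort.n_individuals
    n_cases = cohort.n_cases

    if config.rule_template.maf_reference is MafReference.POOLED:
        masks, units = _scan_units(cohort, config)
        observed = _scan_from_units(cohort, config, masks, units)
        lookups, a_mins = _pooled_lookups(cohort, config, units)
        r = 0
        for _ in range(B):
            case_idx = rng.permutation(n)[:n_cases]
            if _min_p_for_case_idx(units, case_idx, lookups, a_mins) <= observed.min_p:
                r += 1
    else:
        observed = vt_scan(cohort, config)
        r = 0
        for _ in range(B):
            perm = rng.permutation(n)
            case_mask = np.zeros(n, dtype=bool)
            case_mask[perm[:n_cases]] = True
            if _permuted_min_p_controls_only(cohort, config, case_mask) <= observed.min_p:
                r += 1

    adjusted = (1 + r) / (1 + B)
    return replace(observed, adjusted_p=adjusted, n_permutations_used=B)


def _permuted_min_p_controls_only(
    cohort: Cohort, config: BurdenConfig, case_mask: np.ndarray
) -> float:
    """Full re-qualification scan for one permuted labeling (controls-only MAF)."""
    gt = cohort.genotype_matrix()
    mafs = sample_maf_vector(cohort, ~case_mask)
    class_region_ok = np.ones(len(cohort.variants), dtype=bool)
    rule = config.rule_template
    class_region_ok &= np.array(
        [v.func_class in rule.classes_included for v in cohort.variants]
    )
    if rule.region is not None:
        class_region_ok &= np.array(
            [rule.region.contains(v.protein_pos) for v in cohort.variants]
        )
    n_cases = int(case_mask.sum())
    n_ctrl = len(case_mask) - n_cases
    case_units, ctrl_units = (
        (n_cases, n_ctrl)
        if config.model is GeneticModel.DOMINANT
        else (2 * n_cases, 2 * n_ctrl)
    )
    best = 1.0
    for t in config.thresholds:
        qmask = class_region_ok & (mafs < t)
        u = _unit_vector(cohort, qmask, config.model)
        a = int(u[case_mask].sum())
        c = int(u[~case_mask].sum())
        p = fisher_exact_two_sided(a, case_units - a, c, ctrl_units - c)
        best = min(best, p)
    return best


def exact_permutation_p(cohort: Cohort, config: BurdenConfig) -> tuple[BurdenResult, float]:
    """Exhaustive-enumeration version of the permutation adjustment.

    Enumerates every case/control label assignment with the observed margin
    (all C(n, n_cases) of them) and returns the exact fraction whose min-p is
    <= the observed min-p, alongside the observed scan.  Only feasible for
    tiny cohorts; intended for validating the Monte-Carlo estimator.
    Requires the pooled MAF reference (qualification is label-invariant).
    """
    cohort = _analysis_cohort(cohort, config)
    if config.rule_template.maf_reference is not MafReference.POOLED:
        raise ConfigError("exact enumeration requires the pooled MAF reference")
    n, n_cases = cohort.n_individuals, cohort.n_cases
    n_assignments = math.comb(n, n_cases)
    if n_assignments > 2_000_000:
        raise ConfigError(
            f"C({n},{n_cases}) = {n_assignments} label assignments is too many "
            "to enumerate; use permutation_adjusted_p"
        )
    masks, units = _scan_units(cohort, config)
    observed = _scan_from_units(cohort, config, masks, units)
    lookups, a_mins = _pooled_lookups(cohort, config, units)
    hits = 0
    for combo in itertools.combinations(range(n), n_cases):
        idx = np.array(combo)
        if _min_p_for_case_idx(units, idx, lookups, a_mins) <= observed.min_p:
            hits += 1
    return observed, hits / n_assignments


# ---------------------------------------------------------------------------
# merging and analysis plans


def merge_cohorts(a: Cohort, b: Cohort) -> Cohort:
    """Union of two cohorts with disjoint individuals and reconciled variants.

    Variants present in both must agree on protein position and functional
    class.  Any sample MAF must afterwards be recomputed on the merged
    sample — callers get this for free because qualification always computes
    MAF from the cohort it is handed.
    """
    overlap = set(a.individual_ids) & set(b.individual_ids)
    if overlap:
        raise MergeError(f"individual id collision: {sorted(overlap)[:5]}")
    variants = list(a.variants)
    known = {v.variant_id: v for v in variants}
    for v in b.variants:
        prev = known.get(v.variant_id)
        if prev is None:
            variants.append(v)
            known[v.variant_id] = v
        elif (prev.protein_pos, prev.func_class) != (v.protein_pos, v.func_class):
            raise MergeError(
                f"variant {v.variant_id!r} annotated inconsistently: "
                f"({prev.protein_pos}, {prev.func_class.value}) vs "
                f"({v.protein_pos}, {v.func_class.value})"
            )
    return Cohort(
        list(a.individuals) + list(b.individuals),
        variants,
        list(a.genotypes) + list(b.genotypes),
    )


class SampleChoice(str, enum.Enum):
    ORIGINAL = "original"
    REPLICATION = "replication"
    COMBINED = "combined"


@dataclass(frozen=True)
class AnalysisPlan:
    """One cell of the analysis grid: sample x control set x scope x model."""

    sample: SampleChoice = SampleChoice.ORIGINAL
    control_set: ControlSubset = ControlSubset.ALL
    region: Optional[str] = None  # None = whole gene; else a region_name
    model: GeneticModel = GeneticModel.DOMINANT
    burden: BurdenConfig = field(default_factory=BurdenConfig)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample", SampleChoice(self.sample))
        object.__setattr__(self, "control_set", ControlSubset(self.control_set))
        object.__setattr__(self, "model", GeneticModel(self.model))

    def key(self) -> str:
        scope = self.region if self.region else "whole_gene"
        return "/".join(
            (self.sample.value, self.control_set.value, scope, self.model.value)
        )


def _plan_config(plan: AnalysisPlan, regions: dict[str, RegionAnnotation]) -> BurdenConfig:
    rule = plan.burden.rule_template
    if plan.region is not None:
        if plan.region not in regions:
            raise ConfigError(f"plan names unknown region {plan.region!r}")
        rule = replace(rule, region=regions[plan.region])
    return replace(
        plan.burden,
        model=plan.model,
        control_subset=plan.control_set,
        rule_template=rule,
    )


def select_sample(cohort: Cohort, sample: SampleChoice) -> Cohort:
    sample = SampleChoice(sample)
    labels = {i.cohort_label for i in cohort.individuals}
    if sample is SampleChoice.COMBINED:
        if len(labels) < 2:
            raise ConfigError(
                "combined analysis requires both cohort labels in the input, "
                f"found only {sorted(l.value for l in labels)}"
            )
        return cohort
    return cohort.select_label(CohortLabel(sample.value))


def run_analysis(
    cohort: Cohort,
    plans: Sequence[AnalysisPlan],
    regions: Optional[dict[str, RegionAnnotation]] = None,
) -> dict[str, BurdenResult]:
    """Run every requested plan cell; keys are 'sample/controls/scope/model'."""
    regions = regions or {}
    report: dict[str, BurdenResult] = {}
    for plan in plans:
        sub = select_sample(cohort, plan.sample)
        config = _plan_config(plan, regions)
        report[plan.key()] = permutation_adjusted_p(sub, config)
    return report
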