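"""Variant qualification: functional class, protein region, and sample-MAF filters.

A variant "qualifies" for a burden test when its functional class is in the
allowed set, its residue position falls inside the optional region, and its
minor-allele frequency — computed *in the analyzed sample* — is strictly
below the threshold.  Computing MAF in the analyzed sample (rather than in an
external reference panel) means the qualifying set is re-derived whenever a
sub-sample or merged sample is analyzed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import FrozenSet, Optional

import numpy as np

from .errors import ConfigError, DegenerateInputError
from .model import Cohort, DISRUPTIVE_CLASSES, FuncClass, RegionAnnotation


class MafReference(str, enum.Enum):
    """Which individuals define the sample allele frequency.

    POOLED (cases + controls of the analyzed sample) makes qualification
    invariant under case/control label permutation, so permutation tests can
    reuse the qualifying sets.  CONTROLS_ONLY follows the convention of using
    the unaffected arm as the frequency reference; under permutation the
    control arm changes, so qualification must be recomputed per permutation.
    """

    POOLED = "pooled"
    CONTROLS_ONLY = "controls_only"


@dataclass(frozen=True)
class QualificationRule:
    """Filter defining which variants enter a burden table."""

    classes_included: FrozenSet[FuncClass] = field(
        default_factory=lambda: frozenset(DISRUPTIVE_CLASSES)
    )
    region: Optional[RegionAnnotation] = None
    maf_threshold: float = 0.005
    maf_reference: MafReference = MafReference.POOLED

    def __post_init__(self) -> None:
        classes = frozenset(FuncClass(c) for c in self.classes_included)
        if not classes:
            raise ConfigError("classes_included must be non-empty")
        object.__setattr__(self, "classes_included", classes)
        if not (0.0 < self.maf_threshold <= 0.5):
            raise ConfigError(
                f"maf_threshold must lie in (0, 0.5], got {self.maf_threshold}"
            )
        object.__setattr__(self, "maf_reference", MafReference(self.maf_reference))

    def with_threshold(self, maf_threshold: float) -> "QualificationRule":
        return replace(self, maf_threshold=maf_threshold)


def sample_maf_vector(cohort: Cohort, reference_mask: np.ndarray) -> np.ndarray:
    """Per-variant alternate-allele frequency among the masked individuals.

    MAF of variant v = (sum of allele counts over reference individuals) /
    (2 x number of reference individuals).
    """
    n_ref = int(np.count_nonzero(reference_mask))
    if n_ref == 0:
        raise DegenerateInputError("MAF reference set is empty")
    counts = cohort.genotype_matrix()[:, reference_mask].sum(axis=1, dtype=np.int64)
    return counts / (2.0 * n_ref)


def reference_mask(cohort: Cohort, reference: MafReference) -> np.ndarray:
    reference = MafReference(reference)
    if reference is MafReference.POOLED:
        return np.ones(cohort.n_individuals, dtype=bool)
    mask = ~cohort.case_mask()
    if not mask.any():
        raise DegenerateInputError("controls_only MAF reference but cohort has no controls")
    return mask


def compute_sample_maf(
    cohort: Cohort,
    variant_id: str,
    reference: MafReference = MafReference.POOLED,
) -> float:
    """Sample MAF of one variant; see :func:`sample_maf_vector`."""
    idx = cohort._var_index.get(variant_id)
    if idx is None:
        cohort.variant(variant_id)  # raises LookupError_ with a clear message
    mafs = sample_maf_vector(cohort, reference_mask(cohort, reference))
    return float(mafs[idx])


def qualify_mask(cohort: Cohort, rule: QualificationRule) -> np.ndarray:
    """Boolean mask over cohort.variants of variants passing all three filters."""
    class_ok = np.array(
        [v.func_class in rule.classes_included for v in cohort.variants], dtype=bool
    )
    if rule.region is not None:
        region_ok = np.array(
            [rule.region.contains(v.protein_pos) for v in cohort.variants], dtype=bool
        )
    else:
        region_ok = np.ones(len(cohort.variants), dtype=bool)
    mafs = sample_maf_vector(cohort, reference_mask(cohort, rule.maf_reference))
    maf_ok = mafs < rule.maf_threshold  # strict: a variant AT the threshold is out
    return class_ok & region_ok & maf_ok


def qualify_variants(cohort: Cohort, rule: QualificationRule) -> set[str]:
    """Ids of variants passing class, region, and sample-MAF filters."""
    mask = qualify_mask(cohort, rule)
    return {v.variant_id for v, ok in zip(cohort.variants, mask) if ok}
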