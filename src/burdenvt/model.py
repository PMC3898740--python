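"""Core data model: variants, genotypes, individuals, cohorts, protein regions.

The analysis is protein-level: each variant is identified by a free-text token
(typically a protein-change label such as ``R684C``), carries a 1-based residue
position on the annotated isoform, and a functional class.  Genotypes are
sparse: an entry exists only for carriers, with allele_count 1 (heterozygous)
or 2 (homozygous alternate); absence means zero copies.  One individual may
hold entries for several variants (compound carriage), each possibly
homozygous.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import (
    DegenerateInputError,
    DuplicateEntryError,
    LookupError_,
    ParseError,
    ReferentialIntegrityError,
)


class FuncClass(str, enum.Enum):
    """Functional consequence class of a coding variant."""

    FRAMESHIFT = "frameshift"
    NONSENSE = "nonsense"
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


#: Classes conventionally treated as potentially protein-disrupting.
DISRUPTIVE_CLASSES = frozenset(
    {FuncClass.FRAMESHIFT, FuncClass.NONSENSE, FuncClass.MISSENSE}
)


class Status(str, enum.Enum):
    CASE = "case"
    CONTROL = "control"


class CohortLabel(str, enum.Enum):
    ORIGINAL = "original"
    REPLICATION = "replication"


class WeightClass(str, enum.Enum):
    NORMAL = "normal"
    OVERWEIGHT = "overweight"
    OBESE = "obese"


#: BMI (kg/m^2) above which an adult is conventionally classed as obese.
DEFAULT_OBESITY_BMI_CUTOFF = 30.0


@dataclass(frozen=True)
class VariantRecord:
    """One coding variant on the protein coordinate system."""

    variant_id: str
    protein_pos: int
    func_class: FuncClass
    notes: str = ""

    def __post_init__(self) -> None:
        if not self.variant_id:
            raise ParseError("variant_id must be a non-empty token")
        if int(self.protein_pos) < 1:
            raise ParseError(
                f"variant {self.variant_id!r}: protein_pos must be >= 1, "
                f"got {self.protein_pos}"
            )
        object.__setattr__(self, "protein_pos", int(self.protein_pos))
        object.__setattr__(self, "func_class", FuncClass(self.func_class))


@dataclass(frozen=True)
class GenotypeEntry:
    """Carriage of one variant by one individual (1 = het, 2 = hom alt)."""

    individual_id: str
    variant_id: str
    allele_count: int

    def __post_init__(self) -> None:
        if int(self.allele_count) not in (1, 2):
            raise ParseError(
                f"genotype ({self.individual_id}, {self.variant_id}): "
                f"allele_count must be 1 or 2, got {self.allele_count}"
            )
        object.__setattr__(self, "allele_count", int(self.allele_count))


def classify_bmi(bmi: Optional[float]) -> Optional[WeightClass]:
    """Conventional adult BMI classes: <25 normal, 25-30 overweight, >30 obese."""
    if bmi is None:
        return None
    if bmi > 30.0:
        return WeightClass.OBESE
    if bmi >= 25.0:
        return WeightClass.OVERWEIGHT
    return WeightClass.NORMAL


@dataclass(frozen=True)
class Individual:
    """A study participant with case/control status and cohort membership."""

    individual_id: str
    status: Status
    cohort_label: CohortLabel
    bmi: Optional[float] = None
    weight_class: Optional[WeightClass] = field(default=None)

    def __post_init__(self) -> None:
        if not self.individual_id:
            raise ParseError("individual_id must be a non-empty token")
        object.__setattr__(self, "status", Status(self.status))
        object.__setattr__(self, "cohort_label", CohortLabel(self.cohort_label))
        if self.bmi is not None:
            bmi = float(self.bmi)
            if bmi < 0:
                raise ParseError(
                    f"individual {self.individual_id!r}: bmi must be non-negative"
                )
            object.__setattr__(self, "bmi", bmi)
        if self.weight_class is None and self.bmi is not None:
            object.__setattr__(self, "weight_class", classify_bmi(self.bmi))
        elif self.weight_class is not None:
            object.__setattr__(self, "weight_class", WeightClass(self.weight_class))


@dataclass(frozen=True)
class RegionAnnotation:
    """A named protein region, 1-based inclusive residue interval."""

    region_name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        start, end = int(self.start), int(self.end)
        if not (1 <= start <= end):
            raise ParseError(
                f"region {self.region_name!r}: need 1 <= start <= end, "
                f"got [{start}, {end}]"
            )
        object.__setattr__(self, "start", start)
        object.__setattr__(self, "end", end)

    def contains(self, protein_pos: int) -> bool:
        return self.start <= protein_pos <= self.end


class Cohort:
    """Individuals, variants, and the sparse genotype entries linking them.

    Construction validates referential integrity (every genotype references
    an existing individual and variant), uniqueness of ids and of
    (individual, variant) pairs.  Individuals with no genotype entries are
    retained: they are the non-carriers that fill the 2x2 tables.
    """

    def __init__(
        self,
        individuals: Sequence[Individual],
        variants: Sequence[VariantRecord],
        genotypes: Sequence[GenotypeEntry],
    ) -> None:
        self.individuals = list(individuals)
        self.variants = list(variants)
        self.genotypes = list(genotypes)
        self._validate()
        self._matrix: Optional[np.ndarray] = None

    def _validate(self) -> None:
        ind_ids = [i.individual_id for i in self.individuals]
        var_ids = [v.variant_id for v in self.variants]
        if len(set(ind_ids)) != len(ind_ids):
            dup = _first_duplicate(ind_ids)
            raise DuplicateEntryError(f"duplicate individual_id {dup!r}")
        if len(set(var_ids)) != len(var_ids):
            dup = _first_duplicate(var_ids)
            raise DuplicateEntryError(f"duplicate variant_id {dup!r}")
        ind_set, var_set = set(ind_ids), set(var_ids)
        seen_pairs = set()
        for g in self.genotypes:
            if g.individual_id not in ind_set:
                raise ReferentialIntegrityError(
                    f"genotype references unknown individual {g.individual_id!r}"
                )
            if g.variant_id not in var_set:
                raise ReferentialIntegrityError(
                    f"genotype references unknown variant {g.variant_id!r}"
                )
            pair = (g.individual_id, g.variant_id)
            if pair in seen_pairs:
                raise DuplicateEntryError(f"duplicate genotype entry for {pair}")
            seen_pairs.add(pair)
        self._ind_index = {iid: k for k, iid in enumerate(ind_ids)}
        self._var_index = {vid: k for k, vid in enumerate(var_ids)}

    # -- basic accessors ---------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_cases(self) -> int:
        return int(np.count_nonzero(self.case_mask()))

    @property
    def n_controls(self) -> int:
        return self.n_individuals - self.n_cases

    @property
    def individual_ids(self) -> list[str]:
        return [i.individual_id for i in self.individuals]

    @property
    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]

    def variant(self, variant_id: str) -> VariantRecord:
        try:
            return self.variants[self._var_index[variant_id]]
        except KeyError:
            raise LookupError_(f"unknown variant {variant_id!r}") from None

    def case_mask(self) -> np.ndarray:
        """Boolean array over individuals, True for cases, in cohort order."""
        return np.array(
            [ind.status is Status.CASE for ind in self.individuals], dtype=bool
        )

    def genotype_matrix(self) -> np.ndarray:
        """Dense (n_variants, n_individuals) int8 allele-count matrix."""
        if self._matrix is None:
            mat = np.zeros((len(self.variants), len(self.individuals)), dtype=np.int8)
            for g in self.genotypes:
                mat[self._var_index[g.variant_id], self._ind_index[g.individual_id]] = (
                    g.allele_count
                )
            self._matrix = mat
        return self._matrix

    # -- derived sub-cohorts -----------------------------------------------

    def subset_individuals(self, keep: Iterable[str]) -> "Cohort":
        """New cohort restricted to the given individual ids (order preserved);
        genotype entries of dropped individuals are dropped, variants kept."""
        keep_set = set(keep)
        unknown = keep_set - set(self._ind_index)
        if unknown:
            raise LookupError_(f"unknown individual ids: {sorted(unknown)[:5]}")
        inds = [i for i in self.individuals if i.individual_id in keep_set]
        gts = [g for g in self.genotypes if g.individual_id in keep_set]
        return Cohort(inds, list(self.variants), gts)

    def select_label(self, label: CohortLabel | str) -> "Cohort":
        label = CohortLabel(label)
        keep = [i.individual_id for i in self.individuals if i.cohort_label is label]
        if not keep:
            raise DegenerateInputError(f"no individuals with cohort_label {label.value!r}")
        return self.subset_individuals(keep)

    def normal_weight_control_subset(
        self, bmi_cutoff: float = DEFAULT_OBESITY_BMI_CUTOFF
    ) -> "Cohort":
        """All cases plus controls with known BMI <= cutoff.

        Controls with missing BMI cannot be verified as non-obese and are
        excluded from the subset.
        """
        keep = [
            i.individual_id
            for i in self.individuals
            if i.status is Status.CASE
            or (i.bmi is not None and i.bmi <= bmi_cutoff)
        ]
        return self.subset_individuals(keep)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        return (
            self.individuals == other.individuals
            and self.variants == other.variants
            and sorted(self.genotypes, key=lambda g: (g.individual_id, g.variant_id))
            == sorted(other.genotypes, key=lambda g: (g.individual_id, g.variant_id))
        )

    def __repr__(self) -> str:
        return (
            f"Cohort(n_cases={self.n_cases}, n_controls={self.n_controls}, "
            f"n_variants={len(self.variants)}, n_genotypes={len(self.genotypes)})"
        )


def _first_duplicate(items: Sequence[str]) -> str:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return ""
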