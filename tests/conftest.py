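import pytest

from burdenvt import (
    Cohort,
    GenotypeEntry,
    Individual,
    VariantRecord,
    ksr2_example_cohort,
)


def make_cohort(individuals, variants, genotypes):
    """Build a cohort from terse tuples:

    individuals: (id, status[, bmi])
    variants:    (id, pos, func_class)
    genotypes:   (ind_id, var_id, allele_count)
    """
    inds = [
        Individual(t[0], t[1], "original", bmi=(t[2] if len(t) > 2 else None))
        for t in individuals
    ]
    vars_ = [VariantRecord(*v) for v in variants]
    gts = [GenotypeEntry(*g) for g in genotypes]
    return Cohort(inds, vars_, gts)


@pytest.fixture(scope="session")
def study_cohort() -> Cohort:
    """The deterministic synthetic cohort matching the published margins."""
    return ksr2_example_cohort()


@pytest.fixture
def toy_cohort() -> Cohort:
    """10 individuals (5 cases / 5 controls), 4 variants, hand-listed genotypes.

    Manual tally of qualifying carriage (classes {frameshift, nonsense,
    missense}, no region, threshold 0.5 so MAF never excludes):
      cases:  ca1 {m1 het}, ca2 {m1 het, fs1 hom}, ca3 {syn1 het}, ca4 {}, ca5 {m2 het}
      ctrls:  co1 {m2 het}, co2 {}, co3 {syn1 hom}, co4 {}, co5 {}
    Dominant carriers: cases ca1, ca2, ca5 -> a=3; controls co1 -> c=1.
    Additive qualifying alleles: cases 1 + (1+2) + 1 = 5; controls 1.
    """
    return make_cohort(
        individuals=[
            ("ca1", "case"), ("ca2", "case"), ("ca3", "case"),
            ("ca4", "case"), ("ca5", "case"),
            ("co1", "control", 24.0), ("co2", "control", 31.0),
            ("co3", "control", 27.0), ("co4", "control", 22.0),
            ("co5", "control", 29.0),
        ],
        variants=[
            ("m1", 100, "missense"),
            ("m2", 700, "missense"),
            ("fs1", 50, "frameshift"),
            ("syn1", 300, "synonymous"),
        ],
        genotypes=[
            ("ca1", "m1", 1),
            ("ca2", "m1", 1), ("ca2", "fs1", 2),
            ("ca3", "syn1", 1),
            ("ca5", "m2", 1),
            ("co1", "m2", 1),
            ("co3", "syn1", 2),
        ],
    )
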