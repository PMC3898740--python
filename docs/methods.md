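# Methods

## Data model and coordinates

The analysis is protein-level. A variant is a token (conventionally a
protein-change label such as `R684C`) with a 1-based residue position on the
annotated isoform and a functional class in {frameshift, nonsense, missense,
synonymous, other}. Genotypes are sparse carrier entries with allele count
1 (heterozygous) or 2 (homozygous alternate); an absent entry means zero
copies. One individual may carry several variants, each possibly homozygous
— compound carriage is multiple entries, never an allele count above 2 per
(individual, variant). Protein regions are 1-based inclusive residue
intervals. No nucleotide coordinates, strand, or transcript liftover are
handled.

The shipped kinase-domain interval [634, 938] covers the reported
kinase-domain mutations (P662L through S904L) but is an approximate,
user-replaceable annotation: exact domain boundaries are an input, not
something the package knows.

## Qualification

A variant qualifies when (i) its class is in the configured set (default:
frameshift, nonsense, missense), (ii) its position falls in the optional
region, and (iii) its sample MAF is **strictly** below the threshold
("MAF < 0.5%" is read as a strict inequality and applied uniformly to every
rung of the ladder).

Sample MAF is allele count over 2N in a reference set of the **analyzed**
sample. The default reference is pooled cases + controls: this matches the
principle that rare categories are defined on the sample being tested, and
it makes qualification invariant under case/control label permutation —
which is both statistically coherent (the qualifying sets are part of the
exchangeable-null machinery) and what makes the permutation scan cheap. A
`controls_only` reference is available; under permutation the control arm
changes, so qualification is then honestly recomputed for every permuted
labeling (a much slower path).

Whenever a sub-sample is analyzed (a single cohort arm, the normal-weight
control subset, a merged sample), MAFs are recomputed on that sample; this
falls out of the design because qualification always computes frequencies
from the cohort object it is handed.

## Collapsing and the exact test

Dominant: a case/control individual contributes one carrier unit if it
carries at least one qualifying allele. Additive: it contributes its total
qualifying allele count, and the margins are alleles (2 × arm size). The
additive table can in principle be inconsistent (an individual carrying more
than two qualifying variants' worth of alleles); cells are validated
non-negative and a degenerate-input error is raised otherwise.

The Fisher test enumerates the hypergeometric support on the log scale
(log-gamma accumulation via the hypergeometric log-pmf), sorts point masses
ascending and accumulates them in that order for accuracy; this is stable
for cohort sizes in the thousands. Two-sidedness is the minimum-likelihood
convention with a 1e-7 **relative** tolerance on the "no more likely than
observed" comparison, so exact ties survive floating point. The whole
support is computed at once (`fisher_p_all`): under permutation the margins
are fixed, so a permuted scan is an O(1) lookup per threshold. An empty
carrier margin gives p = 1 (the observed table is the only one consistent
with its margins). One-sided (enrichment) p-values are available at the
library level but the scan is two-sided.

## Variable-threshold min-p and permutation adjustment

Per-threshold tables and p-values are computed for the decreasing ladder
(default 0.005, 0.001, 0.0005); `min_p` is their minimum, ties broken toward
the widest threshold. The adjustment shuffles status labels uniformly,
preserving arm sizes, **within the analyzed individual set** (after any BMI
exclusion), recomputes the full scan per shuffle, and reports

    adjusted_p = (1 + #{permuted min_p <= observed min_p}) / (1 + B),

the standard exact-permutation estimator: including the observed labeling
guarantees validity and a floor of 1/(B+1); ties count as extreme (the
conservative choice). One seeded `numpy` generator drives the whole
procedure; the same seed gives bit-identical results, and the seed is
recorded in every result. For tiny cohorts `exact_permutation_p` enumerates
all C(n, n_cases) labelings instead.

Degenerate inputs fail fast: an empty case or control arm (before or after
subsetting), an empty MAF reference, a qualifying set naming unknown
variants.

## Subset, region, and merged analyses

The analysis grid is {original, replication, combined} × {all controls,
normal-weight controls} × {whole gene, named region} × {dominant, additive}.
"Normal weight" keeps controls with known BMI ≤ 30 (configurable): controls
above the cutoff are excluded as potentially mis-labeled for an obesity
phenotype, overweight controls (25–30) remain, and controls with missing BMI
are excluded because they cannot be verified. Cases are never BMI-filtered.
Merging requires disjoint individual ids and identical annotation for shared
variant ids; the merged sample then re-derives all MAFs.

## The simulator

`simulate_cohort` draws independent sites (no linkage disequilibrium —
appropriate for rare variants in one gene in unrelated individuals, and the
collapsing test ignores LD anyway). Controls at a site with baseline MAF q
get Hardy-Weinberg genotypes, Binomial(2, q); cases use the enriched
frequency q′ solving odds(q′) = OR × odds(q) on the allele scale, the same
OR at every site — the simplest generative model consistent with a
carrier-level analysis. Enrichment pushing q′ to 0.5 or beyond is a
configuration error. Functional classes and positions are drawn from
configurable distributions; BMIs come from truncated normals (controls
centered at 26 kg/m², SD 4.5, so a realistic minority exceed the obesity
cutoff and the subset path is exercisable; cases all above it).

Defaults emulate the motivating screen: 2,101 cases / 1,536 controls, 15
sites with MAFs from a point mixture (0.0001 w.p. 0.6, 0.0003 w.p. 0.3,
0.002 w.p. 0.1 — straddling the threshold ladder at that sample size), class
mix 8% frameshift / 7% nonsense / 65% missense / 20% synonymous, odds
ratio 2; this yields roughly 1% of controls and 2% of cases carrying a
qualifying variant. The simulator reproduces the study's *statistical
structure* only: no sequencing error, no relatedness, no population
stratification, no per-variant effect heterogeneity — so passing simulation
tests shows the machinery is correct under the model's assumptions, not that
real cohorts satisfy them.

`ksr2_example_cohort` is a fully deterministic synthetic cohort matching the
published *marginal* counts (45/2,101 vs 16/1,536 carriers; 27 vs 7 distinct
variants, 5 shared; one case homozygous for two variants and one
heterozygous for two; 14 carriers among 1,353 normal-weight controls; 17 vs
3 kinase-domain carriers). The individual-level layout beneath those margins
is arbitrary, because the per-variant carrier table of the study is not
reproducible from its text.

## Calibration design and a known limitation

`calibration_study` measures the empirical rejection rate of
`adjusted_p ≤ α` over a simulation grid, with exact Clopper-Pearson
intervals; all per-replicate seeds derive from one master seed.

For type-I-error and power studies at a few hundred individuals,
`calibration_sim_config` places every site at q = λ\*/2N with λ\* = 2.2 and
makes all sites missense. Rationale: qualification caps a site's
contribution at the widest threshold (at 2N = 800 and t = 0.005, at most 3
copies), so the expected number of *qualifying* copies E[X; X ≤ 3] for
X ~ Poisson(λ) is maximized near λ ≈ 2.2. This maximizes the carrier
margin, hence the number of values the collapsed statistic can take —
which is what makes a permutation-calibration study informative.

Even at this design the statistic is discrete: at 200 + 200 individuals only
the 0.005 rung is active (2N × 0.001 < 1) and the expected carrier margin is
~27, so the valid, tie-inclusive, +1-corrected permutation test is
noticeably conservative — its exact size at α = 0.05 (computable by
convolving the per-site qualifying-carrier law and integrating the
binomial-blurred permutation CDF) is ≈ 0.031, not 0.05. This is a property
of exact permutation inference with sparse collapsed statistics, not an
implementation artifact; at study scale (thousands of individuals, richer
carrier margins) the conservatism shrinks. The test suite states the
nominal-size expectation and will flag this conservatism rather than hide
it; the acceptance script reports the measured null rate.

## Problem sizes used in checks

The bundled checks use: exhaustive Fisher validation over every 2×2 table
with N ≤ 60 against an exact integer-arithmetic enumeration oracle;
Monte-Carlo vs exhaustive permutation comparison on an 8-person cohort
(C(8,4) = 70 labelings, B = 50,000); null calibration with 1,000 replicates
of 200 + 200 individuals and 20 sites at B = 200; and a power curve over
odds ratios {1, 2, 4, 8} at 500 + 500 with 200 replicates each. Tiny-cohort
tests use a threshold ladder matched to their scale (a singleton among 8
people has MAF 1/16, so the study ladder would qualify nothing).

## Report conventions

JSON reports keep full precision and embed schema version, package version,
resolved configuration, seed, and SHA-256 digests of the inputs. The flat
TSV rounds p-values to 4 significant figures and carrier percentages to one
decimal (the precision such results are conventionally printed at); the raw
fractions remain in the JSON.
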