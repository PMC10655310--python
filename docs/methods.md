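# Methods

This note records the statistical models, estimators and design choices
behind ystrkit, and what the synthetic-data generators do and do not
emulate.

## Haplotype tables and panels

A haplotype is the tuple of exact allele strings over a panel's loci.
Intermediate alleles (e.g. 17.2 = 17 repeats + 2 bases) and null alleles
are distinct states for identity and counting; numeric recoding (rounding
to the nearest repeat, half away from zero; nulls as the 99 code or as
missing) is applied only where an analysis needs allele *sizes* — Rst and
network construction — never for haplotype identity. DYS385 is stored as
an order-normalised unordered pair and counts as two loci toward a
panel's nominal size; DYS389II is kept as reported, with no subtraction
of DYS389I. Tables are UTF-8 tab-delimited with "." as the decimal mark
and "-" separating DYS385 copies, matching common haplotype-database
export style.

The six built-in panels are nested by construction (9 ⊂ 11 ⊂ 12 ⊂ 17 ⊂
23 ⊂ 26 loci), so the number of distinct haplotype classes is
non-decreasing along the chain — a property the tests assert on random
tables.

## Forensic parameters

All summary statistics are functions of the class spectrum (how many
haplotypes occur once, twice, ...). RMP is the plain sample match
probability Σp², not the unbiased variant: only Σp² reproduces the
conventional published tables cell-for-cell. HD uses the unbiased
n/(n−1)(1−Σp²); both are computed with an exact integer numerator and a
single division so that degenerate cases (all singletons → HD exactly 1)
are exact in floating point. The HD standard error is the Nei-style
sampling-variance estimator

V(HD) = 2/(n(n−1)) · [2(n−2)(Σp³ − (Σp²)²) + Σp² − (Σp²)²],

offered as an optional output; published ± values rarely state their
formula, so it is not treated as a validation target. Display formatting
follows the field's table convention: RMP/HD rounded to 4 decimals,
percentage rows (DC, unique fraction) *truncated* to 2 decimals — the
convention under which the reference table's percent cells reproduce
exactly. Internal values are never rounded. The unique-haplotype
percentage uses denominator n (sample size), the only choice consistent
with all printed cells.

## Haplogroup assignment

Assignment walks a rooted haplogroup hierarchy whose non-root nodes carry
defining SNPs with ancestral/derived alleles. A node's status is derived
when all its typed defining SNPs are derived (disagreement among a node's
own SNPs is an error); a sample is assigned the deepest node that is
derived and has no ancestral-state ancestor. An untyped SNP on the path
is non-blocking when a deeper marker on the same path is derived — the
behaviour of hierarchical assays, which skip markers implied by the
assay design. Derived states on disjoint branches are impossible on the
non-recombining Y and raise a conflict listing both paths. Observed
alleles are oriented against the tree's allele definitions; exact allele
matches take precedence over the a/d keyword shortcuts, since the bases
A and D collide with them. No fixed Y-phylogeny release is bundled:
real analyses load their own child–parent SNP table, and the test
fixtures use a small synthetic tree.

## AMOVA, Fst and Rst

The one-level decomposition follows the standard squared-distance
formulation given in the README. Negative variance components (hence
negative Φst for near-undifferentiated populations) are reported raw;
clamping would distort the permutation null distribution. The
permutation p-value is (1 + #{Φst* ≥ Φst}) / (B + 1), counting the
observed arrangement, with B = 10,000 by default and an explicit seed.
Under the null this statistic is uniform on its grid, which the tests
check with a Kolmogorov–Smirnov test over simulated datasets.

Fst mode uses 0/1 identity distances on haplogroup labels (haplotype
keys can be passed instead). Rst mode uses d²(i,j) = Σ_l (a_il − a_jl)²
over single-copy loci; intermediate alleles are rounded to the nearest
repeat and nulls are treated as missing — a numeric null code would
inject huge spurious squared distances. Missing data are handled
pairwise-complete with rescaling by (panel loci / shared loci); a pair
sharing no typed locus is an error. No multiple-testing correction is
applied by default, matching raw reporting practice; a Benjamini–
Hochberg adjustment is available on the distance matrix.

## Ordination

MDS is the classical Torgerson construction: B = −½·J·(D∘D)·J,
eigendecomposition, coordinates V·Λ^½ from the top-k non-negative
eigenpairs (requests beyond the positive spectrum are truncated with a
warning). It was chosen over stress-minimising variants because it is
deterministic, closed-form and exactly recovers Euclidean
configurations, which makes it testable; published MDS plots are used
qualitatively, so the metric variant serves the same purpose. PCA
operates on the covariance of raw frequencies by default (frequencies
share a scale); a correlation-mode flag exists. Coordinates are defined
up to rotation/reflection; for reproducibility each axis is oriented so
its largest-magnitude loading is positive, and tests compare distance
matrices, never raw coordinates.

## Median-joining networks

Input preprocessing drops DYS385, rounds intermediates, recodes nulls to
99 and merges identical vectors. The default distance is weighted
stepwise Σ w_l·|Δ repeats| (repeat counts are ordered states; the
star-like expansion reading of networks presumes stepwise mutation),
with uniform weight 10 per locus unless a per-locus table is given; a
0/1 mismatch mode is available. The 99 state is categorical: one step
against any typed allele, zero against another 99 — |a − 99| would be
meaningless.

Construction iterates: (a) minimum spanning network — Kruskal passes in
cost batches, keeping every link within ε of the batch minimum that
joins components distinct at batch start; (b) quasi-medians from node
triplets sharing ≥ 2 network links (per-locus median of three states;
99 by majority; with a single 99 the two typed states contribute their
floor midpoint, a deterministic integer consensus); (c) the cheapest
candidates (within ε of the minimal connection cost) are admitted when
they strictly shorten the minimum-spanning-tree length of the node set.
Total length is monotone decreasing over a finite candidate space, so
the loop terminates; a generous iteration cap guards the invariant.
Median nodes of degree ≤ 1 are pruned with link recomputation until
stable. ε defaults to 0. Node iteration order is lexicographic, making
output deterministic. When medians replace all direct observed–observed
links (as in the three-haplotype Steiner toy), the observed-node
subgraph intentionally has no edges; the spanning-tree containment
property applies to networks without added medians.

## Synthetic data

The generators define the study-shaped conditions every stage is tested
under:

- **Spectrum inversion** builds class representatives by mixed-radix
  repeat offsets (0–3) from modal-allele-like base haplotypes, keeping
  alleles in realistic ranges so the tables remain usable downstream;
  the output's class spectrum equals the request exactly, and sample
  order is shuffled.
- **Island model**: per-population haplogroup frequencies are Dirichlet
  with parameters p̄_k(1−θ)/θ (Balding–Nichols), so expected pairwise
  Fst is θ. The default ancestral profile is an O-dominated East Asian
  cohort (O 0.57, J 0.0886, C 0.0851, Q 0.0815, D 0.0531, remainder over
  N/R/other).
- **Stepwise mutation model**: each locus accumulates a Poisson number
  of ±1 repeat steps; populations diverge independently from a shared
  ancestor for a configurable number of generations, with 50 generations
  of within-population history (rate 2 × 10⁻³ per locus per generation,
  the canonical Y-STR average) supplying internal diversity. A star
  preset (founder + single-step offspring) reproduces the
  recent-expansion signature.

All draws flow through a single numpy Generator; identical configuration
and seed give bit-identical output. What the generators do **not**
emulate: linkage between haplogroup and STR background, locus-specific
mutation rates and range constraints, multi-step mutations, migration,
or genealogical (coalescent) correlation among men. Passing tests
therefore demonstrate estimator correctness and calibration under the
stated models, not robustness to every feature of real cohorts.

## Problem sizes and numerical choices

The test and acceptance workloads use reduced but statistically adequate
sizes chosen as part of the package's own test design: island-model
calibration at 4 populations × 100 men × 200 replicates; permutation
uniformity at 500 permutations × 200 datasets; brute-force AMOVA
equivalence on instances with ≤ 8 individuals; MDS/PCA oracles at ≤ 10
points / 2000 rows. Tolerances: 10⁻¹² for algebraic identities against
brute-force oracles, 10⁻⁹ for eigen-based reconstructions, ±0.015 for
the Fst calibration mean, ±0.03 for planted-variance recovery. Distance
matrices must be exactly symmetric with a zero diagonal; frequency rows
must sum to 1 within 10⁻⁶.
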