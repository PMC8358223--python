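# Methods

This note documents the models, numerical choices and known limitations of
`pantrait`, in the order the pipeline runs them.

## Trait extraction

Subsystem annotations arrive as long-format records (genome, category,
subcategory, subsystem, role).  The retained-category list, removed
subsystems and removed subcategories ship as an editable YAML file
(`src/pantrait/rules/default_rules.yaml`); matching is case-insensitive
with whitespace normalization, and category selection is applied before
subsystem/subcategory removals (the outcome is identical for the shipped
rule names either way).  Counting rules that matter:

- **Role identity** is the case-folded, whitespace-normalized role string.
  Annotation roles are free text and no canonicalization beyond this is
  attempted; a role annotated on several gene features (duplications,
  fragmented genes) counts once per genome × subcategory.
- A role assigned under two different subcategories counts once in *each*;
  cross-subcategory deduplication is deliberately not applied, because the
  quantity of interest is functions per subcategory.
- Relative counts divide by each genome's total over the retained
  subcategories only.  Genomes with zero retained roles are dropped from
  the relative matrix with a warning.

Filtering is idempotent and counting is invariant under record
duplication; both are property-tested.

## Dissimilarities and ordination

Bray–Curtis is evaluated directly from its definition on nonnegative rows
(all-zero rows are an error naming the sample); binary Jaccard assigns
distance 0 to a pair with empty union (logged).  PCoA eigendecomposes the
Gower-centered matrix −½·J·D²·J.  No Lingoes/Cailliez correction is
applied: negative eigenvalues are reported as-is and excluded from the
percent-variance denominator, so the reported percentages sum to 100 over
the positive axes.  Variable loadings are plain Pearson correlations
between each input variable and the site scores of each axis — a
documented choice; constrained-ordination "species score" scalings differ
between packages and none is canonical for unconstrained PCoA.

## Permutation tests

All permutation p-values use the add-one convention (1 + count)/(1 + B),
so p ≥ 1/(B+1) and p = 0 is impossible.  Each stochastic stage of the
pipeline derives a child seed from the global seed and the stage name
(CRC32), so stage order never changes results and every stage is
independently reproducible.

- **PERMANOVA** partitions SS_T = Σ_{i<j} d²ᵢⱼ/N into among/within via the
  within-group pair sums; the null permutes whole rows of the label
  vector.  On univariate Euclidean input the pseudo-F equals the classical
  one-way ANOVA F exactly (tested).  Pairwise contrasts subset the
  distance matrix and BH-adjust across pairs.
- **Mantel** correlates strictly-lower-triangle entries (Spearman with
  average ranks by default), permuting rows+columns of the second matrix
  jointly; the p-value is one-sided upper.  Matrices are aligned by label,
  never by position.
- **Procrustes** centers both configurations and scales each to unit total
  sum of squares; m² = 1 − (Σ singular values of X'Y)², which equals the
  symmetric disparity of standard Procrustes analysis (tested against
  scipy).  Significance permutes rows of one configuration.

## Ward clustering and multiscale bootstrap

`ward_cluster` implements the Lance–Williams recurrence.  The default
`ward.D2` variant squares the dissimilarities before the recurrence and
reports square-root merge heights — the squared-distance Ward convention
used by the bootstrap-support workflow this mirrors; `ward.D` is available
as a sensitivity flag.  Ties break deterministically toward the smallest
(cluster-id, cluster-id) pair.  Heights match scipy's `linkage(…, "ward")`
on Euclidean input to 1e−10 (tested), and the bootstrap inner loop uses
scipy's condensed pdist + linkage as a fast path whose cluster sets are
asserted identical to the from-scratch implementation on random fixtures.

Multiscale bootstrap support: for each scale r ∈ {0.5, 0.6, …, 1.4},
features are resampled with replacement at size round(m·r) and the
Bray–Curtis/Ward tree recomputed; BP_r(cluster) is the fraction of
replicates containing the identical tip set.  z_r = Φ⁻¹(1 − BP_r) is
fitted by weighted least squares to z_r = v√r + c/√r with weights
B·φ(z)²/(BP(1−BP)); AU = 1 − Φ(v − c), and BP is the raw proportion at the
scale nearest r = 1.  Numerical conventions: BP_r of 0 or 1 is clipped to
(1/(2B), 1 − 1/(2B)); a cluster at the ceiling (or floor) at *every* scale
gets AU = 1 (or 0) directly, because the signed-distance fit is
unidentified there; scales yielding <2 features are dropped with a
warning, and clusters seen at fewer than two distinct usable scales get
AU = NaN.  Significance is reported at both AU ≥ 0.95 and BP ≥ 0.50.

## Tree metrics

Cophenetic distances are path sums of branch lengths; trees read with
missing branch lengths (imputed as 0, counted) are refused by all
distance-based operations, while topology-only nRF still works.  nRF
counts non-trivial unrooted bipartitions present in exactly one tree and
divides by the total non-trivial bipartitions of both trees — 2(n−3) for
two binary trees — so nRF ∈ [0,1] also for multifurcating inputs.  The
denominator convention matters because packages differ on multifurcation
handling; it is stated here for that reason.

Pagel's λ multiplies the off-diagonal entries of the Brownian-motion
covariance C (C_ij = root-to-MRCA depth) while keeping the diagonal; σ²
and the root state are profiled analytically and λ is maximized by bounded
Brent search on [0, λ_max], where λ_max is the largest value keeping C(λ)
positive definite, capped at 1 by default (values >1 are rarely
interpretable and the cap is configurable).  The LRT against λ = 0 (tips
independent with variance σ²·depth) uses a χ²₁ reference; at the λ = 0
boundary this is conservative, which the calibration test reflects
(empirical size ≤ 7 % at α = 0.05).

## Pangenome statistics

Core = presence in 100 % of a species' strains (threshold configurable;
with 4–13 strains per species any softer threshold ≥ 0.99 is equivalent).
Multi-copy genes collapse to presence before partitioning, with the
multiplicity logged — the distribution index and the exact tests are
defined on gene-family incidence.  The distribution index
D = (n_core − n_accessory(strain))/n_pangenome is 1 for an all-core
pangenome, near 0 when a strain's accessory matches the core, and may go
negative (flagged) when it exceeds it.

Shannon residue diversity averages per-column entropy (base-2 by default,
switchable) with gaps excluded from each column's distribution and
all-gap columns skipped.  Nucleotide diversity π is the mean pairwise
difference fraction with pairwise deletion of gap/N positions.

Exact tests.  The species × {present, absent} incidence test uses the
Freeman–Halton extension of Fisher's exact test for r×2 tables: the
p-value sums probabilities of all margin-fixed tables whose probability is
at most the observed one (relative tolerance 1e−7).  Enumeration splits
rows into two halves and combines their first-column fill profiles by
sorted prefix sums, making moderate tables exact and fast; totals above 60
fall back to seeded Monte-Carlo over the multivariate hypergeometric with
a reported standard error.  Orthogroups must carry genes from ≥3 genomes
to be tested (configurable); strain-count tables are used rather than
binary species-level presence, which is the finer-grained of the two
possible constructions.  Accessory enrichment counts *distinct roles* per
subsystem and compartment (genes without a role annotation are excluded),
uses the one-sided hypergeometric upper tail, and reports the sample odds
ratio ad/bc with a Haldane 0.5 correction when any cell is zero.  BH
step-up FDR is applied within each test family.

## Model layer

Beta regression parameterizes Beta(μφ, (1−μ)φ) with logit(μ) = Xβ and
constant precision φ; the likelihood is maximized through statsmodels'
BetaModel, and the test suite checks the intercept-only fit against an
independent two-parameter Beta MLE.  Responses touching {0, 1} are first
squeezed by y′ = (y(n−1) + 0.5)/n, flagged on the fit.  An all-equal
response yields a capped-precision degenerate fit with a warning rather
than an optimizer failure.  The LRT is 2·ΔlogL on a χ² reference with df =
Δparameters (df = 0 returns χ² = 0, p = 1).

ANOVA with a patristic-distance covariate uses Type-II sums of squares
(Type I/III reachable through statsmodels directly); genome size and CDS
counts should be log₁₀-transformed via the `transform` flag.  The
quasibinomial GLM is an IRLS logistic fit whose dispersion is Pearson
χ²/df, scaling the per-term Wald χ² omnibus statistics.  Post-hoc
Tukey-style letter groupings are out of scope; pairwise contrasts with BH
adjustment serve that role where needed.  Model summaries report raw group
means with model-based standard errors, not estimated marginal means on a
reference grid.

## Synthetic data

The default configuration reproduces the scale of the study design the
package targets: 96 genomes in three orders (28/18/50), seven prevalent
species with 5–13 strains (46 strains total), 38 primary-metabolism
subcategories, per-genome function totals of roughly 290–960, core genomes
drawn from 264–488 genes, per-strain accessory counts up to ~100 and total
pangenomes capped at 538.

- **Trait counts**: per genome, counts ~ Multinomial(N_g, p) with
  p ~ Dirichlet(α·(base + δ·order-shift + δ_sp·species-shift)), α = 400.
  δ = 0.52 was calibrated once so that a PERMANOVA by order on the default
  panel yields R² ≈ 0.56–0.57, the effect size regime the analysis is
  meant to exercise; δ_sp = 0.12 adds the species-level structure that
  makes trait dendrograms cluster by species.  The companion function
  table realizes these counts as role records (so extraction recovers the
  planted matrix exactly) plus out-of-scope and removed-subsystem records
  that extraction must drop.
- **Pangenomes**: each species carries a shared core (present in every
  strain of every species, 55 % of the minimum core size), a
  species-private core, and an accessory pool from which strains draw
  Poisson-many genes, split between a shared sub-pool (recurring accessory
  genes) and strain-private genes.  With enrichment odds ρ > 1 (default 4,
  matching the planted-effect regime of the power checks), accessory genes
  favor one configured subsystem ρ-fold.
- **Alignments**: i.i.d.-site substitution along the tree (Jukes–Cantor
  for nucleotides, uniform exchange over 20 amino acids), with per-species
  rate multipliers on edges whose descendant tips all belong to one
  species — giving direct control of within-species diversity.
- **Continuous traits**: multivariate normal draws under the λ-scaled BM
  covariance.

What the generator does *not* emulate: annotation noise and mis-assigned
roles, draft-genome fragmentation (which miscategorizes core genes as
accessory in real data), horizontal transfer between species, rate
heterogeneity across sites, and codon structure.  Passing tests therefore
demonstrate the statistical engine's correctness and calibration, not
robustness to those real-data artifacts.

## Problem sizes and effort defaults

The pipeline defaults to 999 permutations for all permutation tests and
1,000 bootstrap replicates per scale (10 scales) for cluster support; the
simulation-based checks in the test suite use 200–500 replicates per
calibration and 25–30 datasets for the bootstrap null, sizes at which the
binomial/KS acceptance bands are meaningful while a full run of suite plus
acceptance script stays around a minute of CPU.  The multiscale-bootstrap
replicate count is the knob to raise (toward the 10⁴ regime) when AU
values near the 0.95 threshold must be resolved finely.

## Known limitations

- PCoA axis signs (and therefore loading signs) are arbitrary, as in any
  eigendecomposition.
- The Freeman–Halton Monte-Carlo fallback yields a stochastic p-value;
  its standard error is reported and the enumeration bound can be raised
  when margins allow.
- Pagel's λ assumes a rooted tree with informative branch lengths; trees
  with imputed zero lengths are refused rather than silently misfitted.
- Beta-regression standard errors come from the observed information at
  the MLE; no small-sample or bias correction is applied.
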