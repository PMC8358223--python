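# pantrait

Phylogeny-aware analysis of metabolic trait repertoires and pangenomes for
collections of bacterial genomes.

## The problem

Gut microbiomes of insects such as *Drosophila* are dominated by a handful
of culturable bacterial orders (Enterobacterales, Lactobacillales,
Rhodospirillales).  Given draft genomes for ~100 isolates, annotated with a
subsystem hierarchy (category → subcategory → subsystem → role), the
questions are: how does primary-metabolism capability partition across the
phylogeny — by order, genus, species — and how much metabolic variation
hides *within* species, in the accessory genome of strains?

`pantrait` implements that analysis end to end for anyone with (a)
subsystem annotation tables (the tabular shape of RAST exports), (b)
gene/orthogroup presence–absence matrices (Roary- or OrthoFinder-style),
(c) Newick phylogenies, and (d) FASTA alignments.  A seeded synthetic-data
module generates all of these with controlled structure, so every stage is
testable without downloads.

## What it computes

**Trait extraction.**  Six primary-metabolism categories are retained
(amino acids and derivatives; carbohydrates; cofactors/vitamins/prosthetic
groups/pigments; fatty acids/lipids/isoprenoids; nitrogen metabolism;
nucleosides and nucleotides); five secondary-metabolism subsystems and the
nucleotide "detoxification"/"no subcategory" subcategories are removed, and
"no subcategory" is relabeled "other" elsewhere.  Each distinct role string
counts once per genome × subcategory; relative counts scale rows to each
genome's total over the retained subcategories.

**Multivariate statistics** (implemented from scratch, cross-checked
against independent oracles in the test suite):

- Bray–Curtis d(x,y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ) and binary Jaccard
  d = 1 − |x∩y|/|x∪y|;
- PCoA: eigendecomposition of the Gower-centered matrix −½·J·D²·J, with
  negative eigenvalues reported and percent variance over positive axes;
- PERMANOVA (McArdle–Anderson): pseudo-F = (SS_A/(a−1))/(SS_W/(N−a)),
  R² = SS_A/SS_T, p by whole-row label permutation, add-one convention
  p = (1 + #{F* ≥ F})/(1 + B); pairwise contrasts with BH FDR;
- Mantel (Spearman, one-sided upper) and symmetric Procrustes
  (m² = 1 − (Σσ)², r = √(1−m²)) randomization tests;
- Ward clustering via Lance–Williams updates on squared dissimilarities
  (ward.D2; ward.D by flag) and multiscale-bootstrap cluster support:
  feature resampling at scales r ∈ {0.5, …, 1.4}, z_r = Φ⁻¹(1−BP_r) fitted
  by weighted least squares to v√r + c/√r, AU = 1 − Φ(v−c).

**Tree metrics.**  Cophenetic (tip–tip) and root-to-tip patristic
distances; normalized Robinson–Foulds nRF ∈ [0,1] on unrooted non-trivial
bipartitions; Pagel's λ by maximum likelihood under a Brownian-motion
covariance whose off-diagonals are scaled by λ, with a χ²₁ likelihood-ratio
test against λ = 0.

**Pangenome statistics.**  Core (present in 100 % of a species' strains) /
accessory partition; per-strain distribution index
D = (n_core − n_accessory(strain)) / n_pangenome; mean per-column Shannon
entropy of amino-acid alignments and nucleotide diversity π; two-sided
Fisher/Freeman–Halton exact tests of orthogroup incidence between species
(exact enumeration to n = 60, seeded Monte-Carlo beyond); one-sided Fisher
enrichment of subsystems in accessory vs core function counts with sample
OR = ad/bc (Haldane-corrected); BH FDR throughout.

**Model layer.**  Beta regression (logit mean link, constant precision)
with likelihood-ratio tests for species effects on D; Type-II ANOVA with a
patristic-distance covariate; quasibinomial logistic regression with Wald
χ² omnibus tests for GC-like proportions; Pearson correlation.

## Worked example

```python
from pantrait.pipeline import PipelineConfig, run_pipeline

results = run_pipeline(PipelineConfig(seed=1, out_dir="demo_run",
                                      n_permutations=999, n_boot=1000))
print(results["permanova"])
print(results["pangenome"])
print(results["betareg_lrt"])
```

prints (seed 1):

```
{'pseudo_F': 59.58452603294824, 'R2': 0.5616702855838013, 'p': 0.001, 'df': (2, 93)}
{'core_min': 275, 'core_max': 468, 'pangenome_min': 336, 'pangenome_max': 538,
 'max_strain_accessory': 43, 'n_species': 7}
{'chi2': 228.54925023114572, 'df': 6, 'p': 1.5618201208457745e-46}
```

Reading: bacterial order explains 56 % of the Bray–Curtis variation in
relative metabolic-function profiles across the 96 synthetic genomes
(pseudo-F₂,₉₃ = 59.6, p = 0.001 with 999 permutations); the seven prevalent
species carry metabolic core genomes of 275–468 genes with pangenomes up to
538; and the pangenome distribution index differs strongly among species
(LRT χ²₆ = 228.5).  `demo_run/` also contains PCoA coordinates, AU/BP
cluster support, tree–trait congruence (nRF, Mantel), Procrustes results,
enrichment tables and a manifest sufficient to reproduce every file.

The same workflow is available from the shell:

```bash
pantrait run --seed 1 --out demo_run
pantrait simulate --seed 2 --out inputs/      # write synthetic input files
pantrait extract-traits --table inputs/annotations.tsv
pantrait tree-compare --tree1 a.nwk --tree2 b.nwk
```

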