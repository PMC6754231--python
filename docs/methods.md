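# Methods

This note documents the models implemented in `grnqg`, the defaults chosen
where the analysis recipe leaves a choice open, and what the synthetic-data
generator does and does not emulate.

## Phenotype model

The traits are penetrances: for each strain, the fraction of arrested
embryos that differentiate gut after knockdown of one of two regulatory
inputs into the endoderm network. The generative model is a liability
threshold construction:

    liability_i = baseline + Σ_j g_ij β_j + polygenic_i + ε_i
    penetrance_i = logistic(liability_i), clipped to [1e-6, 1 − 1e-6]
    observed_i = mean_r Binomial(n_embryos, penetrance_i) / n_embryos

with `g_ij ∈ {0, 1, 2}` the allele dosage, `β_j` QTL effects in liability
units per allele copy, `polygenic` a genotype-borne background (many small
effects spread over randomly chosen markers, scaled to a target liability
SD), and `ε` a strain-level normal noise term. Defaults: two replicates of
500 embryos (the study design this emulates scores ≥ 500 embryos per
replicate per isotype); strain noise SD 0.25 liability units. The magnitude
of strain-level variation beyond binomial sampling is not derivable from
the study description (replicate scatter of roughly ±2 percentage points
on a 32% penetrance is consistent with a wide range of liability noise),
so 0.25 was fixed once as a value giving realistic between-replicate
reproducibility, and is configurable.

The logistic link is a modelling choice — the source analyses treat
penetrance non-parametrically — chosen because it keeps liabilities
unbounded while guaranteeing penetrances in (0, 1). The polygenic term is
realised through genotypes rather than as a drawn random effect so that
kinship confounding is real in the simulated data and the mixed model's
correction is genuinely testable.

## Isolate panel

Homozygous clonal strains from `k` subpopulations under the
Balding–Nichols construction: per marker an ancestral frequency
p ~ U(0.05, 0.95); subpopulation frequencies
Beta(p(1−F)/F, (1−p)(1−F)/F) with differentiation F (exactly p when
F = 0); one Bernoulli allele draw per strain, doubled to a homozygous
genotype. Uniform genotyping error (0↔2 flips) and uniform missingness are
injected at configurable rates; real missingness is structured (library
effects, coverage), which this does not emulate — QC behaviour under
structured missingness is therefore untested by construction.

## RIL simulation

Meiosis follows Haldane's model: crossover count per chromosome
~ Poisson(length in Morgans), placement uniform, no interference. This
matches the map-function convention of the interval-mapping HMM by design,
so simulator and mapper are self-consistent (an interference model such as
chi-square/Kosambi would make the HMM's Haldane assumption slightly
wrong — a deliberate non-goal). An F1 (uniformly heterozygous) selfs once
to give F2 lines, each of which then selfs a configurable number of further
generations (default 10). Expected residual heterozygosity per locus after
t extra selfings is (1/2)^(t+1), i.e. ≈ 4.9 × 10⁻⁴ at the default;
residual heterozygotes are emitted as code 1 and treated as missing by the
mapper (standard selfed-RIL convention). Two-point recombinant fractions
expand as r_RIL = 2r/(1 + 2r) (Haldane–Waddington), which the test suite
verifies against simulation for r ∈ {0.01, 0.1, 0.25, 0.4}.

## Mixed-model association

Exact EMMA-style REML: for each tested marker the variance ratio
δ = σe²/σg² is re-estimated with the marker in the fixed effects (the exact
variant, not the one-fit approximation — at panel sizes of ~100 strains the
difference is material). The restricted likelihood is profiled through the
eigendecomposition of S K S (S the projection orthogonal to the fixed
effects); a 100-interval grid on log10 δ ∈ [−5, 5] brackets sign changes of
the derivative, each bracket is refined to a root, and the global optimum
(boundaries included, flagged when attained) is taken. Fixed effects are
intercept-only by default; covariates can be supplied. Missing genotypes
drop the strain for that marker's test (complete-case); markers below the
MAF threshold (default 0.05 for the panel scan, configurable) or
monomorphic after missingness are flagged untested rather than silently
skipped.

Permutation significance: phenotype labels are permuted against fixed
genotypes and kinship and the full exact scan recomputed per permutation
(the per-marker spectral decompositions depend only on genotypes, so they
are computed once and reused across permutations; the permuted statistics
are numerically identical to running the scalar scan). Two summaries are
reported, because "permutation FDR" can mean either: (i) the ratio
estimator FDR(t) = mean permuted count of p ≤ t over observed count,
monotonised step-up and clipped to [0, 1]; (ii) the family-wise
max-statistic threshold (α-quantile of per-permutation minimum p).

## Interval mapping

Genotype probabilities from a two-state forward–backward pass per
chromosome; transitions use the RIL-expanded recombination fraction between
adjacent grid positions, emissions allow a symmetric genotyping error.
Applying the expansion between pseudomarker steps treats r_RIL as locally
additive, the same approximation standard RIL mappers make. Defaults match
common R/qtl practice: step 1 cM, error rate 1e-4, EM tolerance 1e-6 on the
log-likelihood, max 4000 iterations. The EM fits class means and a common
variance with known mixing proportions, vectorised across all grid
positions; at a fully observed marker with zero error rate it reduces
exactly to marker regression, LOD = (n/2) log10(RSS0/RSS1). Genome-wide
thresholds use the ⌈(1−α)N⌉-th order statistic of permuted maximum LOD
(no interpolation). Support intervals take the outermost positions within
`drop` (default 1.5) LOD of the peak, linearly interpolated between grid
points and clipped to chromosome ends; an all-zero curve yields an explicit
no-peak result. When only physical positions are available, genetic
positions are assigned at a constant 1 cM / 250 kb (configurable per run),
a round figure for a compact selfing-nematode genome.

## Phylogenetic signal

Distances are Hamming proportions over markers non-missing in both strains
(the tree-building recipe names only "pairwise distances"; Hamming is the
simplest consistent choice and is configurable). Neighbor joining is
implemented in-package because the required determinism — Q-criterion ties
broken by taxon-name order, negative branch lengths clamped to zero with
the deficit moved to the sister branch, trifurcating unrooted output — is
not controllable in library implementations; an independent library NJ
serves as the topology oracle in the tests. Pseudo-rooting at a named
outgroup is display-only.

Pagel's λ scales the off-diagonal entries of the Brownian-motion covariance
C (C_ij = shared root-to-path length). The ML fit profiles (rate, root
mean) in closed form per λ and optimises λ on [0, 1] by grid + bounded
refinement; λ > 1 is excluded since the diagonal is held fixed. The LRT
against λ = 0 is referred to χ²₁ despite the boundary, matching common
practice; this is conservative for λ̂ > 0 interior and slightly liberal at
the boundary, and the type-I error test budgets for it (≤ 7.5% at nominal
5%).

## Reciprocity analysis

Per SNP and trait: effect = median(phenotype | alternate-class strains) −
median(phenotype | reference-class strains), with the reference class fixed
across traits (parent-A/N2-like) so signs are comparable; flipping the
global reference negates all effects and leaves the cross-trait correlation
unchanged (tested). Pipeline order is fixed: allele-class-size filter
(default minimum 3 strains per class) → LD pruning → effect computation →
outlier filter → correlation. Pruning defaults — window 50 markers, step 5,
r² 0.8 — stand in for unstated PLINK parameters and are echoed in every
report. Outlier exclusion is a single pass at |z| > 1.96 computed per trait
from the included effects, removing a marker extreme in *either* trait
(so one trait's outlier cannot leverage the correlation); statistics are
deliberately not recomputed iteratively, and the report logs counts at each
stage. Groups with fewer than 3 markers report an undefined (NaN)
correlation rather than an error.

## Pipeline and reproducibility

A single global seed drives every stage through named substreams
(seed XOR SHA-256(stage name), kept below 2³¹), so enabling or disabling
one stage never shifts another's draws; identical configs produce
byte-identical machine-readable reports. All intermediate artifacts are
plain-text files in the documented formats (vcftools 012 trio, GT-only
VCF, CSV phenotypes with replicate counts, TSV maps, Newick). Group
comparison tests in the reporting stage (Fisher exact, Welch t) delegate
to scipy.

## Problem sizes used in the checks

The automated checks run at desk scale, chosen to exercise the statistical
properties rather than the full study dimensions: REML/grid agreement at
n = 50 strains × 200 markers; null calibration of both permutation
procedures over 200 replicate scans × 200 permutations (n = 30 strains ×
40 markers for association; 50 RILs × 30 markers for linkage); interval
coverage over 200 replicates of 100 RILs; simulator expectations at
50,000 loci and 10,000 RILs; reciprocity recovery over 50 replicates of
80 strains × 90 markers; λ recovery over 200 replicates on a 64-tip tree.

## Known limitations

* No coalescent demography, selection, or structured missingness in the
  simulator; genotyping error is uniform flips only.
* Single-QTL scans only: no composite interval mapping, multi-QTL or
  epistasis models.
* The mixed model has one random effect; no GxE or rare-variant tests.
* λ's LRT reference distribution is approximate at the boundary (above).
* Penetrance values near 0 or 1 compress liability-scale effects; power at
  extreme baselines is correspondingly lower.
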