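# Methods

This note records the statistical models behind each component, the
numerical conventions, and the design decisions taken where the design was
genuinely open. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Data model

Genotypes are unordered diploid allele pairs (microsatellite phase is
unknowable), stored canonically as (min, max) integer fragment sizes with
`(0, 0)` for a missing call; a call is either fully typed or fully missing.
Allele frequencies are direct counts over typed genes, per population and
pooled. Individuals failing to amplify at more than six loci (default) are
removed before analysis. Dates accept `DD.MM.YYYY` and ISO-8601. GenePop
files are written 3-digit and read with per-file 2/3-digit auto-detection;
Structure export recodes alleles to consecutive integers with −9 missing.
All writers are byte-deterministic for a given dataset.

## Probability of identity

Per locus, with aₘ = Σᵢ pᵢᵐ over allele frequencies:
biased P_ID = 2a₂² − a₄ (the sum over genotypes of squared Hardy–Weinberg
probabilities); the unbiased small-sample version is

  P̂_ID = [n³(2a₂² − a₄) − 2n²(a₃ + 2a₂) + n(9a₂ + 2) − 6] / [(n−1)(n−2)(n−3)]

with n the number of sampled genes. We verified by Monte-Carlo that this
estimator is exactly unbiased for the parametric P_ID and converges to the
biased form as n → ∞ (that simulation is frozen into the test suite as the
convergence property). The sibling bound is
P_ID(sib) = 0.25 + 0.5a₂ + 0.5a₂² − 0.25a₄. Multilocus values are products
over loci (independence assumption; loci are screened for LD separately).
Loci with fewer than 4 genes are excluded from the unbiased product.

## Matching and re-encounters

A locus mismatches iff the unordered allele pairs differ — a one-allele and
a two-allele difference both count one mismatching locus, matching the
multilocus-matching semantics of the common toolchain. Loci missing in
either member are excluded from the comparison. Exact match = 0 mismatches;
near match = 1..3 (default). Near matches are annotated per locus as
`false_homozygote` (one member homozygous for an allele the other carries —
the allelic-dropout/null-allele signature) or `different_alleles`, to
support the manual forensics such matches need. Deduplication keeps, per
matched component, the genotype with fewest missing loci (ties: earlier
sampling date, then lexicographic id); non-clique components are retained
with a warning rather than split. Distances between sampling points use the
haversine formula on the mean Earth radius (6371.0088 km); a planar
equirectangular option exists for reproducing legacy "euclidean" distances.
Within-season means same calendar year; same site means within 20 km
(default) or, lacking coordinates, an identical site label.

## Diversity statistics

Unbiased H_E = (2n/(2n−1))(1 − Σp²); F_IS = (H_E − H_O)/H_E per locus,
averaged over loci where defined (the convention of the spreadsheet
toolchain this field uses; Weir–Cockerham f is available from the
differentiation module but not used for summary tables). Allelic richness
rarefies to g genes (default 14 = 7 diploids):
A_R = Σₐ [1 − C(N−Nₐ, g)/C(N, g)], computed via log-gammas; populations
with fewer than g typed genes are reported non-applicable. Private alleles
require ≥ 2 populations. Means are reported with SE = sd/√(loci).

## Exact Hardy–Weinberg test

The p-value is Fisher-style probability ordering under Levene's conditional
distribution of genotype tables given allele counts:
P(table) ∝ n! 2^h Πₐ nₐ! / (2n)! / Πᵢ≤ⱼ kᵢⱼ!, with h heterozygotes. With
two alleles the table space is enumerated completely. Otherwise we run a
switch chain on the underlying gene pairing: each step swaps one allele
between two random individuals. The uniform distribution over pairings is
invariant under this symmetric proposal and induces exactly Levene's
distribution on tables, so no Metropolis correction is needed; this is the
Guo–Thompson switch chain expressed at the pairing level. Default 10,000
recorded sweeps after 1,000 burn-in; the Monte-Carlo SE uses 50-batch means
to absorb autocorrelation. Monomorphic loci are flagged inapplicable rather
than given p = 1.

## Linkage disequilibrium screen

The statistic is the log-likelihood-ratio G between the two-locus genotype
contingency table and independence; the null shuffles one locus's genotypes
among individuals, with (count + 1)/(permutations + 1) smoothing. This is a
genotypic (unphased) permutation test — the same null hypothesis as the
classic contingency-table MCMC, chosen because a permutation null is easy
to verify for size; its type-I error is checked by simulation in the test
suite. Pairs with < 5 jointly typed individuals are computed but flagged
underpowered.

## Relatedness

Reference allele frequencies default to the full sample, pair included
(the default of the standard co-ancestry software); an external frequency
table can be supplied. Loci are used pairwise-complete.

- **QG** (Queller–Goodnight): per direction, locus numerators
  0.5(δ_ac+δ_ad+δ_bc+δ_bd) − p_a − p_b over denominators 1 + δ_ab − p_a −
  p_b, summed across loci before the ratio; directions averaged. Loci where
  the focal individual's denominator vanishes (e.g. homozygous at a fixed
  allele) are excluded from that direction.
- **LynchRD** (Lynch–Ritland): the reference-individual form with the
  standard locus weights (numerator and denominator divided by 2p_ap_b,
  summed, then ratioed); directions averaged.
- **Wang**: a similarity-class moment estimator. Each locus's genotype pair
  falls into one of four phenotypic similarity classes (identical;
  homozygote–heterozygote sharing one allele; two heterozygotes sharing
  exactly one; no shared alleles). The class probabilities given 2, 1 or 0
  IBD allele pairs are closed forms in a₂, a₃, a₄ (derived from first
  principles under HWE and unit-tested against the estimator's behaviour on
  pedigree simulations). Stacking the class-indicator moment equations
  across loci and solving by least squares gives a linear — hence exactly
  unbiased — estimator of (k₂, k₁), and r̂ = k̂₂ + k̂₁/2. This follows
  Wang's construction; we solve the moment system directly rather than
  transcribing the published closed-form algebra, trading his
  minimum-variance weights for transparent exact unbiasedness (verified at
  r ∈ {0, 0.25, 0.5} by the simulation oracle in the acceptance tests).
- **DyadML**: maximizes Πₗ Σₛ wₛ Pₛ(locus) over the simplex, where states s
  are (k₀,k₁,k₂) (non-inbred) or the nine condensed Jacquard coefficients
  Δ₁..Δ₉ (inbreeding allowed), with genotype-pair probabilities per state
  derived from the IBD structure. Because the log-likelihood is concave in
  the mixture weights, EM from the barycentre converges to the global
  optimum; vertex checks are kept as cheap safeguards and the result is
  validated against a dense 0.01-step grid search (agreement within 1e-6
  log-likelihood). Convergence tolerance 1e-10 on the log-likelihood.
  Frequencies are floored at 1e-6 and renormalized so no observed genotype
  has zero probability. DyadML is range-constrained to r ∈ [0, 1]; being a
  boundary-constrained ML estimator it is upward-biased by O(1/L) near the
  simplex boundary (≈ +0.05 at r = 0 with 19 loci), which is why mean-bias
  oracles are applied to the moment estimators and DyadML is validated by
  its likelihood oracle and category ordering instead.

**Dyad simulators** draw parents under HWE and produce unrelated,
parent–offspring, half-sib and full-sib pairs by Mendelian segregation;
truth (k₀,k₁,k₂) is recorded. `compare_estimators` scores estimators by
pooled Pearson correlation with true r and per-category mean/variance.

**Group test**: observed per-group R is the mean of within-group pairwise
estimates; the overall statistic averages group means with equal weight
(mirroring the group-shuffling tools; a pair-pooled variant would weight
large groups more). The null shuffles individuals among groups preserving
sizes, 1,000 iterations by default; p = (#null ≥ observed + 1)/(iters + 1).
Per-group p-values compare each group against null group means pooled by
matching size, since no standard defines the per-group null construction.
Groups of size 1 are excluded with a warning.

**Inbreeding**: per-individual F̂ maximizes Πₗ P(genotype | F) with
P(hom i) = F pᵢ + (1−F) pᵢ² and P(het ij) = (1−F) 2pᵢpⱼ, constrained to
[0, 1] (log-likelihood concave; bounded scalar optimization). Group mean F
and a Spearman permutation test against group R are provided.

## Differentiation

Weir–Cockerham θ uses the standard variance components a, b, c per allele
and locus, summed before the ratio. H_S and H_T use the Nei–Chesser
bias corrections with harmonic-mean sample size ñ (including the H_O term).
From the multilocus averages: G_ST = (H_T−H_S)/H_T;
G″_ST = k(H_T−H_S)/((kH_T−H_S)(1−H_S)); D = (k/(k−1))(H_T−H_S)/(1−H_S) with
k = 2 populations. All four are reported side by side because published
"G_ST/D_ST" labels are ambiguous across toolchains. Multilocus combining is
ratio-of-averages throughout. Note the bias-corrected estimators are
deterministically ≤ 0 when two "populations" are literally the same sample
(observed between-population variance is below its sampling expectation);
they converge to 0 for independent samples from one gene pool.

Bootstrap CIs resample individuals within populations, 1,000 replicates,
bias-corrected (BC, not BCa — the simpler default of the R package this
mirrors); significance means the interval excludes zero from below.
Nei's (1972) standard distance D = −ln(J_XY/√(J_X J_Y)) averages the J
identity terms over loci; disjoint allele sets give +∞, flagged. PCoA is
classical metric scaling of the double-centred squared-distance matrix;
negative eigenvalues are reported but excluded from the percent-variance
denominator (the spreadsheet-toolchain convention), and the implementation
is cross-checked against scikit-bio in the tests.

## Effective population size

For each locus pair, over the S individuals typed at both, the Burrows
composite disequilibrium for alleles A, B is
Δ̂ = (S/(S−1))(ΣXY/(2S) − 2p̂_Ap̂_B) with X, Y per-individual allele counts,
and r̂² = Δ̂²/(p̂_A(1−p̂_A)p̂_B(1−p̂_B)). Alleles with frequency < P_crit
(0.02/0.05) are screened out; loci with nothing retained are dropped. The
mean weights each comparison by S (the behaviour of the standard tool with
missing data; an unweighted mean differs only with missingness). The drift
signal is r²′ = mean r̂² − E[r̂²|S], with E = 1/S + 3.19/S² for S ≥ 30 and
0.0018 + 0.907/S + 4.44/S² below; then
N̂e = (1/3 + √(1/9 − 2.76 r²′))/(2r²′) under random mating (0.308/2.08
coefficients for S < 30). Non-positive r²′ or a negative discriminant
reports infinity — drift indistinguishable from sampling noise.

Parametric CIs bound mean r̂² by chi-square and transform the bounds through
the same formula. The degrees of freedom are the number of **locus pairs**,
not the Σ(k₁−1)(k₂−1) allele combinations (which are reported separately as
`n_comparisons`): comparisons within a locus pair share one realization of
drift and are strongly correlated, and Wright–Fisher simulation shows
allele-combination df gives severely anticonservative intervals while
locus-pair df keeps coverage at or above the nominal 95%. This conservative
convention is this package's documented choice; df conventions genuinely
vary across versions of the field-standard software. Jackknife CIs are out
of scope. The age-structure correction divides the point estimate by a
ratio in (0, 1] (defaults 0.74–0.86, from mixed-age samples of long-lived
mammals), and the census inference divides by an Ne/N ratio (default 0.6);
infinity propagates through both.

## Synthetic data

The generators emulate the statistical shape of a multi-year basking-shark
swab survey: 19 dinucleotide loci with allele counts uniform on [3, 18] on
a motif-spaced fragment ladder, Dirichlet(0.35) ancestral frequencies
(chosen so expected heterozygosity averages ≈ 0.66 across that allele-count
range), 407 individuals in 4 populations, and weak structure
(Balding–Nichols at G_ST ≈ 0.01) for the field-survey preset. Structure comes
either from Dirichlet-sampled Balding–Nichols demes (marginally
Beta(p(1−F)/F, (1−p)(1−F)/F) per allele) or a finite-island Wright–Fisher
drift-migration simulation with truth records. Kin groups (2–14 members,
full-sib/half-sib/unrelated) are built from explicit pedigrees over a
supplied frequency table. The error model applies, per single-locus call:
null-allele masking (designated allele; heterozygous carriers appear
homozygous, null homozygotes go missing), allelic dropout of heterozygotes
(larger-allele-biased by default, reflecting amplification failure of
longer fragments), ± one-motif mis-scoring, and whole-call missingness —
every change is logged and the log replays to the exact original. The
Wright–Fisher generator is individual-based (random union of gametes from a
finite parent pool) because the between-locus LD that the Ne estimator
measures only arises from the shared, finite pedigree; per-locus frequency
simulation would produce none.

What the simulations do *not* emulate: mutation (timescales are tens of
generations), overlapping generations and age structure, linked loci,
selection, spatially continuous sampling, and real allele-binning noise.
Passing tests therefore demonstrate correctness of the estimators under
their own model assumptions, not robustness to the violations (age
structure, mixture sampling) that real surveys face — those are handled by
the explicit correction factors and by study design, not by the estimators.

## Problem sizes and determinism

Every stochastic routine takes an explicit seed and is a pure function of
(inputs, config, seed); the pipeline writes byte-identical reports on
rerun. The validation suite uses simulation sizes chosen to make its checks
statistically decisive at comfortable margins: ≥ 5,000 dyads per pedigree
category for estimator bias (3·SE ≈ 0.006), 1,000 replicate datasets for
permutation-test and LD-test calibration (binomial 95% band ≈ ±0.014 around
0.05), 200 replicates for Balding–Nichols θ and Wright–Fisher Ne recovery,
and 100-replicate versions of the same computations in the acceptance
script.

## Known limitations

- Near matches beyond 3 mismatching loci are flagged for human review, not
  auto-resolved.
- The LD-Ne small-S (< 30) expectation and the locus-pair df convention are
  this package's documented choices; other implementations differ at the
  margins.
- DyadML reports the ML point; no profile-likelihood intervals.
- G_ST-family estimators are reported jointly; which variant a given
  published number used is generally unrecoverable.
- PCoA percent variance ignores negative eigenvalues; strongly non-Euclidean
  distance matrices will understate distortion.
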