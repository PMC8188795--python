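# Methods

This note documents the statistical models behind `ssrhyb`, the defaults
they ship with, what the synthetic-data generator does and does not
emulate, and the numerical choices a maintainer should know about.

## Data model

Genotypes are diploid, co-dominant allele codes at unlinked microsatellite
loci. Allele codes are labels: no size ordering, binning or mutation model
is assumed anywhere. Missing is a property of the whole call; a
half-missing call (one allele read) is treated as fully missing, since a
single read cannot be attributed to a genotype class under the null-allele
observation model. Each individual carries a population code that maps to
exactly one species and one site (the `SITE-SPECIES` convention, e.g.
`BY-A`, or an explicit mapping).

## Diversity statistics

Per locus and group: N_A; N_E = 1/Σp²; H_O as the heterozygote fraction of
non-missing calls; unbiased H_E = (2n/(2n−1))(1−Σp²); PIC
= 1 − Σp² − Σ_{i<j} 2p²_i p²_j; H_S as the across-population mean of
unbiased within-population diversity (reported on the pooled rows).
Allelic richness uses hypergeometric rarefaction,
A_R = Σ_a [1 − C(N−N_a, g)/C(N, g)], with the baseline **g = 20 gene
copies** (10 diploid individuals, the FSTAT convention); cells for groups
smaller than g/2 individuals are reported undefined rather than
extrapolated. A_R is non-decreasing in g and equals N_A at g = N.

HWE and LD are tested by permutation rather than Markov-chain exact
tests: same null hypotheses, simpler machinery, and the calibration is
directly checkable (rejection at the 5% level stays within [0.03, 0.08]
under simulated nulls). The HWE statistic is the within-population
inbreeding estimate f = 1 − H_O/H_E with a two-sided p-value from
re-pairing the 2n sampled allele copies into random diploids; LD uses the
G statistic on the two-locus genotype table with one locus permuted
across individuals. All permutation p-values use the add-one correction
(b+1)/(n_perm+1). The level for the all-pairs LD screen is α/C(L, 2)
(0.000368 for 17 loci at 5%).

## Null-allele models

The observation model throughout: a true heterozygote (i, j) is observed
as is; a true (i, null) as the apparent homozygote (i, i); a true
(null, null) as missing; independently, any call fails with probability
b.

**EM estimator** (per locus × population, f = b = 0): the E-step
attributes a fraction 2p_iπ/(p²_i + 2p_iπ) of each apparent-homozygote
class to (i, null) and all structural missing to (null, null); the M-step
renormalizes expected allele-copy counts. The log-likelihood is asserted
non-decreasing every iteration; convergence at a maximum frequency change
below 1e−8. The estimate matches an independent numerical ML fit within
2e−3 on small datasets.

**Bayesian n/f/b model**: per-locus null frequencies π_l, one
population-level inbreeding coefficient f and one failure rate b, with
flat priors (Dirichlet(1) jointly over visible frequencies and π per
locus; Uniform(0,1) for f and b). The sampler augments each call with its
latent state (identical-by-descent or not; carrying a null copy or not; a
failure or not), which makes every conditional conjugate: Dirichlet
updates for (p, π), Beta updates for f and b. An IBD genotype contributes
one independent allele copy, an outbred genotype two. DIC = D̄ + p_D with
p_D = D̄ − D(posterior means); the full model is compared against the
reduced fb model (π ≡ 0), differences under 2 reported as
indistinguishable. The posterior mean of f under the full model is the
corrected inbreeding coefficient F_IS′. Default chain lengths are
20,000/2,000/10 (iterations/burn-in/thinning) — pipeline and tests run
shorter chains; program-scale lengths (500k/50k/50) are a config choice.

Using a single population-level f rather than individual inbreeding
coefficients is a deliberate simplification: at n ≈ 30 per population
only the population mean is identifiable, and that is what gets
reported.

**Identifiability caveat**: if π were constant across all loci, (π, f, b)
would sit on an exact likelihood ridge (a homozygote excess f′ and
rescaled frequencies reproduce the same observed distribution, with b
absorbing the missing), and no estimator could separate them.
Identification comes from locus-to-locus variation in π while f and b are
shared — which real SSR panels show and the generator reproduces. Tests
exercise the model under locus-varying π for this reason.

**Locus screening** keeps a locus iff max π̂ < 0.2 AND mean π̂ < 0.1
across populations (both strict).

## Differentiation

Weir–Cockerham θ uses the multi-allelic variance components a, b, c per
allele and locus; the global estimate is the ratio of summed components
(never a mean of per-locus ratios), and f (F_IS) falls out of the same
sums. Monomorphic loci contribute zero components; negative estimates are
reported as-is.

The ENA ("exclusion null alleles") correction takes the EM output and
rebuilds complete-data inputs with the null class as a hidden allele: the
sample size becomes all individuals (structural missing are the null
homozygotes), visible-allele frequencies come from the EM, and each
visible allele's heterozygote frequency is augmented by the expected
2p_aπ hidden (a, null) genotypes. Components are then summed over visible
alleles only. When π̂ = 0 the correction is the identity. On simulations
with π = 0.2 the corrected estimate is closer to the pre-observation
truth than the uncorrected one in essentially every replicate (the
uncorrected θ is inflated by the apparent loss of heterozygosity). 95%
CIs for both come from a percentile bootstrap over loci (resampling loci
with replacement).

G_ST is computed from unbiased H_S (mean within-population diversity) and
H_T (pooled-sample diversity); G′_ST = G_ST(s−1+H_S)/[(s−1)(1−H_S)].
Gene flow offers both printed conventions:
N_m = (1−F_ST)/(4F_ST) (Wright) and N_m = 0.5(1−G_ST)/G_ST. The two do
not reproduce each other's values from the same input — both are exposed
and the caller picks the formula; nothing is reconciled silently.

Pairwise θ over all population pairs feeds two consumers: stratified
means (same site + different species = sympatric heterogeneous; different
site + same species = allopatric homologous; different site + different
species = allopatric heterogeneous; same site + same species cannot occur
in the supported design and is asserted against), and PCoA via Gower
double-centering of −½D∘D with negative eigenvalues reported but excluded
from the explained-variance percentages.

## AMOVA

Squared inter-individual distance = allele differences per locus (0, 1
or 2) summed over loci both individuals have typed, rescaled by
total/shared loci so that missingness does not shrink distances. Sums of
squares come from within-partition pairwise-distance sums; variance
components solve the mean-square equations with unequal-size
coefficients. F_CT permutes whole populations among groups, F_SC permutes
individuals among populations within groups, F_ST permutes individuals
among all populations. Negative components are retained and flagged.
Note the F_CT permutation space is coarse when there are few populations
(C(P, P/2) distinct assignments); with fewer than ~8 populations the test
cannot reach the 5% level at all.

## Clustering

Nei's (1978) unbiased distance with the (2nΣp²−1)/(2n−1) within-
population bias correction, J-terms averaged over loci; an infinite
distance (zero shared identity) is flagged and never capped — the caller
decides. Individual-level distance is the allele-sharing distance
1 − shared/(2·shared loci), the standard individual-level analogue of a
population genetic distance on co-dominant markers (an alternative
binary presence/absence encoding over all observed alleles gives nearly
identical trees and is not separately implemented). NJ trees come from scikit-bio; trait dendrograms standardize
columns (constant columns dropped with a note), use Euclidean distance
and average linkage by default (single/complete available). Partition
agreement uses the adjusted Rand index.

## Admixture

The Gibbs sampler implements the admixture model with uncorrelated
cluster frequencies: latent origin Z per allele copy ∝ q_ik·p_kla;
P | Z ~ Dirichlet(λ + counts) with λ = 1; Q_i | Z ~ Dirichlet(α + copy
counts); missing copies skipped. ln P(X|K) is estimated as
mean(lnL) − var(lnL)/2 over post-burn-in sweeps, and K is selected by
Evanno's ΔK = |mean L(K+1) − 2 mean L(K) + mean L(K−1)| / sd L(K) over
replicate runs (interior K only; the fallback when ΔK is undefined
everywhere is max mean L).

**α is fixed at 0.5 by default, not inferred.** Inferring a single shared
α (Metropolis with uniform prior, available via `infer_alpha=True`)
collapses toward zero whenever most sampled individuals are purebred;
the resulting Dirichlet(α→0) prior is a sparsity prior that pushes
admixed individuals' q toward the corners and systematically misclassifies
backcrosses (q ≈ 0.75 estimated as > 0.9). A fixed symmetric
Dirichlet(0.5) is diffuse enough not to manufacture admixture in
purebreds (their q̂ stays > 0.9) while leaving backcross q̂ essentially
unbiased; on the generator's study conditions this choice recovers F1 at
≥ 80%, backcrosses at ≥ 70% and purebreds at ≥ 90% specificity, which α
inference does not.

Replicate runs are aligned by minimizing the summed squared difference
between Q matrices and an incrementally built reference. That objective
decomposes per cluster column, so the Hungarian assignment gives the
exact optimal permutation at any K — no exhaustive search or greedy
fallback is needed.

Default chain lengths (1,000 burn-in / 2,000 sweeps) are desk-scale;
program-scale runs (500k/500k, 20 replicates, K = 1–9) are configuration,
not code.

## Hybrid classification

With q_max the largest ancestry: q_max > 0.9 purebred; 0.6 < q_max ≤ 0.9
backcross toward that cluster; otherwise F1 between the top two clusters
— except that three or more ancestries each above 0.1 make a trihybrid
regardless of q_max. The F1 band is nominally [0.4, 0.6]; with K = 2 the
band below 0.4 is unreachable, and with K ≥ 3 a sub-0.4 q_max almost
always triggers the trihybrid rule first, so the residual case falls to
F1 (the nearest class). All four thresholds are configurable.
Rates are computed at full precision and rounded only for display
(2 decimals); aggregation is exact, so per-population NH sums equal
per-species and overall NH.

## Synthetic data

The generator emulates the study design end to end: per-locus base
frequencies ~ Dirichlet(1) over ~21 alleles; species frequencies
~ Dirichlet(c·base) (Balding–Nichols style, F ≈ 1/(1+c); default c = 8
gives realized θ ≈ 0.10 on purebreds, c = 4 gives θ ≈ 0.15–0.2;
`calibrate_divergence` bisects c for a target θ); per-species, per-locus
null frequencies Uniform(0, 0.2) by default; F1 (one copy per parent
pool), gametic backcross (second copy from either parent with probability
1/2 per locus, loci independent) and trihybrid crosses; purebred
inbreeding as whole-locus IBD with probability f; failure as missingness
with probability b. The bundled study preset reproduces the 10-population
layout (BY-A 31, BY-V 29, LT-F 38, LT-B 22, ZW-V 30, ZW-B 30, ZJ-A 30,
ZJ-V 30, ZJ-F 33, ZJ-B 27; 300 individuals). Truth labels carry ancestry
vectors, class labels and pre-observation genotypes.

What the generator does **not** emulate: linkage between loci, mutation
models (SMM/IAM), spatial structure or pollen-dispersal kernels, allele
size homoplasy, and locus-specific amplification quality beyond the null
frequency. Passing recovery tests on this generator therefore shows the
estimators do the right thing under the model's own assumptions — it
does not certify performance on panels with strong LD or size homoplasy.

## Problem sizes and seeds

Everything stochastic flows from integer seeds through named child
streams (CRC32-hashed stage keys via `child_rng`), so stages are
individually reproducible and pipeline stages never perturb each other's
draws. The test and acceptance experiments use deliberately moderate
sizes — e.g. permutation calibrations at 300–500 replicates × 200
permutations, EM recovery at 200 replicates of n = 50 × 17 loci,
admixture recovery at 5 seeds × 3 replicate chains of 1,500–2,000 sweeps
— chosen so the full battery completes in minutes on one CPU while
leaving the binomial error on each calibration rate well inside its
acceptance band.

## Known limitations

* The nfb model reports a population-level f only; individual-level
  inbreeding variation is out of scope.
* ENA correction quality degrades if the EM's HWE assumption is badly
  violated within populations (strong Wahlund effect).
* The admixture sampler implements the uncorrelated-frequencies prior
  only; correlated frequencies (better for very recently diverged
  clusters) and LOCPRIOR are not implemented.
* Evanno's ΔK cannot, by construction, select K = 1 or K = K_max.
* NJ ties are resolved by scikit-bio's internal order; on non-additive
  matrices with exact ties the topology may depend on label order.
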