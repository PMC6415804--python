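# Methods

This note documents the models behind each module, the defaults that
matter, the numerical choices, and what the synthetic-data experiments do
and do not demonstrate.

## Genotype model

A genotype is an unordered pair of positive integer allele labels
(fragment sizes or repeat counts); a genotype is observed with both copies
or not at all — half-calls are promoted to missing at parse time, because
every estimator downstream assumes 0 or 2 gene copies per individual and
locus. Statistics treat labels as opaque; only the mutation models
interpret them as repeat counts. GenePop files carry no population names,
so labels default to the last individual name per `POP` block (the format
convention) unless supplied explicitly.

## Diversity statistics

* Gene diversity uses Nei's unbiased estimator `n/(n−1)·(1 − Σpᵢ²)`
  (`unbiased=False` gives the plug-in variant).
* `F_IS = 1 − mean(H_O)/mean(H_E)` is a ratio of across-locus means, not a
  mean of per-locus ratios; the variance-components alternative is the
  Weir–Cockerham `b/(b+c)` available from the structure module.
* Allele and private-allele counts (`A`, `PA`) are totals across loci;
  allelic richness is the across-locus mean of the hypergeometric
  rarefaction `Σᵢ [1 − C(n−nᵢ,g)/C(n,g)]`, standardised by default to
  `g = 2 × (smallest sample size)` gene copies, clamped to the smallest
  per-cell copy count when data are missing. Alleles whose remaining
  complement is smaller than `g` contribute exactly 1.
* The HWE test is a Monte-Carlo exact test: the statistic is the
  conditional (Levene) probability of the genotype table given the allele
  counts, with null tables generated by re-pairing the observed gene
  copies. The LD test is a permutation G-test on the two-locus genotype
  contingency table — the software the field uses for this step does not
  document its exact variant, so reports flag the G-test explicitly. The
  H_E comparison reassigns individuals between the two populations.
* Every Monte-Carlo p-value uses `(1 + #{null ≥ obs})/(1 + n_perm)`, so
  p = 0 never occurs; with `n_perm = 199` and rejection at `p ≤ 0.05` the
  tests are exactly sized for continuous statistics (verified empirically
  in the acceptance suite at 500 null replicates per test).

## Null alleles

The EM treats each apparent homozygote class i/i as a mixture of true
i/i and i/null heterozygotes under HWE, and blanks as null homozygotes.
Two blank conventions exist because non-amplification is indistinguishable
from failed PCR in real data: `blanks="null_homozygote"` counts blanks as
null/null; the default `blanks="marginalize"` treats them as unknown and
handles the truncated likelihood by imputing the expected number of
unobserved null homozygotes each E-step (`n_obs·r²/(1−r²)`) — without that
imputation the fixed point is not the conditional MLE. The observed-data
log-likelihood is recorded per iteration and is non-decreasing (asserted
in tests). Convergence: `|Δr| < 1e-8`, at most 10,000 iterations.

At n = 100 individuals and five visible alleles the information bound for
the null frequency is `sd(r̂) ≈ 0.033`, so roughly 1-in-7 estimates fall
outside ±0.05 of the truth even for an efficient estimator; the recovery
tests are written with that bound in mind. Estimates on partially selfing
populations are inflated: the EM attributes any inbreeding-driven
homozygote excess to nulls. This is a property of the HWE assumption
shared with the standard tools, and it is visible in the synthetic study
(planted mean rate ≈ 0.12, estimated ≈ 0.3 at F_IS ≈ 0.5).

The ENA-corrected F_ST recomputes Weir–Cockerham components with the null
treated as an extra allele at its estimated frequency per population and
then excludes the null class from the numerator and denominator sums;
with all `r = 0` it reduces exactly to the uncorrected estimator. Loci
with `r ≥ 0.9` in either population of a pair are dropped with a warning.

## F-statistics and AMOVA

Pairwise F_ST is Weir & Cockerham's θ: per-locus, per-allele components
a (among populations), b (among individuals within), c (within
individuals), combined multilocus as Σa/Σ(a+b+c). Small negative values
are preserved, never clipped.

AMOVA is locus-by-locus on gene copies with the 0/1 identity metric by
default (the F_ST analogue; squared repeat-count difference gives the
R_ST analogue behind `metric="rst"`). The sum of squares of a set equals
the sum of squared deviations of one-hot allele coordinates from the set
centroid, which is how both the implementation and the independent test
oracle compute it (the oracle via explicit pairwise distances). Because
every individual carries exactly 2 copies, the expected-mean-square
coefficients are `E[MS_within] = σ_c²`, `E[MS_among-ind] = σ_c² + 2σ_b²`,
`E[MS_among-group] = σ_c² + 2σ_b² + n_c·σ_a²` with the standard unbalanced
`n_c`, averaged across loci when missingness unbalances them. Negative
components are reported as-is and percentages computed on the raw
components. Permutation p-values: whole individuals among groups for the
among-group component; re-pairing gene copies within groups for the
among-individual component.

PCoA double-centres `−D²/2` and reports negative eigenvalues rather than
dropping them; coordinate axes use the positive ones. The
individual-level distance is Euclidean on allele dosage vectors (0/1/2
per allele, missing imputed to the locus mean) — the metadata of every
PCoA export records this choice, since "Euclidean" alone underdetermines
it. Mantel permutes rows/columns of the second matrix simultaneously and
is two-sided on |r|; geographic distances are haversine great circles on
region centroids by default.

## Admixture clustering

The Gibbs sampler follows the classic admixture model: each gene copy
carries a latent cluster assignment z sampled ∝ q_ik·p_k,l,a; cluster
allele frequencies get Dirichlet(λ + counts) updates with λ = 1
(uncorrelated-frequencies prior); individual ancestries get
Dirichlet(α + counts); α takes Metropolis random-walk steps (sd 0.1)
under a uniform prior on (0, 10]. Missing copies are skipped. An optional
mode makes α population-specific using the sampling-island labels — a
weak analogue of the location-prior variant, off by default because the
island-level structure is recoverable without it. `lnP` is the mean
post-burn-in log-likelihood `Σ ln Σ_k q_ik p_k,l,a`; Evanno's
`ΔK = |L(K+1) − 2L(K) + L(K−1)|/sd(L(K))` is computed over replicate
runs, with sd = 0 flagged as ∞. Replicate runs are aligned by greedy
column matching maximising ΣQ·Q′ (exact for the well-separated runs it is
used on; verified against exhaustive search for K ≤ 4). Test-scale runs
use 2,500–5,000 sweeps with 500–1,000 burn-in — the production-scale
analyses this emulates use hundreds of times more, but the planted-K
experiments here mix well at desk scale (stationarity is checked by a
thinned two-window comparison of the likelihood trace).

## Coalescent simulator

Backward-time structured coalescent in continuous time: within an epoch a
population with k lineages coalesces at rate C(k,2)/(2N) (N diploid);
founding events move lineages into their source (or split them between
two sources with probability r_a for admixture); a founder bottleneck
holds the population at N_b for the d_b generations after founding
(clipped at the founding time). Waiting times for a whole epoch are drawn
in one vectorised batch. Mutations are Poisson on branch lengths; SMM
steps are ±1, TPM draws single steps with probability `p_single` (default
0.9) and geometric multi-step jumps with mean 2.8 otherwise — the
standard software's defaults, stated prominently because the analyses
this package emulates never document them. Allele states are unbounded
integers anchored at 100 repeats (shifted, never wrapped, in the rare
event a label would fall below 1 — statistics are label-agnostic). The
simulator is validated against the Kingman expectations for tree height
(cross-checked against an independent coalescent implementation) and
total length `4N·Σ_{i=1}^{k−1} 1/i`, and against the SMM equilibrium gene
diversity `1 − 1/√(1+2θ)`.

The 14-scenario space: each of the three islands in turn as the ancestral
population, the other two founded by introductions at t2 (from the
ancestor) and t1 ≤ t2 (from the ancestor or from the first-founded
island) — 12 scenarios — plus two in which the central island is founded
at t1 by admixture of the other two, whose own founding order differs.
Every introduction carries a founder bottleneck. Priors are uniform
10.0–10000.0 for sizes, times and the (shared) bottleneck duration, and
uniform 0.001–0.999 for the admixture rate, with (t1, t2) redrawn until
t2 ≥ t1. Per-locus mutation rates are drawn uniformly from 1e-4–1e-3 in
reference tables (recorded in table metadata); the per-event-duration
variant of d_b sits behind a flag.

## ABC

Summaries are the nine statistics per dataset: per-island mean allele
number and mean gene diversity across loci, and the three pairwise F_ST
(non-finite θ from monomorphic comparisons conventionally 0). Rejection
normalises by the reference table's per-statistic MAD (sd fallback) and
keeps the `⌈tolerance·rows⌉` nearest rows with a floor (default 500).
Scenario posteriors come from an Epanechnikov-weighted multinomial
logistic regression of the scenario label on the summary deviations,
evaluated at deviation zero, falling back to retained-row proportions if
the fit degenerates (flagged in the result). Parameter posteriors use
Beaumont-style weighted local-linear adjustment on the log scale for
positive parameters, with the rejection posterior returned (flagged) when
the design is rank-deficient.

Scenario discrimination across all 14 topologies under the full priors is
intrinsically weak: most prior draws are old or equilibrated and leave no
topological trace in the nine summaries, so the 14-way recovery rate
hovers near 20–30% at desk-scale tables regardless of classifier. The
recovery experiment the package therefore reports is the two-model
confidence check: the serial-introduction history with strong founder
bottlenecks (10–100 colonisers) versus the same topology without
bottlenecks — a contrast the summaries do carry — where the true model is
recovered for ≳85% of pseudo-observed datasets at a 5,000-row table.

## Bottleneck tests

After a collapse, allele numbers drop faster than gene diversity, leaving
a transient heterozygosity excess relative to the equilibrium expectation
for the observed allele count k; an expansion leaves a deficiency. The
conditional distribution of gene diversity given k is simulated: one
mutation-drift parameter θ per population is fitted by bisection so the
simulated mean allele count matches the across-locus mean, and replicates
realising exactly k alleles are retained per locus (per-locus θ re-tuning
is the fallback when acceptance collapses). Fitting θ per population
rather than per locus matters: E[H|k] increases with θ, so per-locus
re-tuning biases the conditional mean low for below-average k and
inflates the excess tail (type-I ≈ 0.13–0.15 at α = 0.05 in our
calibration runs).

Because H|k is left-skewed, Wilcoxon signed-rank on mean-centred
differences is miscalibrated even with an unbiased centre. The default
input is therefore the probability-integral transform: each locus'
observed gene diversity is converted to its mid-quantile u within the
simulated conditional distribution, and the test is run on u − ½, which
is symmetric-uniform under equilibrium — giving empirical type-I of
0.05–0.07 per tail at α = 0.05 (200 equilibrium replicates, both SMM and
TPM). The classic mean-centred convention of the original method remains
available (`center="mean"`), and the standardized difference DH is
reported per locus either way. The signed-rank null is enumerated exactly
by dynamic programming for ≤25 untied differences, with a
continuity-corrected normal approximation (tie-corrected variance)
otherwise; zeros are dropped.

Power of the calibrated excess test is modest by nature: across a scan of
99%-collapse designs (timing 10–160 generations, ancestral θ 5–40,
samples 30–60, both mutation models) it peaks near 40–50% with 11 loci —
the apparent extra power of the uncorrected variant is inflation of the
test level, not signal.

## Synthetic study generator

The generator emulates the survey design: serial-introduction demography
(ancestral San Cristóbal seeds Isabela at t2 = 120 generations, Isabela
seeds Santa Cruz at t1 = 35, founder sizes ≤ 50), present sizes
N = 100/2000/800 (Isabela/Santa Cruz/San Cristóbal), mutation rate 7e-4,
then five rounds of partial-selfing reproduction (rates 0.67/0.59/0.36,
equilibrium F_IS = s/(2−s)), null-allele injection (per-locus rates
uniform on 0–0.25; a random set of allele lineages totalling ≈ the rate
is relabelled null: visible/null pairs become apparent homozygotes,
null/null becomes missing) and 2% missing genotypes. These constants were
fixed once against the survey's reported magnitudes and live in the
config, not in logic. Selfing is applied after the coalescent rather than
inside it so that demographic and mating-system ground truths stay
independent.

What the defaults reproduce: per-island gene diversity ≈ 0.28–0.45,
F_IS ≈ 0.35–0.65, total allele counts ≈ 23–31 per island, and the
most-distant island pair (Isabela–San Cristóbal) carrying the largest
F_ST in the clear majority of seeds. What they do not: the absolute F_ST
level runs ≈ 0.15–0.28, somewhat above the survey's 0.07–0.21, because
under a strictly serial topology the central island inherits all of the
first-founded island's pre-split drift — keeping the distant pair largest
forces extra post-split drift onto the first island. Passing tests on
this generator demonstrate internal consistency of estimators, tests and
recovery machinery under a realistic mixed-mating SSR regime; they say
nothing about genotyping artefacts beyond nulls/missingness (no stutter,
no large-allele dropout) or about spatial structure within islands.

## Problem sizes

Test- and script-scale experiments use deliberately reduced sizes chosen
as desk-scale analogues of the production analyses they emulate:
reference tables of a few thousand rows (versus millions), MCMC runs of a
few thousand sweeps (versus 10⁶), and 200–800 conditional replicates per
bottleneck locus. Every stochastic experiment is seeded and reproducible.
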