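# guavapop

Population-genetic reconstruction of island invasion histories from
microsatellite (SSR) genotypes.

The motivating system is the common guava (*Psidium guajava*), an
aggressive invader of the Galápagos archipelago sampled on three inhabited
islands — Isabela, Santa Cruz and San Cristóbal — at 11 polymorphic SSR
loci. The package implements the complete analysis chain such a survey
needs, as one tested library:

* **Diversity and inbreeding** — allele counts and private alleles,
  rarefied allelic richness `AR = Σᵢ [1 − C(n−nᵢ,g)/C(n,g)]`, observed
  heterozygosity, Nei's unbiased gene diversity
  `H_E = n/(n−1)·(1 − Σpᵢ²)`, and `F_IS = 1 − H̄_O/H̄_E`, plus
  Monte-Carlo exact HWE tests, permutation G-tests of linkage
  disequilibrium, Monte-Carlo H_E comparisons and Bonferroni correction.
* **Null alleles** — EM estimation of per-locus null frequencies (apparent
  homozygote classes treated as mixtures of true homozygotes and
  visible/null heterozygotes under HWE) and ENA-corrected pairwise F_ST.
* **Structure** — Weir–Cockerham θ (per-allele variance components a, b,
  c; multilocus θ = Σa/Σ(a+b+c)), Nei's (1972) standard distance,
  locus-by-locus AMOVA over islands / individuals / gene copies with
  permutation inference, PCoA with negative-eigenvalue reporting, Mantel
  tests, and haversine geographic distances.
* **Admixture clustering** — a Gibbs sampler for the classic admixture
  model (latent cluster assignment per gene copy, Dirichlet updates for
  allele frequencies and individual ancestry, Metropolis update of the
  concentration α), Evanno's ΔK = |L″(K)|/sd(L(K)) for choosing K, and
  CLUMPP-style greedy alignment of replicate runs.
* **Coalescent simulation** — backward-time structured coalescent for the
  14-scenario colonisation space of a three-island system (one ancestral
  island and two founder-bottlenecked introductions, or an admixed origin
  of the central island), with stepwise (SMM) and two-phase (TPM)
  microsatellite mutation.
* **ABC model choice** — reference tables of summary statistics
  (per-island mean allele number and gene diversity, pairwise F_ST),
  MAD-normalised rejection, Epanechnikov-weighted multinomial logistic
  regression for scenario posterior probabilities, and local-linear
  adjusted parameter posteriors.
* **Bottleneck tests** — heterozygosity-excess/deficiency tests comparing
  each locus' gene diversity with its simulated equilibrium distribution
  conditional on the observed allele count, combined across loci by
  Wilcoxon signed-rank tests (exact null for ≤25 untied loci).
* **Synthetic data** — a study-emulating generator (3 islands of 95/80/94
  individuals, 11 loci, serial-introduction demography, partial selfing,
  null alleles, missing data) with full ground-truth records, so every
  stage is testable without any external dataset.

## Worked example

```python
from guavapop.synthetic_data import StudyEmulationConfig, generate_study_like
from guavapop.diversity import diversity_table
from guavapop.structure_stats import pairwise_fst

gm, truth = generate_study_like(StudyEmulationConfig(seed=1))
print(diversity_table(gm).table.round(3)[["N", "A", "AR", "H_O", "H_E", "F_IS"]])
print(pairwise_fst(gm).values.round(3))
```

```
           N   A     AR    H_O    H_E   F_IS
pop                                         
ISA       95  23  2.056  0.156  0.353  0.558
SCZ       80  28  2.545  0.200  0.445  0.551
SCY       94  30  2.698  0.266  0.413  0.355
overall  269  36  3.175  0.208  0.470  0.557
[[0.    0.15  0.259]
 [0.15  0.    0.188]
 [0.259 0.188 0.   ]]
```

Reading: each island keeps 23–30 alleles over the 11 loci; gene diversity
(0.35–0.45) well above observed heterozygosity gives the high inbreeding
coefficients (F_IS 0.36–0.56) expected for a partially selfing tree with
null alleles; and the two islands at the opposite ends of the archipelago
(Isabela and San Cristóbal, rows 1 and 3) are the most differentiated pair
(F_ST = 0.259), the qualitative signature of a serial introduction with
continued drift on the first-founded island.

The command-line interface wraps the same functions
(`guavapop --seed 1 synth`, `guavapop diversity data.gen`,
`guavapop cluster data.gen --k 1-5`, `guavapop all`, ...).

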