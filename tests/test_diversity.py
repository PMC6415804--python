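import numpy as np
import pytest

from guavapop.diversity import (
    allelic_richness,
    bonferroni,
    count_alleles,
    diversity_table,
    fis,
    gene_diversity,
    he_difference_test,
    hwe_test,
    individual_inbreeding,
    ld_test,
    observed_heterozygosity,
    private_alleles,
)
from guavapop.genotypes import GenotypeMatrix, allele_frequencies
from tests.conftest import hwe_population


def brute_force_ho(gm, pop, locus):
    j = gm.loci.index(locus)
    het = tot = 0
    for i in range(gm.n_individuals):
        if gm.pop[i] != pop:
            continue
        a, b = gm.alleles[i, j]
        if a < 0:
            continue
        tot += 1
        het += a != b
    return het / tot


def brute_force_he(gm, pop, locus):
    j = gm.loci.index(locus)
    copies = []
    for i in range(gm.n_individuals):
        if gm.pop[i] == pop:
            a, b = gm.alleles[i, j]
            if a > 0:
                copies += [a, b]
    n = len(copies)
    ssq = sum((copies.count(u) / n) ** 2 for u in set(copies))
    return n / (n - 1) * (1 - ssq)


class TestAlleleCounts:
    def test_frequency_threshold_splits_rare_and_common(self):
        gm = GenotypeMatrix(
            individuals=[f"i{k}" for k in range(50)], loci=["L1"],
            alleles=np.array([[[1, 1]]] * 44 + [[[1, 2]]] * 4 + [[[1, 3]]] * 2),
            pop=np.array(["P"] * 50, dtype=object))
        aft = allele_frequencies(gm)
        # freqs: 1 -> 0.94, 2 -> 0.04, 3 -> 0.02
        assert count_alleles(aft, "P", 0.05) == (3, 1)
        assert count_alleles(aft, "P", 0.0) == (3, 3)

    def test_totals_match_brute_force_recount(self, rng):
        gm = hwe_population(rng, [0.5, 0.3, 0.1, 0.06, 0.04], n=60, loci=11)
        aft = allele_frequencies(gm)
        a, a_freq = count_alleles(aft, "P", 0.05)
        exp_a = exp_f = 0
        for locus in gm.loci:
            for al, f in aft.freqs[(locus, "P")].items():
                exp_a += 1
                exp_f += f > 0.05
        assert (a, a_freq) == (exp_a, exp_f)


class TestPrivateAlleles:
    def test_allele_in_one_population_is_private_there(self, toy_matrix):
        aft = allele_frequencies(toy_matrix)
        pa = private_alleles(aft, 0.05)
        # L1: pop A holds {1,2,3}? A: individuals 0-2 -> alleles {1,2}; B: {1,3}
        # allele 2 private to A; allele 3 private to B
        assert pa["A"][0] >= 1 and pa["B"][0] >= 1

    def test_shared_allele_private_nowhere(self):
        gm = GenotypeMatrix(individuals=["a", "b"], loci=["L1"],
                            alleles=np.array([[[1, 1]], [[1, 1]]]),
                            pop=np.array(["A", "B"], dtype=object))
        pa = private_alleles(allele_frequencies(gm))
        assert pa["A"] == (0, 0) and pa["B"] == (0, 0)

    def test_single_population_is_an_error(self):
        gm = GenotypeMatrix(individuals=["a"], loci=["L1"],
                            alleles=np.array([[[1, 2]]]),
                            pop=np.array(["A"], dtype=object))
        with pytest.raises(ValueError):
            private_alleles(allele_frequencies(gm))

    def test_planted_private_allele_counts_recovered(self, rng):
        # plant 3 private alleles in pop A, one of them common
        gm = hwe_population(rng, [0.5, 0.5], n=40, pops=("A", "B"), loci=1)
        alleles = gm.alleles.copy()
        alleles[0] = [[11, 11]]          # rare private (freq 2/80)
        alleles[1] = [[12, 13]]
        alleles[2:14, 0, :] = 14         # common private (freq 24/80 > 0.05)
        gm2 = GenotypeMatrix(individuals=list(gm.individuals), loci=gm.loci,
                             alleles=alleles, pop=gm.pop)
        pa = private_alleles(allele_frequencies(gm2), 0.05)
        assert pa["A"][0] == 4 and pa["A"][1] == 1


class TestAllelicRichness:
    def test_full_sample_returns_observed_count(self, toy_matrix):
        sub = toy_matrix.by_population("A")
        table, _ = allelic_richness(sub, g_copies=6)
        assert table.loc["L1", "A"] == pytest.approx(2.0, abs=1e-12)

    def test_single_draw_yields_one_allele(self, toy_matrix):
        table, _ = allelic_richness(toy_matrix, g_copies=1)
        assert np.allclose(table.to_numpy(dtype=float), 1.0)

    def test_small_case_matches_resampling_oracle(self, rng):
        # one locus, n=6 copies with counts (3,2,1), rarefied to g=4
        alleles = np.array([[[1, 1]], [[1, 2]], [[2, 3]]])
        gm = GenotypeMatrix(individuals=["a", "b", "c"], loci=["L1"],
                            alleles=alleles, pop=np.array(["P"] * 3, dtype=object))
        table, _ = allelic_richness(gm, g_copies=4)
        pool = np.array([1, 1, 1, 2, 2, 3])
        keys = rng.random((100_000, 6)).argsort(axis=1)[:, :4]
        draws = pool[keys]
        n_distinct = (np.sort(draws, axis=1)[:, 1:] != np.sort(draws, axis=1)[:, :-1]).sum(axis=1) + 1
        assert table.loc["L1", "P"] == pytest.approx(n_distinct.mean(), abs=0.02)

    def test_monotone_in_subsample_size(self, rng):
        gm = hwe_population(rng, [0.4, 0.3, 0.2, 0.1], n=30, loci=5)
        means = [allelic_richness(gm, g)[1].iloc[0] for g in (2, 6, 12, 30, 60)]
        assert all(b >= a - 1e-12 for a, b in zip(means, means[1:]))

    def test_oversized_subsample_rejected(self, toy_matrix):
        with pytest.raises(ValueError):
            allelic_richness(toy_matrix, g_copies=7)


class TestHeterozygosity:
    def test_observed_het_is_fraction_of_heterozygotes(self):
        gm = GenotypeMatrix(individuals=["a", "b"], loci=["L1"],
                            alleles=np.array([[[1, 2]], [[1, 1]]]),
                            pop=np.array(["P", "P"], dtype=object))
        per_locus, mean = observed_heterozygosity(gm)
        assert per_locus["L1"] == 0.5 and mean == 0.5

    def test_all_homozygous_gives_zero(self, rng):
        gm = hwe_population(rng, [1.0], n=10, loci=2)
        assert observed_heterozygosity(gm)[1] == 0.0

    def test_matches_brute_force(self, toy_with_missing):
        for pop in ("A", "B"):
            per_locus, _ = observed_heterozygosity(toy_with_missing, pop)
            for locus in toy_with_missing.loci:
                assert per_locus[locus] == pytest.approx(
                    brute_force_ho(toy_with_missing, pop, locus), abs=1e-12)

    def test_gene_diversity_monomorphic_zero(self, rng):
        gm = hwe_population(rng, [1.0], n=10, loci=2)
        assert gene_diversity(gm)[1] == 0.0

    def test_gene_diversity_closed_form_two_alleles(self, rng):
        alleles = np.concatenate([np.full((50, 1, 2), 1), np.full((50, 1, 2), 2)])
        gm = GenotypeMatrix(individuals=[f"i{k}" for k in range(100)],
                            loci=["L1"], alleles=alleles,
                            pop=np.array(["P"] * 100, dtype=object))
        # n=200 copies at 0.5/0.5 -> (200/199) * 0.5
        assert gene_diversity(gm)[1] == pytest.approx(200 / 199 * 0.5, abs=1e-12)

    def test_matches_direct_formula(self, toy_with_missing):
        per_locus, _ = gene_diversity(toy_with_missing, "A")
        for locus in toy_with_missing.loci:
            assert per_locus[locus] == pytest.approx(
                brute_force_he(toy_with_missing, "A", locus), abs=1e-12)

    def test_unbiasedness_of_estimator(self, rng):
        # mean over 2000 samples of size 10 approximates 1 - sum p^2
        p = np.array([0.5, 0.3, 0.2])
        target = 1 - np.sum(p ** 2)
        vals = []
        for _ in range(2000):
            copies = rng.choice(3, size=20, p=p)
            cnt = np.bincount(copies, minlength=3)
            vals.append((1 - np.sum((cnt / 20) ** 2)) * 20 / 19)
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - target) < 4 * se + 1e-3


class TestFis:
    def test_zero_when_observed_equals_expected(self, rng):
        gm = hwe_population(rng, [0.5, 0.5], n=5000, loci=1)
        assert abs(fis(gm)) < 0.03

    def test_one_when_no_heterozygotes(self):
        alleles = np.array([[[1, 1]], [[2, 2]], [[1, 1]], [[2, 2]]])
        gm = GenotypeMatrix(individuals=list("abcd"), loci=["L1"],
                            alleles=alleles, pop=np.array(["P"] * 4, dtype=object))
        assert fis(gm) == pytest.approx(1.0)

    def test_random_mating_simulation_near_zero(self, rng):
        gm = hwe_population(rng, [0.4, 0.3, 0.2, 0.1], n=200, loci=11)
        assert abs(fis(gm)) < 0.05

    def test_selfing_equilibrium_matches_closed_form(self):
        # partial selfing at rate s: equilibrium F_IS = s / (2 - s)
        from guavapop.synthetic_data import mating_rounds

        rng = np.random.default_rng(7)
        gm = hwe_population(rng, [0.3, 0.3, 0.2, 0.2], n=400, loci=11)
        selfed = mating_rounds(gm, 0.6, n_rounds=25, rng=rng)
        assert fis(selfed) == pytest.approx(0.6 / 1.4, abs=0.05)


class TestIndividualInbreeding:
    def test_fully_heterozygous_individual_has_zero_f(self, rng):
        gm = hwe_population(rng, [0.5, 0.5], n=50, loci=8)
        het = np.flatnonzero((gm.alleles[:, :, 0] != gm.alleles[:, :, 1]).all(axis=1))
        if het.size:
            assert individual_inbreeding(gm, int(het[0])) == 0.0

    def test_homozygous_at_rare_alleles_near_one(self, rng):
        gm = hwe_population(rng, [0.9, 0.1], n=100, loci=10)
        alleles = gm.alleles.copy()
        alleles[0] = 2  # homozygous for the rare allele everywhere
        gm2 = GenotypeMatrix(individuals=list(gm.individuals), loci=gm.loci,
                             alleles=alleles, pop=gm.pop)
        assert individual_inbreeding(gm2, 0) > 0.9

    def test_grid_matches_continuous_optimum(self, rng):
        from scipy.optimize import minimize_scalar

        gm = hwe_population(rng, [0.5, 0.3, 0.2], n=80, loci=10)
        aft = allele_frequencies(gm)
        i = 3

        def negll(f):
            ll = 0.0
            for j, locus in enumerate(gm.loci):
                a, b = gm.alleles[i, j]
                freqs = aft.freqs[(locus, gm.pop[i])]
                if a == b:
                    lik = f * freqs[a] + (1 - f) * freqs[a] ** 2
                else:
                    lik = (1 - f) * 2 * freqs[a] * freqs[b]
                ll += np.log(max(lik, 1e-300))
            return -ll

        opt = minimize_scalar(negll, bounds=(0, 1), method="bounded").x
        assert abs(individual_inbreeding(gm, i) - opt) <= 0.01 + 1e-9


class TestMonteCarloTests:
    def test_hwe_proportions_not_rejected(self, rng):
        gm = hwe_population(rng, [0.5, 0.3, 0.2], n=200, loci=1)
        assert hwe_test(gm, "L0", "P", n_perm=400, seed=1) > 0.2

    def test_all_heterozygotes_rejected(self):
        alleles = np.tile([[1, 2]], (50, 1, 1)).reshape(50, 1, 2)
        gm = GenotypeMatrix(individuals=[f"i{k}" for k in range(50)],
                            loci=["L1"], alleles=alleles,
                            pop=np.array(["P"] * 50, dtype=object))
        assert hwe_test(gm, "L1", "P", n_perm=400, seed=1) < 0.01

    def test_monomorphic_locus_p_one(self, rng):
        gm = hwe_population(rng, [1.0], n=20, loci=1)
        assert hwe_test(gm, "L0", "P", n_perm=100, seed=0) == 1.0

    def test_ld_perfect_association_minimal_p(self):
        # locus B a copy of locus A with unevenly filled genotype classes:
        # any permutation that breaks the pairing lowers the G statistic
        a = np.array([[1, 1]] * 18 + [[1, 2]] * 12 + [[2, 2]] * 6 + [[2, 3]] * 4)
        alleles = np.stack([a, a], axis=1)
        gm = GenotypeMatrix(individuals=[f"i{k}" for k in range(40)],
                            loci=["LA", "LB"], alleles=alleles,
                            pop=np.array(["P"] * 40, dtype=object))
        n_perm = 199
        assert ld_test(gm, "LA", "LB", n_perm=n_perm, seed=3) == 1 / (n_perm + 1)

    def test_ld_monomorphic_p_one(self, rng):
        gm = hwe_population(rng, [1.0], n=20, loci=2)
        assert ld_test(gm, "L0", "L1", n_perm=100, seed=0) == 1.0

    def test_he_difference_identical_pops_p_one(self, toy_matrix):
        gm = GenotypeMatrix(individuals=list(toy_matrix.individuals),
                            loci=list(toy_matrix.loci),
                            alleles=np.concatenate([toy_matrix.alleles[:3]] * 2),
                            pop=np.array(["A"] * 3 + ["B"] * 3, dtype=object))
        assert he_difference_test(gm, "A", "B", n_perm=200, seed=0) == 1.0

    def test_he_difference_detects_extra_diversity(self, rng):
        # pop B carries extra alleles -> higher H_E; moderate power check
        hits = 0
        for rep in range(20):
            r = np.random.default_rng([5, rep])
            a = hwe_population(r, [0.6, 0.4], n=80, loci=11)
            b = hwe_population(r, [0.3, 0.25, 0.25, 0.2], n=80, loci=11)
            gm = GenotypeMatrix(
                individuals=[f"a{k}" for k in range(80)] + [f"b{k}" for k in range(80)],
                loci=a.loci, alleles=np.concatenate([a.alleles, b.alleles]),
                pop=np.array(["A"] * 80 + ["B"] * 80, dtype=object))
            hits += he_difference_test(gm, "A", "B", n_perm=199, seed=rep) <= 0.05
        assert hits >= 16  # >= 80 % power


class TestBonferroni:
    def test_marginal_p_not_significant_after_correction(self):
        threshold, flags = bonferroni([0.037], m=3)
        assert threshold == pytest.approx(0.05 / 3)
        assert not flags[0]

    def test_small_p_survives_correction(self):
        _, flags = bonferroni([0.001, 0.005, 0.037], m=3)
        assert list(flags) == [True, True, False]

    def test_single_test_unchanged(self):
        _, flags = bonferroni([0.04, 0.06], m=None)
        # m defaults to 2 here; with m=1 a single test keeps its decision
        _, single = bonferroni([0.04], m=1)
        assert single[0]

    def test_empty_input_empty_output(self):
        _, flags = bonferroni([])
        assert flags.size == 0


def test_diversity_table_invariants(rng):
    gm = hwe_population(rng, [0.4, 0.3, 0.2, 0.1], n=40, pops=("A", "B"), loci=5)
    table = diversity_table(gm).table
    assert set(table.index) == {"A", "B", "overall"}
    assert (table["A_freq"] <= table["A"]).all()
    assert table.loc[["A", "B"], "PA"].le(table.loc[["A", "B"], "A"]).all()
    assert table["H_O"].between(0, 1).all() and table["H_E"].between(0, 1).all()
    assert (table["AR"] <= table["A"] + 1e-9).all()
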