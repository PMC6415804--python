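import numpy as np
import pytest

from guavapop.genotypes import GenotypeMatrix, allele_frequencies
from guavapop.structure_stats import (
    DistanceMatrix,
    amova,
    geographic_distances,
    individual_distances,
    mantel,
    nei_distance,
    pairwise_fst,
    pcoa,
    wc_theta,
)
from tests.conftest import hwe_population


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def oracle_wc_theta(gm, labels):
    """Literal Weir & Cockerham (1984) formulas, per allele, summed."""
    groups = list(dict.fromkeys(labels))
    r = len(groups)
    num = den = 0.0
    for j in range(gm.n_loci):
        sub_by_g = {}
        for g in groups:
            rows = gm.alleles[np.asarray(labels) == g, j, :]
            rows = rows[rows[:, 0] >= 0]
            sub_by_g[g] = rows
        ni = np.array([len(sub_by_g[g]) for g in groups], dtype=float)
        if (ni < 1).any():
            continue
        nbar = ni.mean()
        nc = (r * nbar - (ni ** 2).sum() / (r * nbar)) / (r - 1)
        alleles = sorted({int(a) for g in groups for a in sub_by_g[g].ravel()})
        for u in alleles:
            p = np.array([np.mean(sub_by_g[g] == u) for g in groups])
            h = np.array([np.mean((sub_by_g[g][:, 0] != sub_by_g[g][:, 1])
                                  & ((sub_by_g[g] == u).any(axis=1)))
                          for g in groups])
            pbar = (ni * p).sum() / (r * nbar)
            s2 = (ni * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
            hbar = (ni * h).sum() / (r * nbar)
            a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                                     - hbar / 4) / (nbar - 1))
            b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                       - (2 * nbar - 1) / (4 * nbar) * hbar)
            c = hbar / 2
            num += a
            den += a + b + c
    return num / den


def oracle_amova_components(gm, labels):
    """Nested ANOVA on gene copies via explicit pairwise-distance sums
    (SS of a set = sum of pairwise squared distances / set size)."""
    groups = list(dict.fromkeys(labels))
    r = len(groups)
    ss = np.zeros(3)
    df = np.zeros(3)
    nc_list = []
    for j in range(gm.n_loci):
        col = gm.alleles[:, j, :]
        keep = col[:, 0] >= 0
        sub, glab = col[keep], np.asarray(labels)[keep]
        copies = sub.ravel()
        owner = np.repeat(np.arange(sub.shape[0]), 2)
        copy_group = np.repeat(glab, 2)

        def ss_set(idx):
            tot = 0.0
            for a in range(len(idx)):
                for b in range(a + 1, len(idx)):
                    tot += copies[idx[a]] != copies[idx[b]]
            return tot / len(idx)

        every = np.arange(copies.size)
        ss_t = ss_set(every)
        ss_wp = sum(ss_set(every[copy_group == g]) for g in groups)
        ss_wi = sum(ss_set(every[owner == i]) for i in range(sub.shape[0]))
        ss += (ss_t - ss_wp, ss_wp - ss_wi, ss_wi)
        n_ind = sub.shape[0]
        df += (r - 1, n_ind - r, n_ind)
        n_g = np.array([np.sum(copy_group == g) for g in groups], dtype=float)
        nc_list.append((n_g.sum() - (n_g ** 2).sum() / n_g.sum()) / (r - 1))
    nc = np.mean(nc_list)
    ms = ss / df
    sigma_c = ms[2]
    sigma_b = (ms[1] - sigma_c) / 2
    sigma_a = (ms[0] - sigma_c - 2 * sigma_b) / (2 * nc)
    return sigma_a, sigma_b, sigma_c


# ---------------------------------------------------------------------------
# F_ST
# ---------------------------------------------------------------------------

class TestPairwiseFst:
    def test_two_samples_from_one_pool_near_zero(self, rng):
        gm = hwe_population(rng, [0.4, 0.3, 0.3], n=100, pops=("A", "B"), loci=11)
        assert abs(pairwise_fst(gm).values[0, 1]) < 0.02

    def test_fixed_alternative_alleles_give_one(self):
        alleles = np.concatenate([np.full((5, 3, 2), 1), np.full((5, 3, 2), 2)])
        gm = GenotypeMatrix(individuals=[f"i{k}" for k in range(10)],
                            loci=["L1", "L2", "L3"], alleles=alleles,
                            pop=np.array(["A"] * 5 + ["B"] * 5, dtype=object))
        assert pairwise_fst(gm).values[0, 1] == pytest.approx(1.0)

    def test_toy_matrix_matches_hand_oracle(self, toy_matrix):
        theta = wc_theta(toy_matrix, toy_matrix.pop)
        assert theta == pytest.approx(oracle_wc_theta(toy_matrix, toy_matrix.pop),
                                      abs=1e-10)

    def test_missing_data_matches_hand_oracle(self, toy_with_missing):
        theta = wc_theta(toy_with_missing, toy_with_missing.pop)
        assert theta == pytest.approx(
            oracle_wc_theta(toy_with_missing, toy_with_missing.pop), abs=1e-10)


class TestNeiDistance:
    def test_identical_frequencies_zero(self, rng):
        gm = hwe_population(rng, [0.5, 0.5], n=30, loci=2)
        aft = allele_frequencies(gm)
        aft.groups = ["P", "Q"]
        for locus in gm.loci:
            aft.freqs[(locus, "Q")] = dict(aft.freqs[(locus, "P")])
            aft.n[(locus, "Q")] = aft.n[(locus, "P")]
        assert nei_distance(aft, "P", "Q") == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_allele_sets_infinite(self):
        alleles = np.array([[[1, 1]], [[2, 2]]])
        gm = GenotypeMatrix(individuals=["a", "b"], loci=["L1"], alleles=alleles,
                            pop=np.array(["A", "B"], dtype=object))
        assert nei_distance(allele_frequencies(gm), "A", "B") == np.inf

    def test_matches_direct_formula(self, toy_matrix):
        aft = allele_frequencies(toy_matrix)
        jx = jy = jxy = 0.0
        for locus in toy_matrix.loci:
            fa, fb = aft.freqs[(locus, "A")], aft.freqs[(locus, "B")]
            jx += sum(v * v for v in fa.values())
            jy += sum(v * v for v in fb.values())
            jxy += sum(fa[a] * fb.get(a, 0.0) for a in fa)
        expected = -np.log(jxy / np.sqrt(jx * jy))
        assert nei_distance(aft, "A", "B") == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

class TestAmova:
    def test_toy_components_match_brute_force(self, toy_matrix):
        res = amova(toy_matrix, n_perm=10, seed=0)
        exp = oracle_amova_components(toy_matrix, toy_matrix.pop)
        np.testing.assert_allclose(res.table["variance"].to_numpy(), exp,
                                   atol=1e-10)

    def test_missing_data_components_match_brute_force(self, toy_with_missing):
        res = amova(toy_with_missing, n_perm=10, seed=0)
        exp = oracle_amova_components(toy_with_missing, toy_with_missing.pop)
        np.testing.assert_allclose(res.table["variance"].to_numpy(), exp,
                                   atol=1e-10)

    def test_percentages_sum_to_hundred(self, rng):
        gm = hwe_population(rng, [0.4, 0.3, 0.3], n=25, pops=("A", "B", "C"), loci=6)
        res = amova(gm, n_perm=20, seed=1)
        assert res.table["pct_variation"].sum() == pytest.approx(100.0, abs=0.01)

    def test_fixed_populations_near_total_among_group_variance(self):
        alleles = np.concatenate([np.full((6, 4, 2), 1), np.full((6, 4, 2), 2)])
        gm = GenotypeMatrix(individuals=[f"i{k}" for k in range(12)],
                            loci=[f"L{j}" for j in range(4)], alleles=alleles,
                            pop=np.array(["A"] * 6 + ["B"] * 6, dtype=object))
        res = amova(gm, n_perm=50, seed=2)
        assert res.table["pct_variation"].iloc[0] > 95
        assert res.p_values["among_groups"] < 0.05

    def test_identical_populations_small_among_group_share(self):
        pcts = []
        for rep in range(25):
            r = np.random.default_rng([31, rep])
            gm = hwe_population(r, [0.4, 0.3, 0.3], n=50, pops=("A", "B"), loci=8)
            pcts.append(amova(gm, n_perm=5, seed=rep).table["pct_variation"].iloc[0])
        assert abs(np.mean(pcts)) < 3.0


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

class TestPcoa:
    def test_three_equidistant_points_two_equal_eigenvalues(self):
        d = np.ones((3, 3)) - np.eye(3)
        res = pcoa(DistanceMatrix(labels=list("abc"), values=d))
        pos = res.eigenvalues[res.eigenvalues > 1e-10]
        assert len(pos) == 2 and pos[0] == pytest.approx(pos[1], rel=1e-9)

    def test_planar_configuration_roundtrips_distances(self, rng):
        pts = rng.random((7, 2)) * 10
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        res = pcoa(DistanceMatrix(labels=[str(i) for i in range(7)], values=d))
        coords = res.coordinates
        d2 = np.sqrt(((coords[:, None] - coords[None, :]) ** 2).sum(-1))
        np.testing.assert_allclose(d2, d, atol=1e-8)

    def test_nonsymmetric_input_rejected(self):
        bad = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError):
            DistanceMatrix(labels=["a", "b"], values=bad)

    def test_percent_variance_reported_for_individual_distances(self, rng):
        gm = hwe_population(rng, [0.5, 0.3, 0.2], n=20, pops=("A", "B"), loci=6)
        res = pcoa(individual_distances(gm))
        assert res.percent_variance[:2].sum() > 0
        assert res.percent_variance[res.eigenvalues > 1e-10].sum() == pytest.approx(100.0)

    def test_agrees_with_skbio(self, rng):
        from skbio.stats.ordination import pcoa as skbio_pcoa

        gm = hwe_population(rng, [0.5, 0.3, 0.2], n=15, loci=5)
        dm = individual_distances(gm)
        ours = pcoa(dm)
        ref = skbio_pcoa(dm.values, number_of_dimensions=3)
        np.testing.assert_allclose(
            np.sort(ours.eigenvalues[:3]), np.sort(ref.eigvals.to_numpy()[:3]),
            rtol=1e-6, atol=1e-8)


# ---------------------------------------------------------------------------
# Mantel and geographic distances
# ---------------------------------------------------------------------------

class TestMantel:
    def test_self_comparison_perfect_correlation(self, rng):
        d = np.abs(rng.normal(size=(8, 8)))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        dm = DistanceMatrix(labels=[str(i) for i in range(8)], values=d)
        r, r2, p = mantel(dm, dm, n_perm=199, seed=0)
        assert r == pytest.approx(1.0) and p == 1 / 200

    def test_affine_transform_preserves_correlation(self, rng):
        d = np.abs(rng.normal(size=(8, 8)))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        noise = rng.normal(scale=0.01, size=d.shape)
        d2 = 2 * d + 5 + noise + noise.T
        np.fill_diagonal(d2, 0)
        labels = [str(i) for i in range(8)]
        r, _, _ = mantel(DistanceMatrix(labels=labels, values=d),
                         DistanceMatrix(labels=labels, values=(d2 + d2.T) / 2),
                         n_perm=99, seed=0)
        assert r > 0.99

    def test_too_few_labels_rejected(self):
        d = np.zeros((2, 2))
        dm = DistanceMatrix(labels=["a", "b"], values=d)
        with pytest.raises(ValueError):
            mantel(dm, dm, n_perm=10)

    def test_agrees_with_skbio_statistic(self, rng):
        from skbio.stats.distance import DistanceMatrix as SkbioDM
        from skbio.stats.distance import mantel as skbio_mantel

        a = np.abs(rng.normal(size=(9, 9)));  a = (a + a.T) / 2; np.fill_diagonal(a, 0)
        b = np.abs(rng.normal(size=(9, 9)));  b = (b + b.T) / 2; np.fill_diagonal(b, 0)
        labels = [str(i) for i in range(9)]
        r_ours, _, _ = mantel(DistanceMatrix(labels=labels, values=a),
                              DistanceMatrix(labels=labels, values=b),
                              n_perm=99, seed=0)
        r_ref, _, _ = skbio_mantel(SkbioDM(a), SkbioDM(b), permutations=0)
        assert r_ours == pytest.approx(r_ref, abs=1e-10)


class TestGeographicDistances:
    def test_identical_points_zero(self):
        dm = geographic_distances({"a": (0.0, 0.0), "b": (0.0, 0.0)})
        assert dm.values[0, 1] == 0.0

    def test_one_degree_latitude_at_equator(self):
        dm = geographic_distances({"a": (0.0, 0.0), "b": (1.0, 0.0)})
        assert dm.values[0, 1] == pytest.approx(111.19, abs=0.2)

    def test_symmetry(self):
        dm = geographic_distances({"a": (-0.7, -90.3), "b": (-0.9, -89.6),
                                   "c": (-1.0, -91.1)})
        np.testing.assert_allclose(dm.values, dm.values.T)

    def test_missing_coordinates_listed(self):
        with pytest.raises(ValueError, match="b"):
            geographic_distances({"a": (0.0, 0.0), "b": (np.nan, 1.0)})
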