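"""Per-population diversity and inbreeding statistics, plus permutation tests.

Statistics follow the conventions of the classic SSR toolchain:

* gene diversity uses Nei's unbiased estimator ``n/(n-1) * (1 - sum p_i^2)``;
* F_IS is the ratio of across-locus means ``1 - mean(H_O)/mean(H_E)``;
* allele and private-allele counts are totals across loci, while allelic
  richness (hypergeometric rarefaction) is the across-locus mean;
* Monte-Carlo tests use the permutation p-value convention
  ``(1 + #{null >= obs}) / (1 + n_perm)`` so that p is never 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from guavapop.genotypes import (
    MISSING,
    AlleleFrequencyTable,
    GenotypeMatrix,
    allele_frequencies,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# allele counts
# ---------------------------------------------------------------------------

def count_alleles(aft: AlleleFrequencyTable, pop, freq_threshold: float = 0.05):
    """Total allele count A and count of frequent alleles (> threshold) for one pop.

    Counts are totals across loci; an allele counts as frequent when its
    within-population frequency is strictly greater than *freq_threshold*.
    """
    if not 0 <= freq_threshold < 1:
        raise ValueError("freq_threshold must be in [0, 1)")
    a = a_freq = 0
    for locus in aft.loci:
        for freq in aft.freqs[(locus, pop)].values():
            a += 1
            if freq > freq_threshold:
                a_freq += 1
    return a, a_freq


def private_alleles(aft: AlleleFrequencyTable, freq_threshold: float = 0.05):
    """Per-population private-allele totals (PA, PA_freq) across loci.

    An allele is private to population p iff its frequency is > 0 in p and
    0 in every other population. Requires >= 2 populations.
    """
    if len(aft.groups) < 2:
        raise ValueError("private alleles undefined for a single population")
    out = {g: [0, 0] for g in aft.groups}
    for locus in aft.loci:
        for allele in aft.alleles_at(locus):
            holders = [g for g in aft.groups
                       if aft.freqs[(locus, g)].get(allele, 0.0) > 0]
            if len(holders) == 1:
                g = holders[0]
                out[g][0] += 1
                if aft.freqs[(locus, g)][allele] > freq_threshold:
                    out[g][1] += 1
    return {g: tuple(v) for g, v in out.items()}


# ---------------------------------------------------------------------------
# rarefied allelic richness
# ---------------------------------------------------------------------------

def _log_comb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def allelic_richness(gm: GenotypeMatrix, g_copies: int | None = None):
    """Hypergeometric rarefaction of allele counts to g gene copies.

    ``AR = sum_i [1 - C(n - n_i, g) / C(n, g)]`` where n_i is the copy
    count of allele i and n the total copies at the (locus, population)
    cell. Defaults g to 2 x the smallest population sample size.

    Returns (per_cell, per_pop_mean): a DataFrame indexed by locus with one
    column per population, and the across-locus mean per population.
    """
    aft = allele_frequencies(gm, "pop")
    pops = aft.groups
    n_min = min(aft.n[(locus, p)] for locus in aft.loci for p in pops)
    if g_copies is None:
        sizes = [int((gm.pop == p).sum()) for p in pops]
        g_copies = min(2 * min(sizes), n_min)  # clamp under missing data
    if g_copies < 1:
        raise ValueError("g_copies must be >= 1")
    if g_copies > n_min:
        raise ValueError(
            f"g_copies={g_copies} exceeds the smallest gene-copy count {n_min}")
    table = pd.DataFrame(index=aft.loci, columns=pops, dtype=float)
    for locus in aft.loci:
        for p in pops:
            n = aft.n[(locus, p)]
            ar = 0.0
            for a, f in aft.freqs[(locus, p)].items():
                ni = round(f * n)
                if n - ni < g_copies:
                    ar += 1.0  # allele guaranteed present in every subsample
                else:
                    ar += 1.0 - np.exp(_log_comb(n - ni, g_copies)
                                       - _log_comb(n, g_copies))
            table.loc[locus, p] = ar
    return table, table.mean(axis=0)


# ---------------------------------------------------------------------------
# heterozygosities and F_IS
# ---------------------------------------------------------------------------

def observed_heterozygosity(gm: GenotypeMatrix, pop=None):
    """Per-locus H_O (fraction of non-missing individuals with two distinct
    alleles) and the across-locus mean. All-missing cells are NaN and are
    excluded from the mean with a warning."""
    sub = gm if pop is None else gm.by_population(pop)
    obs = sub.alleles[:, :, 0] != MISSING
    het = (sub.alleles[:, :, 0] != sub.alleles[:, :, 1]) & obs
    counts = obs.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore"):
        per_locus = np.where(counts > 0, het.sum(axis=0) / counts, np.nan)
    if np.isnan(per_locus).any():
        logger.warning("observed_heterozygosity: %d all-missing cells excluded",
                       int(np.isnan(per_locus).sum()))
    per_locus = pd.Series(per_locus, index=sub.loci)
    return per_locus, float(np.nanmean(per_locus.to_numpy()))


def gene_diversity(gm: GenotypeMatrix, pop=None, unbiased: bool = True):
    """Per-locus expected heterozygosity (gene diversity) and its mean.

    Nei's unbiased estimator ``n/(n-1) * (1 - sum p_i^2)`` by default;
    ``unbiased=False`` gives the plug-in ``1 - sum p_i^2``. Cells with
    fewer than 2 gene copies are NaN.
    """
    sub = gm if pop is None else gm.by_population(pop)
    vals = np.empty(sub.n_loci)
    for j in range(sub.n_loci):
        copies = sub.alleles[:, j, :].ravel()
        copies = copies[copies != MISSING]
        n = copies.size
        if n < 2:
            vals[j] = np.nan
            continue
        _, cnt = np.unique(copies, return_counts=True)
        h = 1.0 - np.sum((cnt / n) ** 2)
        vals[j] = h * n / (n - 1) if unbiased else h
    per_locus = pd.Series(vals, index=sub.loci)
    return per_locus, float(np.nanmean(vals))


def fis(gm: GenotypeMatrix, pop=None):
    """F_IS = 1 - mean_loci(H_O) / mean_loci(H_E) (ratio of means)."""
    _, ho = observed_heterozygosity(gm, pop)
    _, he = gene_diversity(gm, pop)
    if not he > 0:
        raise ValueError("mean H_E is zero: F_IS undefined")
    return 1.0 - ho / he


def individual_inbreeding(gm: GenotypeMatrix, individual, grid_step: float = 0.01):
    """Maximum-likelihood individual inbreeding coefficient F-hat on a grid.

    Likelihood per locus given population allele frequencies p:
    heterozygote i!=j -> (1-F) * 2 p_i p_j; homozygote i ->
    F p_i + (1-F) p_i^2. Maximised over F in {0, grid_step, ..., 1}.
    """
    i = gm.individuals.index(individual) if not isinstance(individual, (int, np.integer)) else int(individual)
    p = gm.pop[i]
    aft = allele_frequencies(gm, "pop")
    fgrid = np.arange(0.0, 1.0 + 1e-9, grid_step)
    loglik = np.zeros_like(fgrid)
    informative = False
    for j, locus in enumerate(gm.loci):
        a1, a2 = gm.alleles[i, j]
        if a1 == MISSING:
            continue
        freqs = aft.freqs[(locus, p)]
        p1 = freqs.get(int(a1), 0.0)
        if a1 == a2:
            lik = fgrid * p1 + (1 - fgrid) * p1 ** 2
        else:
            p2 = freqs.get(int(a2), 0.0)
            lik = (1 - fgrid) * 2 * p1 * p2
        informative = True
        with np.errstate(divide="ignore"):
            loglik += np.log(np.maximum(lik, 1e-300))
    if not informative:
        raise ValueError("individual has no genotyped loci")
    return float(fgrid[int(np.argmax(loglik))])


# ---------------------------------------------------------------------------
# Monte-Carlo tests
# ---------------------------------------------------------------------------

def _mc_pvalue(n_extreme: int, n_perm: int) -> float:
    return (1 + n_extreme) / (1 + n_perm)


def _log_table_prob(copies: np.ndarray) -> float:
    """Log multinomial probability of the genotype table given allele counts.

    Levene's conditional distribution: with allele counts m_a among 2n
    copies and genotype counts f_ab,
    P = n! prod m_a! 2^h / ((2n)! prod f_ab!) with h the heterozygote count.
    Only table-dependent terms are needed for comparisons, but the full
    value is computed for clarity.
    """
    n = copies.shape[0]
    vals, m = np.unique(copies, return_counts=True)
    key = copies[:, 0] * np.int64(1 << 20) + copies[:, 1]
    _, f = np.unique(key, return_counts=True)
    h = int((copies[:, 0] != copies[:, 1]).sum())
    return (gammaln(n + 1) + gammaln(m + 1).sum() + h * np.log(2.0)
            - gammaln(2 * n + 1) - gammaln(f + 1).sum())


def hwe_test(gm: GenotypeMatrix, locus, pop, n_perm: int = 10_000, seed=None) -> float:
    """Monte-Carlo exact test of Hardy-Weinberg equilibrium at one locus.

    The statistic is the conditional probability of the genotype table;
    null tables are generated by randomly pairing the observed gene copies.
    p = (1 + #{P(table) <= P(obs)}) / (1 + n_perm); monomorphic loci give 1.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    sub = gm.by_population(pop)
    j = sub.loci.index(locus)
    g = sub.alleles[:, j, :]
    g = g[g[:, 0] != MISSING]
    g = np.sort(g, axis=1)
    if g.shape[0] == 0 or np.unique(g).size < 2:
        return 1.0
    rng = np.random.default_rng(seed)
    obs_logp = _log_table_prob(g)
    pool = g.ravel().copy()
    n_extreme = 0
    for _ in range(n_perm):
        rng.shuffle(pool)
        tab = np.sort(pool.reshape(-1, 2), axis=1)
        if _log_table_prob(tab) <= obs_logp + 1e-12:
            n_extreme += 1
    return _mc_pvalue(n_extreme, n_perm)


def _g_statistic(ka: np.ndarray, kb: np.ndarray, ma: int, mb: int) -> float:
    """G statistic of the two-way contingency table of integer codes."""
    tab = np.bincount(ka * mb + kb, minlength=ma * mb).reshape(ma, mb).astype(float)
    total = tab.sum()
    exp = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / total
    mask = tab > 0
    return 2.0 * float(np.sum(tab[mask] * np.log(tab[mask] / exp[mask])))


def ld_test(gm: GenotypeMatrix, locus_a, locus_b, pop=None,
            n_perm: int = 10_000, seed=None) -> float:
    """Permutation G-test of genotypic association between two loci.

    The two-locus genotype contingency table's G statistic is compared to
    its null distribution obtained by permuting individuals' genotypes at
    locus B. Monomorphic loci give p = 1.
    """
    sub = gm if pop is None else gm.by_population(pop)
    ja, jb = sub.loci.index(locus_a), sub.loci.index(locus_b)
    ga = np.sort(sub.alleles[:, ja, :], axis=1)
    gb = np.sort(sub.alleles[:, jb, :], axis=1)
    keep = (ga[:, 0] != MISSING) & (gb[:, 0] != MISSING)
    ga, gb = ga[keep], gb[keep]
    if np.unique(ga).size < 2 or np.unique(gb).size < 2:
        return 1.0
    # encode genotype categories as small integer codes
    ka = pd.factorize(ga[:, 0] * np.int64(1 << 20) + ga[:, 1])[0]
    kb = pd.factorize(gb[:, 0] * np.int64(1 << 20) + gb[:, 1])[0]
    ma, mb = ka.max() + 1, kb.max() + 1
    rng = np.random.default_rng(seed)
    obs = _g_statistic(ka, kb, ma, mb)
    kb_perm = kb.copy()
    n_extreme = 0
    for _ in range(n_perm):
        rng.shuffle(kb_perm)
        if _g_statistic(ka, kb_perm, ma, mb) >= obs - 1e-12:
            n_extreme += 1
    return _mc_pvalue(n_extreme, n_perm)


def he_difference_test(gm: GenotypeMatrix, pop_a, pop_b,
                       n_perm: int = 10_000, seed=None) -> float:
    """Monte-Carlo test of a difference in mean gene diversity between two pops.

    Statistic: |mean H_E(A) - mean H_E(B)|; the null reassigns individuals
    to the two populations at random, preserving sizes.
    """
    from guavapop.genotypes import locus_codes

    ia = np.flatnonzero(gm.pop == pop_a)
    ib = np.flatnonzero(gm.pop == pop_b)
    if ia.size == 0 or ib.size == 0:
        raise ValueError("both populations must be non-empty")
    both = gm.subset(np.concatenate([ia, ib]))
    na = ia.size
    codes, m = locus_codes(both)

    def stat(idx_a, idx_b):
        return abs(_mean_he_codes(codes, m, idx_a)
                   - _mean_he_codes(codes, m, idx_b))

    all_idx = np.arange(both.n_individuals)
    obs = stat(all_idx[:na], all_idx[na:])
    rng = np.random.default_rng(seed)
    n_extreme = 0
    for _ in range(n_perm):
        perm = rng.permutation(all_idx)
        if stat(perm[:na], perm[na:]) >= obs - 1e-12:
            n_extreme += 1
    return _mc_pvalue(n_extreme, n_perm)


def _mean_he_codes(codes: np.ndarray, m: list, idx: np.ndarray) -> float:
    """Mean unbiased gene diversity across loci for a row subset (fast path
    over pre-computed per-locus allele codes)."""
    vals = []
    sub = codes[idx]
    for j, mj in enumerate(m):
        copies = sub[:, j, :].ravel()
        copies = copies[copies >= 0]
        n = copies.size
        if n < 2:
            continue
        cnt = np.bincount(copies, minlength=mj)
        h = 1.0 - np.sum((cnt / n) ** 2)
        vals.append(h * n / (n - 1))
    return float(np.mean(vals)) if vals else np.nan


def bonferroni(p_values, m: int | None = None, alpha: float = 0.05):
    """Bonferroni decisions: reject iff p < alpha/m.

    Returns (threshold, flags). m defaults to the number of tests and must
    be at least that number.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return alpha, np.zeros(0, dtype=bool)
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("m must be >= number of tests")
    threshold = alpha / m
    return threshold, p < threshold


# ---------------------------------------------------------------------------
# Table-1-style report
# ---------------------------------------------------------------------------

@dataclass
class DiversityTable:
    """Per-population diversity summary (plus an 'overall' row)."""

    table: pd.DataFrame

    def to_csv(self, path, sep="\t"):
        self.table.to_csv(path, sep=sep)


def diversity_table(gm: GenotypeMatrix, freq_threshold: float = 0.05,
                    rarefaction_copies: int | None = None) -> DiversityTable:
    """Assemble the per-island diversity report: N, A, A_freq, PA, PA_freq,
    AR, H_O, H_E and F_IS per population plus a pooled 'overall' row."""
    aft = allele_frequencies(gm, "pop")
    pops = aft.groups
    priv = private_alleles(aft, freq_threshold) if len(pops) > 1 else None
    _, ar = allelic_richness(gm, rarefaction_copies)
    rows = []
    for p in pops:
        a, af = count_alleles(aft, p, freq_threshold)
        _, ho = observed_heterozygosity(gm, p)
        _, he = gene_diversity(gm, p)
        pa, paf = priv[p] if priv else (np.nan, np.nan)
        rows.append(dict(pop=p, N=int((gm.pop == p).sum()), A=a, A_freq=af,
                         PA=pa, PA_freq=paf, AR=float(ar[p]),
                         H_O=ho, H_E=he, F_IS=fis(gm, p)))
    # pooled row
    aft_all = allele_frequencies(gm, "all")
    a, af = count_alleles(aft_all, "all", freq_threshold)
    _, ho = observed_heterozygosity(gm)
    _, he = gene_diversity(gm)
    ar_all = _pooled_richness(gm, rarefaction_copies)
    rows.append(dict(pop="overall", N=gm.n_individuals, A=a, A_freq=af,
                     PA=np.nan, PA_freq=np.nan, AR=ar_all,
                     H_O=ho, H_E=he, F_IS=fis(gm)))
    return DiversityTable(pd.DataFrame(rows).set_index("pop"))


def _pooled_richness(gm: GenotypeMatrix, g_copies):
    pooled = GenotypeMatrix(individuals=list(gm.individuals), loci=list(gm.loci),
                            alleles=gm.alleles.copy(),
                            pop=np.asarray(["all"] * gm.n_individuals, dtype=object))
    aft = allele_frequencies(pooled, "pop")
    n_min = min(aft.n[(locus, "all")] for locus in pooled.loci)
    if g_copies is None:
        g_copies = 2 * min(int((gm.pop == p).sum()) for p in gm.populations)
    _, ar = allelic_richness(pooled, min(g_copies, n_min))
    return float(ar.iloc[0])
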