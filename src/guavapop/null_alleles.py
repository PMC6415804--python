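"""EM estimation of null-allele frequencies and null-corrected F_ST.

A null allele fails to amplify: a true visible/null heterozygote is scored
as a visible homozygote, and a null/null individual yields a blank. The EM
algorithm treats each observed homozygote class i/i as a mixture of true
i/i and i/null under HWE. Blanks are either counted as null homozygotes
("null_homozygote" convention) or marginalised out ("marginalize", the
default, matching data in which non-amplification and failed PCR are
indistinguishable and coded as missing).

The corrected pairwise F_ST follows the ENA approach: Weir-Cockerham
components are computed with the null treated as an extra allele at its
estimated frequency, and the null-allele class is then excluded from the
numerator and denominator sums. With zero estimated null frequencies the
result equals the uncorrected multilocus theta exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from guavapop.genotypes import MISSING, GenotypeMatrix, allele_frequencies
from guavapop.structure_stats import DistanceMatrix

logger = logging.getLogger(__name__)


@dataclass
class NullAlleleEstimate:
    """EM result for one (locus, population) cell."""

    r: float                       # null-allele frequency
    visible_freqs: dict            # allele -> corrected frequency
    iterations: int
    converged: bool
    loglik_trace: list = field(default_factory=list)

    def __post_init__(self):
        total = self.r + sum(self.visible_freqs.values())
        if self.visible_freqs and abs(total - 1.0) > 1e-9:
            raise ValueError(f"frequencies sum to {total}, not 1")


def _genotype_classes(genotypes: np.ndarray):
    """Counts of het pairs (i, j), observed-homozygote classes i and blanks."""
    blank = int(np.sum(genotypes[:, 0] == MISSING))
    obs = genotypes[genotypes[:, 0] != MISSING]
    obs = np.sort(obs, axis=1)
    het_counts, hom_counts = {}, {}
    for a, b in obs:
        if a == b:
            hom_counts[int(a)] = hom_counts.get(int(a), 0) + 1
        else:
            het_counts[(int(a), int(b))] = het_counts.get((int(a), int(b)), 0) + 1
    return het_counts, hom_counts, blank


def em_null_frequency(genotypes: np.ndarray, tol: float = 1e-8,
                      max_iter: int = 10_000,
                      blanks: str = "marginalize") -> NullAlleleEstimate:
    """EM null-allele frequency at one locus in one population.

    genotypes: (n, 2) allele labels with MISSING rows counted as blanks.
    blanks="null_homozygote" treats blanks as null/null individuals;
    "marginalize" (default) drops them from the likelihood.
    """
    het_counts, hom_counts, n_blank = _genotype_classes(np.asarray(genotypes))
    alleles = sorted(set(hom_counts) | {a for pair in het_counts for a in pair})
    k = len(alleles)
    aidx = {a: i for i, a in enumerate(alleles)}
    n_obs = sum(het_counts.values()) + sum(hom_counts.values())
    use_blanks = blanks == "null_homozygote"

    if n_obs == 0:
        if n_blank > 0:
            # degenerate: everything blank; boundary estimate
            return NullAlleleEstimate(r=1.0, visible_freqs={}, iterations=0,
                                      converged=False)
        raise ValueError("no genotypes supplied")
    if not hom_counts and not (use_blanks and n_blank):
        # all hets: no homozygote excess signal at all
        p = _gene_count_freqs(het_counts, hom_counts, alleles)
        return NullAlleleEstimate(r=0.0, visible_freqs=p, iterations=0,
                                  converged=True)

    # init: gene counting ignoring nulls, small r
    p = np.array([v for v in _gene_count_freqs(het_counts, hom_counts, alleles).values()])
    r = 0.05
    p = p * (1 - r)
    loglik_trace = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step: expected allele-copy counts
        copies = np.zeros(k)
        null_copies = 0.0
        for (a, b), c in het_counts.items():
            copies[aidx[a]] += c
            copies[aidx[b]] += c
        for a, c in hom_counts.items():
            i = aidx[a]
            denom = p[i] ** 2 + 2 * p[i] * r
            w_true = (p[i] ** 2 / denom) if denom > 0 else 1.0
            copies[i] += c * (2 * w_true + (1 - w_true))      # ii:2 copies, i-null:1
            null_copies += c * (1 - w_true)
        if use_blanks:
            null_copies += 2 * n_blank
        else:
            # truncated-sample EM: impute the unseen null/null individuals
            # expected given the current r (their class is never observed)
            b_hat = n_obs * r ** 2 / max(1.0 - r ** 2, 1e-12)
            null_copies += 2 * b_hat
        total = copies.sum() + null_copies
        p_new = copies / total
        r_new = null_copies / total
        # observed-data log-likelihood (for the monotonicity invariant)
        ll = _loglik(het_counts, hom_counts, n_blank, p_new, r_new,
                     dict(aidx.items()), use_blanks)
        loglik_trace.append(ll)
        delta = abs(r_new - r)
        p, r = p_new, r_new
        if delta < tol:
            converged = True
            break
    visible = {a: float(p[aidx[a]]) for a in alleles}
    # close the simplex exactly
    gap = 1.0 - (r + sum(visible.values()))
    if visible:
        first = alleles[0]
        visible[first] += gap
    return NullAlleleEstimate(r=float(r), visible_freqs=visible,
                              iterations=it, converged=converged,
                              loglik_trace=loglik_trace)


def _gene_count_freqs(het_counts, hom_counts, alleles):
    counts = {a: 0.0 for a in alleles}
    for (a, b), c in het_counts.items():
        counts[a] += c
        counts[b] += c
    for a, c in hom_counts.items():
        counts[a] += 2 * c
    tot = sum(counts.values())
    return {a: v / tot for a, v in counts.items()} if tot else {}


def _loglik(het_counts, hom_counts, n_blank, p, r, aidx, use_blanks):
    ll = 0.0
    norm = 1.0 if use_blanks else max(1.0 - r ** 2, 1e-300)
    for (a, b), c in het_counts.items():
        ll += c * np.log(max(2 * p[aidx[a]] * p[aidx[b]] / norm, 1e-300))
    for a, c in hom_counts.items():
        i = aidx[a]
        ll += c * np.log(max((p[i] ** 2 + 2 * p[i] * r) / norm, 1e-300))
    if use_blanks and n_blank:
        ll += n_blank * np.log(max(r ** 2, 1e-300))
    return float(ll)


def null_allele_table(gm: GenotypeMatrix, blanks: str = "marginalize") -> pd.DataFrame:
    """Long-format table (locus, pop, r, iterations, converged) of EM estimates."""
    rows = []
    estimates = {}
    for p in gm.populations:
        sub = gm.by_population(p)
        for j, locus in enumerate(gm.loci):
            est = em_null_frequency(sub.alleles[:, j, :], blanks=blanks)
            estimates[(locus, p)] = est
            rows.append(dict(locus=locus, pop=p, r=est.r,
                             iterations=est.iterations, converged=est.converged))
    df = pd.DataFrame(rows)
    df.attrs["estimates"] = estimates
    return df


# ---------------------------------------------------------------------------
# ENA-corrected pairwise F_ST
# ---------------------------------------------------------------------------

NULL_LABEL = -999  # internal pseudo-allele label for the null class


def fst_ena(gm: GenotypeMatrix, estimates: dict | None = None,
            blanks: str = "marginalize", r_exclude: float = 0.9) -> DistanceMatrix:
    """Pairwise multilocus F_ST corrected for null alleles (ENA).

    estimates maps (locus, pop) -> NullAlleleEstimate; computed if absent.
    Loci with an estimated null frequency >= r_exclude in any population of
    a pair are dropped for that pair (with a warning).
    """
    if estimates is None:
        estimates = null_allele_table(gm, blanks=blanks).attrs["estimates"]
    pops = gm.populations
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    k = len(pops)
    mat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            mat[i, j] = mat[j, i] = _theta_ena_pair(gm, pops[i], pops[j],
                                                   estimates, r_exclude)
    return DistanceMatrix(labels=pops, values=mat, kind="F_ST")


def _theta_ena_pair(gm: GenotypeMatrix, pop_a, pop_b, estimates, r_exclude):
    num = den = 0.0
    for j, locus in enumerate(gm.loci):
        est = {p: estimates[(locus, p)] for p in (pop_a, pop_b)}
        if any(e.r >= r_exclude for e in est.values()):
            logger.warning("fst_ena: locus %s dropped (r >= %.2f)", locus, r_exclude)
            continue
        a_sum, abc_sum = _wc_locus_ena(gm, j, pop_a, pop_b, est)
        num += a_sum
        den += abc_sum
    return num / den if den != 0 else np.nan


def _wc_locus_ena(gm: GenotypeMatrix, j: int, pop_a, pop_b, est):
    """WC components at one locus with the null as an extra allele class;
    the null class is excluded from the sums (ENA)."""
    pops = (pop_a, pop_b)
    r = 2
    ni = []
    freq_maps, het_maps = [], []
    for p in pops:
        sub = gm.alleles[gm.pop == p, j, :]
        sub = sub[sub[:, 0] != MISSING]
        n = sub.shape[0]
        ni.append(n)
        if n == 0:
            freq_maps.append({})
            het_maps.append({})
            continue
        e = est[p]
        fm = dict(e.visible_freqs)
        if e.r > 0:
            fm[NULL_LABEL] = e.r
        # observed heterozygote frequency per visible allele (unchanged by
        # nulls masking het i/null as hom i); null class has no observable h
        het = sub[sub[:, 0] != sub[:, 1]]
        hm = {}
        for u in set(np.unique(sub.ravel()).tolist()):
            hm[int(u)] = float(np.sum((het == u).any(axis=1)) / n)
        freq_maps.append(fm)
        het_maps.append(hm)
    if any(n < 1 for n in ni):
        return 0.0, 0.0
    ni = np.asarray(ni, dtype=float)
    nbar = ni.mean()
    if nbar <= 1:
        return 0.0, 0.0
    nc = (r * nbar - np.sum(ni ** 2) / (r * nbar)) / (r - 1)
    alleles = sorted(set().union(*[set(m) for m in freq_maps]))
    a_sum = abc_sum = 0.0
    for u in alleles:
        if u == NULL_LABEL:
            continue  # ENA: exclude the null-allele class from the sums
        p = np.array([m.get(u, 0.0) for m in freq_maps])
        h = np.array([m.get(u, 0.0) for m in het_maps])
        pbar = np.sum(ni * p) / (r * nbar)
        s2 = np.sum(ni * (p - pbar) ** 2) / ((r - 1) * nbar)
        hbar = np.sum(ni * h) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                                 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        a_sum += a
        abc_sum += a + b + c
    return a_sum, abc_sum
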