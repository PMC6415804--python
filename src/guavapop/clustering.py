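"""Bayesian admixture-model clustering of multilocus genotypes.

A Gibbs sampler for the classic admixture model: each individual i has
admixture proportions q_i over K clusters, each cluster k has allele
frequencies p_kl. per locus; every gene copy carries a latent cluster
assignment z. Sweeps alternate

    z | q, p   (categorical, proportional to q_ik * p_k,l,a)
    p | z      (Dirichlet, lambda + allele counts)
    q | z      (Dirichlet, alpha + assignment counts)
    alpha      (Metropolis random walk, uniform prior on (0, 10])

The allele-frequency prior lambda is fixed at 1 (uncorrelated
frequencies). Model selection across K uses Evanno's second-order
statistic Delta K; replicate runs are aligned with a greedy CLUMPP-style
column matching before averaging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from guavapop.genotypes import GenotypeMatrix, locus_codes


@dataclass
class ClusterRun:
    """Posterior summaries of one MCMC run at fixed K."""

    K: int
    Q: np.ndarray                # (n, K) posterior-mean admixture proportions
    P: np.ndarray                # (K, L, m_max) posterior-mean frequencies
    lnP: float                   # mean post-burn-in data log-likelihood
    alpha: float                 # posterior-mean Dirichlet concentration
    seed: object
    sweeps: int
    burn_in: int

    def __post_init__(self):
        if not np.allclose(self.Q.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("Q rows must sum to 1")


def run_admixture_mcmc(gm: GenotypeMatrix, K: int, sweeps: int = 5000,
                       burn_in: int = 1000, seed=None, alpha_init: float = 1.0,
                       lambda_: float = 1.0, pop_alpha: bool = False,
                       return_trace: bool = False):
    """Run the admixture-model Gibbs sampler and return a ClusterRun.

    pop_alpha=True makes alpha population-specific (a weak use of the
    sampling-island labels as prior information); default is the plain
    admixture model. Missing gene copies are skipped in the z updates.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > gm.n_individuals:
        raise ValueError("K cannot exceed the number of individuals")
    if sweeps <= burn_in:
        raise ValueError("sweeps must exceed burn_in")
    rng = np.random.default_rng(seed)
    codes, m = locus_codes(gm)
    n, L = codes.shape[:2]
    m_max = max(m)
    a = codes.copy()
    valid = a >= 0                       # (n, L, 2)
    a[~valid] = 0
    allele_ok = np.zeros((L, m_max))
    for j in range(L):
        allele_ok[j, :m[j]] = 1.0

    if pop_alpha:
        pop_idx = pd.factorize(gm.pop)[0]
        n_pop = pop_idx.max() + 1
    else:
        pop_idx = np.zeros(n, dtype=int)
        n_pop = 1
    alpha = np.full(n_pop, float(alpha_init))

    # init
    P = rng.gamma(lambda_ * allele_ok[None, :, :] + 0.0,
                  size=(K, L, m_max)) * allele_ok[None, :, :]
    P /= P.sum(axis=2, keepdims=True)
    Q = rng.dirichlet(np.full(K, alpha_init), size=n)

    l_idx = np.arange(L)[None, :, None]          # broadcast index for gather
    valid_flat = valid.ravel()
    i_of_copy = np.repeat(np.arange(n), L * 2)[valid_flat]
    l_of_copy = np.tile(np.repeat(np.arange(L), 2), n)[valid_flat]
    a_of_copy = a.ravel()[valid_flat]

    q_acc = np.zeros_like(Q)
    p_acc = np.zeros_like(P)
    lnp_samples = []
    alpha_acc = 0.0
    kept = 0
    sd_prop = 0.1

    for sweep in range(sweeps):
        # z | q, p
        G = P[:, l_idx, a]                       # (K, n, L, 2)
        W = np.moveaxis(G, 0, -1) * Q[:, None, None, :]   # (n, L, 2, K)
        tot = W.sum(axis=-1)
        lnp = float(np.log(np.maximum(tot[valid], 1e-300)).sum())
        W = W / np.maximum(tot[..., None], 1e-300)
        u = rng.random((n, L, 2, 1))
        z = (np.cumsum(W, axis=-1) < u).sum(axis=-1)      # (n, L, 2)
        z_flat = z.ravel()[valid_flat]

        # p | z
        codes_p = (z_flat * L + l_of_copy) * m_max + a_of_copy
        counts_p = np.bincount(codes_p, minlength=K * L * m_max).reshape(K, L, m_max)
        shape = (lambda_ + counts_p) * allele_ok[None, :, :]
        P = rng.standard_gamma(shape)
        P *= allele_ok[None, :, :]
        P /= np.maximum(P.sum(axis=2, keepdims=True), 1e-300)

        # q | z
        counts_q = np.bincount(i_of_copy * K + z_flat, minlength=n * K).reshape(n, K)
        Q = rng.standard_gamma(alpha[pop_idx][:, None] + counts_q)
        Q /= np.maximum(Q.sum(axis=1, keepdims=True), 1e-300)
        Q = np.maximum(Q, 1e-300)

        # alpha | q (Metropolis random walk, uniform prior on (0, 10])
        if K > 1:
            lq_sum = np.log(Q)
            for g in range(n_pop):
                rows = lq_sum[pop_idx == g]
                prop = alpha[g] + rng.normal(0.0, sd_prop)
                if 0 < prop <= 10:
                    cur, new = alpha[g], prop
                    n_g = rows.shape[0]
                    def _lp(av):
                        return (n_g * (gammaln(K * av) - K * gammaln(av))
                                + (av - 1.0) * rows.sum())
                    if np.log(rng.random()) < _lp(new) - _lp(cur):
                        alpha[g] = prop

        if sweep >= burn_in:
            q_acc += Q
            p_acc += P
            lnp_samples.append(lnp)
            alpha_acc += alpha.mean()
            kept += 1

    Qm = q_acc / kept
    Qm /= Qm.sum(axis=1, keepdims=True)
    Pm = p_acc / kept
    Pm /= np.maximum(Pm.sum(axis=2, keepdims=True), 1e-300)
    run = ClusterRun(K=K, Q=Qm, P=Pm, lnP=float(np.mean(lnp_samples)),
                     alpha=alpha_acc / kept, seed=seed, sweeps=sweeps,
                     burn_in=burn_in)
    if return_trace:
        return run, np.asarray(lnp_samples)
    return run


# ---------------------------------------------------------------------------
# Evanno Delta K
# ---------------------------------------------------------------------------

def evanno(lnp_by_k: dict) -> pd.DataFrame:
    """Evanno table from replicate log-likelihoods per K.

    lnp_by_k maps K -> iterable of lnP values (>= 2 runs each, >= 3
    consecutive K). Delta K = |L(K+1) - 2 L(K) + L(K-1)| / sd(L(K)) is
    defined for interior K only; sd = 0 yields +inf (flagged).
    """
    ks = sorted(lnp_by_k)
    if len(ks) < 3 or any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("need >= 3 consecutive K values")
    if any(len(list(lnp_by_k[k])) < 2 for k in ks):
        raise ValueError("need >= 2 runs per K")
    mean = {k: float(np.mean(lnp_by_k[k])) for k in ks}
    sd = {k: float(np.std(lnp_by_k[k], ddof=1)) for k in ks}
    rows = []
    for k in ks:
        lp = mean.get(k + 1, np.nan) - mean[k] if k + 1 in mean else np.nan
        lpp = np.nan
        dk = np.nan
        if k - 1 in mean and k + 1 in mean:
            lpp = mean[k + 1] - 2 * mean[k] + mean[k - 1]
            dk = abs(lpp) / sd[k] if sd[k] > 0 else np.inf
        rows.append(dict(K=k, mean_lnP=mean[k], sd_lnP=sd[k],
                         L_prime=lp, L_doubleprime=lpp, delta_K=dk))
    return pd.DataFrame(rows).set_index("K")


def best_k(ev_table: pd.DataFrame) -> int:
    """K with the largest Delta K (interior K only)."""
    dk = ev_table["delta_K"].dropna()
    if dk.empty:
        raise ValueError("no interior K with a defined Delta K")
    return int(dk.idxmax())


# ---------------------------------------------------------------------------
# CLUMPP-style alignment of replicate runs
# ---------------------------------------------------------------------------

def _greedy_permutation(q_ref: np.ndarray, q_run: np.ndarray) -> np.ndarray:
    """Greedy column matching maximising sum of elementwise products."""
    K = q_ref.shape[1]
    sim = q_ref.T @ q_run                 # (K_ref, K_run)
    perm = np.full(K, -1)
    used_ref, used_run = set(), set()
    order = np.dstack(np.unravel_index(np.argsort(sim, axis=None)[::-1],
                                       sim.shape))[0]
    for i, j in order:
        if i not in used_ref and j not in used_run:
            perm[i] = j
            used_ref.add(int(i))
            used_run.add(int(j))
            if len(used_ref) == K:
                break
    return perm


def align_runs(runs: list):
    """Align replicate runs to the first by greedy column permutation and
    return (consensus Q, aligned Q list, permutations). All runs must share
    K and individuals."""
    if not runs:
        raise ValueError("no runs supplied")
    qs = [r.Q if isinstance(r, ClusterRun) else np.asarray(r) for r in runs]
    K = qs[0].shape[1]
    if any(q.shape != qs[0].shape for q in qs):
        raise ValueError("all runs must share K and individuals")
    aligned = [qs[0]]
    perms = [np.arange(K)]
    for q in qs[1:]:
        perm = _greedy_permutation(qs[0], q)
        aligned.append(q[:, perm])
        perms.append(perm)
    consensus = np.mean(aligned, axis=0)
    return consensus, aligned, perms


def q_table(gm: GenotypeMatrix, q: np.ndarray) -> pd.DataFrame:
    """Q matrix as a tidy table (individual, pop, q_1..q_K)."""
    df = pd.DataFrame(q, columns=[f"q_{k + 1}" for k in range(q.shape[1])])
    df.insert(0, "pop", gm.pop)
    df.insert(0, "individual", gm.individuals)
    return df
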