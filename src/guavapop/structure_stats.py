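"""Population-structure statistics: pairwise F_ST, Nei distance, hierarchical
AMOVA, principal-coordinate analysis and Mantel tests.

F_ST is Weir & Cockerham's theta: per-locus, per-allele variance components
a (among populations), b (among individuals within populations) and c
(within individuals), combined multilocus as sum(a)/sum(a+b+c).

AMOVA decomposes squared differences between gene copies (0 if identical
allele, 1 otherwise by default; squared repeat-count difference optionally)
across the nesting groups / individuals / gene copies, with the
level-appropriate permutation schemes for inference. Negative variance
components are retained and reported, never silently truncated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from guavapop.genotypes import MISSING, AlleleFrequencyTable, GenotypeMatrix

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088


@dataclass
class DistanceMatrix:
    """Labelled symmetric distance matrix with a kind tag.

    F_ST entries may be small negatives (unbiased estimators); they are
    preserved and flagged rather than clipped.
    """

    labels: list
    values: np.ndarray
    kind: str = "generic"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if (np.nan_to_num(self.values) < 0).any():
            logger.info("DistanceMatrix(%s): negative entries preserved", self.kind)

    def get(self, a, b) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def to_csv(self, path, sep="\t"):
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# Weir & Cockerham variance components
# ---------------------------------------------------------------------------

def _wc_components(gm: GenotypeMatrix, labels: np.ndarray):
    """Per-locus summed WC (1984) components (a, b, c) over alleles.

    labels assigns each individual to a group; individuals with a missing
    genotype at a locus are excluded for that locus.
    """
    groups = [g for g in dict.fromkeys(labels)]
    r = len(groups)
    out = np.zeros((gm.n_loci, 3))
    for j in range(gm.n_loci):
        ni, p_iu, h_iu, alleles = [], [], [], None
        # collect per-group frequencies and het frequencies
        freq_maps, het_maps = [], []
        for g in groups:
            sub = gm.alleles[labels == g, j, :]
            sub = sub[sub[:, 0] != MISSING]
            n = sub.shape[0]
            ni.append(n)
            if n == 0:
                freq_maps.append({})
                het_maps.append({})
                continue
            vals, cnt = np.unique(sub.ravel(), return_counts=True)
            freq_maps.append({int(v): c / (2 * n) for v, c in zip(vals, cnt)})
            het = sub[sub[:, 0] != sub[:, 1]]
            hm = {}
            for u in vals:
                hm[int(u)] = np.sum((het == u).any(axis=1)) / n
            het_maps.append(hm)
        if any(n < 1 for n in ni) or sum(n > 0 for n in ni) < 2:
            logger.warning("locus %s dropped: a group has no data", gm.loci[j])
            continue
        ni = np.asarray(ni, dtype=float)
        alleles = sorted(set().union(*[set(m) for m in freq_maps]))
        nbar = ni.mean()
        nc = (r * nbar - np.sum(ni ** 2) / (r * nbar)) / (r - 1)
        for u in alleles:
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
            out[j] += (a, b, c)
    return out


def wc_theta(gm: GenotypeMatrix, labels: np.ndarray) -> float:
    """Multilocus Weir-Cockerham theta over the given grouping."""
    comp = _wc_components(gm, labels)
    denom = comp.sum()
    return float(comp[:, 0].sum() / denom) if denom != 0 else np.nan


def pairwise_fst(gm: GenotypeMatrix, partition: str = "pop") -> DistanceMatrix:
    """Pairwise multilocus Weir-Cockerham theta between all groups."""
    labels = gm.pop if partition == "pop" else gm.region
    if labels is None:
        raise ValueError(f"no labels for partition {partition!r}")
    groups = list(dict.fromkeys(labels))
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    k = len(groups)
    mat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            keep = (labels == groups[i]) | (labels == groups[j])
            mat[i, j] = mat[j, i] = wc_theta(gm.subset(keep), labels[keep])
    return DistanceMatrix(labels=groups, values=mat, kind="F_ST")


# ---------------------------------------------------------------------------
# Nei (1972) standard genetic distance
# ---------------------------------------------------------------------------

def nei_distance(aft: AlleleFrequencyTable, pop_a, pop_b) -> float:
    """Nei's standard distance D = -ln(J_xy / sqrt(J_x J_y)), ratio of sums
    over loci. Disjoint allele sets at every locus give +inf (flagged)."""
    jxy = jx = jy = 0.0
    for locus in aft.loci:
        fa = aft.freqs[(locus, pop_a)]
        fb = aft.freqs[(locus, pop_b)]
        jx += sum(v ** 2 for v in fa.values())
        jy += sum(v ** 2 for v in fb.values())
        jxy += sum(fa[a] * fb.get(a, 0.0) for a in fa)
    if jxy == 0:
        logger.warning("nei_distance: no shared alleles; distance infinite")
        return np.inf
    return float(-np.log(jxy / np.sqrt(jx * jy)))


def nei_distance_matrix(aft: AlleleFrequencyTable) -> DistanceMatrix:
    groups = aft.groups
    k = len(groups)
    mat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            mat[i, j] = mat[j, i] = nei_distance(aft, groups[i], groups[j])
    return DistanceMatrix(labels=groups, values=mat, kind="Nei1972")


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

@dataclass
class AmovaResult:
    """Hierarchical AMOVA: df, SS, variance components, percentages,
    Phi-statistics and permutation p-values per level."""

    table: pd.DataFrame
    phi: dict = field(default_factory=dict)
    p_values: dict = field(default_factory=dict)

    def to_csv(self, path, sep="\t"):
        self.table.to_csv(path, sep=sep)


def _amova_ss(gm: GenotypeMatrix, groups: np.ndarray, metric: str):
    """Sums of squares per level from gene-copy distances.

    The 0/1 identity metric equals half the squared Euclidean distance of
    one-hot allele vectors, so SS of a set = sum of squared deviations from
    the set centroid; with metric="rst" copies are repeat counts and the
    distance is the squared count difference.
    Returns (ss_among_groups, ss_among_ind, ss_within_ind, df triple, n_c).
    """
    ss_ag = ss_ai = ss_wi = 0.0
    df_ag = df_ai = df_wi = 0
    nc_list = []
    group_list = list(dict.fromkeys(groups))
    r = len(group_list)
    for j in range(gm.n_loci):
        col = gm.alleles[:, j, :]
        keep = col[:, 0] != MISSING
        if keep.sum() < 2:
            continue
        sub = col[keep]
        glab = groups[keep]
        if metric == "rst":
            x = sub.astype(float)[:, :, None]  # coords = repeat count
        else:
            vals = np.unique(sub)
            # one-hot / sqrt(2): |u-v|^2 = 1 for distinct alleles
            x = (sub[:, :, None] == vals[None, None, :]) / np.sqrt(2.0)
        flat = x.reshape(-1, x.shape[2])  # 2 copies per kept individual
        copies_g = np.repeat(glab, 2)

        def ss_of(idx):
            pts = flat[idx]
            return float(np.sum((pts - pts.mean(axis=0)) ** 2))

        ss_t = ss_of(np.arange(flat.shape[0]))
        ss_wp = 0.0
        n_g = []
        for g in group_list:
            idx = np.flatnonzero(copies_g == g)
            n_g.append(idx.size)
            if idx.size:
                ss_wp += ss_of(idx)
        ss_wi_l = 0.0
        for i in range(sub.shape[0]):
            ss_wi_l += ss_of(np.array([2 * i, 2 * i + 1]))
        n_ind = sub.shape[0]
        n_g = np.asarray(n_g, dtype=float)
        n_copies = n_g.sum()
        ss_ag += ss_t - ss_wp
        ss_ai += ss_wp - ss_wi_l
        ss_wi += ss_wi_l
        df_ag += r - 1
        df_ai += n_ind - r
        df_wi += n_ind
        if r > 1:
            nc_list.append((n_copies - np.sum(n_g ** 2) / n_copies) / (r - 1))
    return (ss_ag, ss_ai, ss_wi), (df_ag, df_ai, df_wi), nc_list


def _amova_components(gm: GenotypeMatrix, groups: np.ndarray, metric: str):
    (ss_ag, ss_ai, ss_wi), (df_ag, df_ai, df_wi), nc_list = _amova_ss(gm, groups, metric)
    nc = float(np.mean(nc_list)) if nc_list else np.nan
    ms_wi = ss_wi / df_wi if df_wi > 0 else np.nan
    ms_ai = ss_ai / df_ai if df_ai > 0 else np.nan
    ms_ag = ss_ag / df_ag if df_ag > 0 else np.nan
    sigma_c = ms_wi
    sigma_b = (ms_ai - sigma_c) / 2.0
    sigma_a = (ms_ag - sigma_c - 2.0 * sigma_b) / (2.0 * nc) if df_ag > 0 else np.nan
    return dict(ss=(ss_ag, ss_ai, ss_wi), df=(df_ag, df_ai, df_wi),
                sigma=(sigma_a, sigma_b, sigma_c))


def amova(gm: GenotypeMatrix, groups=None, n_perm: int = 1000, seed=None,
          metric: str = "fst") -> AmovaResult:
    """Locus-by-locus AMOVA over groups / individuals / gene copies.

    groups defaults to the population labels. metric="fst" scores gene-copy
    pairs 0/1 (identity); metric="rst" uses squared repeat-count differences.
    p-values: among-groups by permuting individuals among groups;
    among-individuals by permuting gene copies among individuals within
    groups (implemented by re-pairing copies within each group).
    """
    labels = gm.pop if groups is None else np.asarray(groups, dtype=object)
    comp = _amova_components(gm, labels, metric)
    sigma_a, sigma_b, sigma_c = comp["sigma"]
    total = sigma_a + sigma_b + sigma_c
    pct = 100.0 * np.array([sigma_a, sigma_b, sigma_c]) / total
    phi_ct = sigma_a / total
    phi_is = sigma_b / (sigma_b + sigma_c)
    phi_it = (sigma_a + sigma_b) / total

    rng = np.random.default_rng(seed)
    # among groups: permute individuals among groups
    n_extreme_a = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        s = _amova_components(gm, perm, metric)["sigma"][0]
        if s >= sigma_a - 1e-12:
            n_extreme_a += 1
    p_a = (1 + n_extreme_a) / (1 + n_perm)
    # among individuals within groups: re-pair gene copies within groups
    n_extreme_b = 0
    for _ in range(n_perm):
        shuffled = _repair_copies_within_groups(gm, labels, rng)
        s = _amova_components(shuffled, labels, metric)["sigma"][1]
        if s >= sigma_b - 1e-12:
            n_extreme_b += 1
    p_b = (1 + n_extreme_b) / (1 + n_perm)

    table = pd.DataFrame({
        "df": comp["df"],
        "SS": comp["ss"],
        "variance": (sigma_a, sigma_b, sigma_c),
        "pct_variation": pct,
    }, index=["Between groups", "Between samples within group", "Within samples"])
    return AmovaResult(table=table,
                       phi=dict(phi_ct=phi_ct, phi_is=phi_is, phi_it=phi_it),
                       p_values=dict(among_groups=p_a, among_individuals=p_b))


def _repair_copies_within_groups(gm: GenotypeMatrix, labels, rng) -> GenotypeMatrix:
    """Randomly re-pair gene copies among individuals within each group,
    independently per locus (the within-individual permutation scheme)."""
    alleles = gm.alleles.copy()
    for g in dict.fromkeys(labels):
        idx = np.flatnonzero(labels == g)
        for j in range(gm.n_loci):
            block = alleles[idx, j, :]
            keep = block[:, 0] != MISSING
            pool = block[keep].ravel()
            pool = pool[rng.permutation(pool.size)]
            block[keep] = pool.reshape(-1, 2)
            alleles[idx, j, :] = block
    return GenotypeMatrix(individuals=list(gm.individuals), loci=list(gm.loci),
                          alleles=alleles, pop=gm.pop.copy())


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

@dataclass
class PcoaResult:
    coordinates: np.ndarray      # (n, n_axes) ordered by eigenvalue
    eigenvalues: np.ndarray      # all eigenvalues, descending (negatives kept)
    percent_variance: np.ndarray  # share of sum of positive eigenvalues
    labels: list = None


def pcoa(dm: DistanceMatrix) -> PcoaResult:
    """Principal-coordinate analysis by double-centering of -D^2/2.

    Negative eigenvalues (non-Euclidean input) are reported, not dropped;
    coordinate axes use only positive eigenvalues.
    """
    d = dm.values
    n = d.shape[0]
    b = -0.5 * d ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = j @ b @ j
    w, v = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    pos = w > 1e-10
    coords = v[:, pos] * np.sqrt(w[pos])
    pct = np.zeros_like(w)
    if pos.any():
        pct[pos] = 100.0 * w[pos] / w[pos].sum()
    return PcoaResult(coordinates=coords, eigenvalues=w, percent_variance=pct,
                      labels=list(dm.labels))


def dosage_matrix(gm: GenotypeMatrix) -> np.ndarray:
    """Individuals x alleles dosage matrix (0/1/2 copies per allele), with
    missing genotypes imputed to the locus mean dosage. Basis for the
    individual-level Euclidean distance used in PCoA."""
    cols = []
    for j in range(gm.n_loci):
        col = gm.alleles[:, j, :]
        keep = col[:, 0] != MISSING
        vals = np.unique(col[keep])
        dos = np.zeros((gm.n_individuals, len(vals)))
        for k, u in enumerate(vals):
            dos[:, k] = (col == u).sum(axis=1)
        if keep.any() and (~keep).any():
            dos[~keep] = dos[keep].mean(axis=0)
        cols.append(dos)
    return np.concatenate(cols, axis=1)


def individual_distances(gm: GenotypeMatrix) -> DistanceMatrix:
    """Euclidean distances between individuals' allele-dosage vectors."""
    x = dosage_matrix(gm)
    sq = np.sum(x ** 2, axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2 * x @ x.T, 0.0)
    return DistanceMatrix(labels=list(gm.individuals), values=np.sqrt(d2),
                          kind="Euclidean-individual")


# ---------------------------------------------------------------------------
# Mantel test and geographic distances
# ---------------------------------------------------------------------------

def mantel(dm_a: DistanceMatrix, dm_b: DistanceMatrix,
           n_perm: int = 10_000, seed=None):
    """Mantel test: Pearson r of lower-triangle entries; null by simultaneous
    row/column permutation of the second matrix. Returns (r, r^2, p)."""
    if dm_a.labels != dm_b.labels:
        raise ValueError("distance matrices must share labels")
    n = len(dm_a.labels)
    if n < 3:
        raise ValueError("need at least 3 labels")
    il = np.tril_indices(n, -1)
    xa = dm_a.values[il]
    b = dm_b.values

    def corr(mat):
        xb = mat[il]
        return float(np.corrcoef(xa, xb)[0, 1])

    r_obs = corr(b)
    rng = np.random.default_rng(seed)
    n_extreme = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if abs(corr(b[np.ix_(perm, perm)])) >= abs(r_obs) - 1e-12:
            n_extreme += 1
    p = (1 + n_extreme) / (1 + n_perm)
    return r_obs, r_obs ** 2, p


def geographic_distances(coords: dict) -> DistanceMatrix:
    """Great-circle (haversine) distances in km between labelled points.

    coords maps label -> (lat, lon) in decimal degrees.
    """
    labels = list(coords)
    missing = [k for k, v in coords.items()
               if v is None or np.any(np.isnan(np.asarray(v, dtype=float)))]
    if missing:
        raise ValueError(f"missing coordinates for: {missing}")
    pts = np.radians(np.array([coords[k] for k in labels], dtype=float))
    lat, lon = pts[:, 0], pts[:, 1]
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    return DistanceMatrix(labels=labels, values=d, kind="geographic-km")


def region_centroids(gm: GenotypeMatrix) -> dict:
    """Mean (lat, lon) per region (falls back to population labels)."""
    labels = gm.region if gm.region is not None else gm.pop
    if gm.coords is None:
        raise ValueError("matrix has no coordinates")
    out = {}
    for g in dict.fromkeys(labels):
        pts = gm.coords[labels == g]
        out[g] = tuple(np.nanmean(pts, axis=0))
    return out
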