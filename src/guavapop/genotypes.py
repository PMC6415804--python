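"""Diploid SSR genotype container and file formats.

Genotypes are unordered pairs of positive integer allele labels (fragment
sizes in bp or repeat counts). A genotype is either fully observed (both
copies present) or missing; half-calls are promoted to missing at parse
time with a logged warning, because every downstream estimator assumes 0
or 2 gene copies per individual per locus.

Supported formats: GenePop 4.x (2- or 3-digit allele coding) and a simple
delimited-text dialect (one row per individual: id, pop, region, lat, lon,
then two columns per locus).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Sentinel for a missing allele copy. Never a valid label (labels are > 0).
MISSING = -1


class GenepopParseError(ValueError):
    """Raised when a GenePop file cannot be parsed; names the line number."""


@dataclass
class GenotypeMatrix:
    """Individuals x loci grid of diploid SSR genotypes.

    Attributes
    ----------
    individuals : list of str
        Unique individual identifiers, one per row.
    loci : list of str
        Unique locus names, one per column.
    alleles : ndarray of shape (n_individuals, n_loci, 2), dtype int
        Allele labels; both entries ``MISSING`` for a missing genotype.
    pop : ndarray of str
        Population label per individual.
    region : ndarray of str or None
        Optional sub-population (sampling region) label per individual.
    coords : ndarray of shape (n_individuals, 2) or None
        Optional (lat, lon) in decimal degrees per individual.
    """

    individuals: list
    loci: list
    alleles: np.ndarray
    pop: np.ndarray
    region: np.ndarray | None = None
    coords: np.ndarray | None = None

    def __post_init__(self):
        self.alleles = np.asarray(self.alleles, dtype=np.int64)
        self.pop = np.asarray(self.pop, dtype=object)
        if self.alleles.ndim != 3 or self.alleles.shape[2] != 2:
            raise ValueError("alleles must have shape (n_individuals, n_loci, 2)")
        n, L = self.alleles.shape[:2]
        if n < 1 or L < 1:
            raise ValueError("need at least one individual and one locus")
        if len(self.individuals) != n:
            raise ValueError("individuals length does not match allele grid")
        if len(self.loci) != L:
            raise ValueError("loci length does not match allele grid")
        if len(set(self.loci)) != L:
            raise ValueError("locus names must be unique")
        if self.pop.shape[0] != n:
            raise ValueError("every individual needs a population label")
        half = (self.alleles == MISSING).sum(axis=2) == 1
        if half.any():
            # promote half-calls to fully missing
            logger.warning("promoting %d half-missing genotypes to missing", half.sum())
            self.alleles = self.alleles.copy()
            self.alleles[half] = MISSING
        present = self.alleles != MISSING
        if (self.alleles[present] <= 0).any():
            raise ValueError("allele labels must be positive integers")
        if self.region is not None:
            self.region = np.asarray(self.region, dtype=object)
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)

    # -- basic introspection -------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_loci(self) -> int:
        return self.alleles.shape[1]

    @property
    def populations(self) -> list:
        """Population labels in order of first appearance."""
        seen, out = set(), []
        for p in self.pop:
            if p not in seen:
                seen.add(p)
                out.append(p)
        return out

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_individuals, n_loci) mask of missing genotypes."""
        return self.alleles[:, :, 0] == MISSING

    def subset(self, mask) -> "GenotypeMatrix":
        """Row-subset by boolean mask or index array."""
        idx = np.asarray(mask)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            individuals=[self.individuals[i] for i in idx],
            loci=list(self.loci),
            alleles=self.alleles[idx],
            pop=self.pop[idx],
            region=None if self.region is None else self.region[idx],
            coords=None if self.coords is None else self.coords[idx],
        )

    def by_population(self, label) -> "GenotypeMatrix":
        return self.subset(self.pop == label)

    def equals(self, other: "GenotypeMatrix") -> bool:
        """Equality of ids, loci, genotypes (as unordered pairs) and labels."""
        if self.individuals != other.individuals or self.loci != other.loci:
            return False
        if not np.array_equal(np.sort(self.alleles, axis=2),
                              np.sort(other.alleles, axis=2)):
            return False
        return bool(np.array_equal(self.pop, other.pop))


@dataclass
class AlleleFrequencyTable:
    """Per (locus, group) allele frequencies and gene-copy counts.

    ``freqs[(locus, group)]`` maps allele label -> relative frequency among
    the observed gene copies; ``n[(locus, group)]`` is the gene-copy count
    (2 x non-missing individuals). A cell with no data has an empty mapping
    and n = 0.
    """

    loci: list
    groups: list
    freqs: dict = field(default_factory=dict)
    n: dict = field(default_factory=dict)

    def counts(self, locus, group) -> dict:
        """Absolute gene-copy counts per allele for one cell."""
        nn = self.n[(locus, group)]
        return {a: f * nn for a, f in self.freqs[(locus, group)].items()}

    def alleles_at(self, locus) -> list:
        """Sorted union of allele labels observed at a locus over all groups."""
        out = set()
        for g in self.groups:
            out.update(self.freqs[(locus, g)])
        return sorted(out)


def allele_frequencies(gm: GenotypeMatrix, partition: str = "pop") -> AlleleFrequencyTable:
    """Tabulate allele frequencies per locus within each group of *partition*.

    partition is ``"pop"``, ``"region"`` or ``"all"`` (single pooled group).
    Missing genotypes are excluded; the gene-copy count n is recorded per
    (locus, group) cell. An empty cell is not an error (empty map, n=0).
    """
    if partition == "pop":
        labels = gm.pop
    elif partition == "region":
        if gm.region is None:
            raise ValueError("matrix has no region labels")
        labels = gm.region
    elif partition == "all":
        labels = np.asarray(["all"] * gm.n_individuals, dtype=object)
    else:
        raise ValueError(f"unknown partition {partition!r}")

    seen, groups = set(), []
    for g in labels:
        if g not in seen:
            seen.add(g)
            groups.append(g)

    aft = AlleleFrequencyTable(loci=list(gm.loci), groups=groups)
    for g in groups:
        sub = gm.alleles[labels == g]  # (m, L, 2)
        for j, locus in enumerate(gm.loci):
            copies = sub[:, j, :].ravel()
            copies = copies[copies != MISSING]
            nn = copies.size
            if nn == 0:
                aft.freqs[(locus, g)] = {}
                aft.n[(locus, g)] = 0
                continue
            vals, cnt = np.unique(copies, return_counts=True)
            aft.freqs[(locus, g)] = {int(a): c / nn for a, c in zip(vals, cnt)}
            aft.n[(locus, g)] = int(nn)
    return aft


# ---------------------------------------------------------------------------
# GenePop format
# ---------------------------------------------------------------------------

def read_genepop(path, pop_labels=None) -> GenotypeMatrix:
    """Parse a GenePop 4.x file (2- or 3-digit allele coding).

    All-zero allele codes map to missing. Population labels are taken from
    the last individual name of each POP block (the GenePop convention)
    unless *pop_labels* supplies one label per block.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise GenepopParseError("empty file")

    # line 1: title; then locus names until the first POP
    loci: list = []
    i = 1
    while i < len(lines) and lines[i].strip().upper() != "POP":
        chunk = lines[i].strip()
        if chunk:
            loci.extend(x.strip() for x in chunk.split(",") if x.strip())
        i += 1
    if not loci:
        raise GenepopParseError(f"line {i + 1}: no locus names before first POP")

    blocks: list = []  # list of list of (name, [codes]) per POP block
    current = None
    for lineno in range(i, len(lines)):
        raw = lines[lineno].strip()
        if not raw:
            continue
        if raw.upper() == "POP":
            if current is not None and not current:
                raise GenepopParseError(f"line {lineno + 1}: empty POP block")
            current = []
            blocks.append(current)
            continue
        if current is None:
            raise GenepopParseError(f"line {lineno + 1}: data before first POP")
        if "," not in raw:
            raise GenepopParseError(f"line {lineno + 1}: missing ',' separator")
        name, _, rest = raw.partition(",")
        codes = rest.split()
        if len(codes) != len(loci):
            raise GenepopParseError(
                f"line {lineno + 1}: expected {len(loci)} genotypes, got {len(codes)}")
        for c in codes:
            if len(c) % 2 != 0 or not c.isdigit():
                raise GenepopParseError(f"line {lineno + 1}: bad genotype code {c!r}")
        current.append((name.strip(), codes))
    if current is not None and not current:
        raise GenepopParseError("trailing empty POP block")
    if not blocks:
        raise GenepopParseError("no POP blocks found")
    if pop_labels is not None and len(pop_labels) != len(blocks):
        raise GenepopParseError("pop_labels length does not match POP block count")

    individuals, pops, rows = [], [], []
    for b, block in enumerate(blocks):
        label = pop_labels[b] if pop_labels is not None else block[-1][0]
        for name, codes in block:
            geno = np.empty((len(loci), 2), dtype=np.int64)
            for j, c in enumerate(codes):
                d = len(c) // 2
                a1, a2 = int(c[:d]), int(c[d:])
                geno[j, 0] = a1 if a1 > 0 else MISSING
                geno[j, 1] = a2 if a2 > 0 else MISSING
            individuals.append(name)
            pops.append(label)
            rows.append(geno)
    logger.info("read_genepop: %d individuals, %d loci, %d populations",
                len(individuals), len(loci), len(blocks))
    return GenotypeMatrix(individuals=individuals, loci=loci,
                          alleles=np.stack(rows), pop=np.asarray(pops, dtype=object))


def write_genepop(gm: GenotypeMatrix, path, digits: int = 3, title: str = "guavapop export"):
    """Write a GenotypeMatrix as a GenePop file with the given digit coding."""
    present = gm.alleles[gm.alleles != MISSING]
    if present.size and present.max() >= 10 ** digits:
        raise ValueError(
            f"allele label {present.max()} does not fit {digits}-digit coding")
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for locus in gm.loci:
            fh.write(locus + "\n")
        for p in gm.populations:
            fh.write("POP\n")
            sub_idx = np.flatnonzero(gm.pop == p)
            for i in sub_idx:
                codes = []
                for j in range(gm.n_loci):
                    a1, a2 = gm.alleles[i, j]
                    a1 = 0 if a1 == MISSING else a1
                    a2 = 0 if a2 == MISSING else a2
                    codes.append(f"{a1:0{digits}d}{a2:0{digits}d}")
                fh.write(f"{gm.individuals[i]} , " + " ".join(codes) + "\n")
    logger.info("write_genepop: wrote %d individuals to %s", gm.n_individuals, path)


# ---------------------------------------------------------------------------
# Delimited text dialect
# ---------------------------------------------------------------------------

def read_delimited(path, sep: str = "\t") -> GenotypeMatrix:
    """Read the delimited dialect: id, pop, region, lat, lon, then 2 columns per locus.

    Empty cells or "NA" denote missing allele copies.
    """
    import csv

    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=sep)
        header = next(reader)
        if len(header) < 7 or (len(header) - 5) % 2 != 0:
            raise ValueError("header must be id,pop,region,lat,lon + 2 cols per locus")
        loci = []
        for k in range(5, len(header), 2):
            name = header[k]
            loci.append(name[:-2] if name.endswith("_1") else name)
        individuals, pops, regions, coords, rows = [], [], [], [], []
        for lineno, row in enumerate(reader, start=2):
            if not row or not any(x.strip() for x in row):
                continue
            if len(row) != len(header):
                raise ValueError(f"line {lineno}: ragged row")
            individuals.append(row[0])
            pops.append(row[1])
            regions.append(row[2] if row[2].strip() else "")
            lat = float(row[3]) if row[3].strip() not in ("", "NA") else np.nan
            lon = float(row[4]) if row[4].strip() not in ("", "NA") else np.nan
            coords.append((lat, lon))
            geno = np.empty((len(loci), 2), dtype=np.int64)
            for j in range(len(loci)):
                for c in (0, 1):
                    cell = row[5 + 2 * j + c].strip()
                    geno[j, c] = MISSING if cell in ("", "NA", "0") else int(cell)
            rows.append(geno)
    region_arr = np.asarray(regions, dtype=object)
    if not any(regions):
        region_arr = None
    coord_arr = np.asarray(coords, dtype=float)
    if np.isnan(coord_arr).all():
        coord_arr = None
    logger.info("read_delimited: %d individuals, %d loci", len(individuals), len(loci))
    return GenotypeMatrix(individuals=individuals, loci=loci, alleles=np.stack(rows),
                          pop=np.asarray(pops, dtype=object),
                          region=region_arr, coords=coord_arr)


def write_delimited(gm: GenotypeMatrix, path, sep: str = "\t"):
    """Write the delimited dialect read by :func:`read_delimited`."""
    with open(path, "w") as fh:
        cols = ["id", "pop", "region", "lat", "lon"]
        for locus in gm.loci:
            cols += [f"{locus}_1", f"{locus}_2"]
        fh.write(sep.join(cols) + "\n")
        for i in range(gm.n_individuals):
            region = "" if gm.region is None else str(gm.region[i])
            if gm.coords is None or np.isnan(gm.coords[i]).any():
                lat = lon = "NA"
            else:
                lat, lon = (f"{x:.6f}" for x in gm.coords[i])
            row = [str(gm.individuals[i]), str(gm.pop[i]), region, str(lat), str(lon)]
            for j in range(gm.n_loci):
                for c in (0, 1):
                    a = gm.alleles[i, j, c]
                    row.append("NA" if a == MISSING else str(int(a)))
            fh.write(sep.join(row) + "\n")


# ---------------------------------------------------------------------------
# Fast internal helpers (used by simulation-heavy modules)
# ---------------------------------------------------------------------------

def locus_codes(gm: GenotypeMatrix):
    """Integer-code alleles per locus for vectorised work.

    Returns (codes, n_alleles) where codes has shape (n, L, 2) with values
    in 0..m_l-1 per locus (missing stays MISSING) and n_alleles lists m_l.
    """
    codes = np.full_like(gm.alleles, MISSING)
    m = []
    for j in range(gm.n_loci):
        col = gm.alleles[:, j, :]
        obs = col != MISSING
        vals = np.unique(col[obs])
        m.append(len(vals))
        if len(vals):
            codes[:, j, :][obs] = np.searchsorted(vals, col[obs])
    return codes, m
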