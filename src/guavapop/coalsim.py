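"""Backward-time coalescent simulator of microsatellite data under
island-colonisation demographic scenarios.

The demographic model space mirrors a three-island invasion: one island
holds the ancestral population and the other two are founded by
introduction events (each with a founder bottleneck of size N_b lasting
d_b generations), or the central island is founded by admixture of the
other two with rate r_a. Time is measured in generations before present
and the continuous-time coalescent approximation is used (rate
C(k,2)/(2N) for k lineages in a diploid population of size N).

Mutation follows the stepwise model (SMM: every mutation is +-1 repeat
unit) or the two-phase model (TPM: single steps with probability p_single,
otherwise geometric multi-step jumps), applied to an unbounded integer
allele state anchored at 100 repeats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from guavapop.genotypes import GenotypeMatrix

ANCESTRAL_STATE = 100
ISLANDS = ("ISA", "SCZ", "SCY")  # pop roles 1, 2, 3


@dataclass
class MutationModel:
    """SMM or TPM mutation model for SSR repeat counts.

    rate is the per-locus per-generation mutation rate; if rate_range is
    given, each locus draws its own rate uniformly from that interval.
    p_single is the probability a mutation is a single +-1 step (1 for
    SMM); multi-step jump sizes are geometric with mean geom_mean.
    """

    kind: str = "SMM"
    rate: float = 5e-4
    p_single: float = 1.0
    geom_mean: float = 2.8
    rate_range: tuple | None = None

    def __post_init__(self):
        if self.kind not in ("SMM", "TPM"):
            raise ValueError("kind must be SMM or TPM")
        if self.kind == "SMM":
            self.p_single = 1.0
        elif not 0 < self.p_single < 1:
            raise ValueError("TPM requires p_single in (0, 1)")
        if not 0 <= self.rate < 1:
            raise ValueError("rate must be in [0, 1)")
        if self.geom_mean < 1:
            raise ValueError("geom_mean must be >= 1")


@dataclass(frozen=True)
class SplitEvent:
    """target founded from source at time `time`; looking backward, target
    lineages move into source. A founder bottleneck of size `founder_size`
    applies for the `duration` generations after founding (forward time)."""

    time: str
    target: int
    source: int
    founder_size: str
    duration: str = "db"


@dataclass(frozen=True)
class AdmixtureEvent:
    """target founded at `time` by sources A (rate r_a) and B (1 - r_a),
    with a founder bottleneck like a split."""

    time: str
    target: int
    source_a: int
    source_b: int
    rate: str = "ra"
    founder_size: str = ""
    duration: str = "db"


@dataclass
class DemographicScenario:
    """DAG of island populations with split/admixture founding events.

    pop i (0-based) has present diploid size parameter size_params[i];
    events are ordered oldest-last by their time parameters at draw time.
    Every target is founded exactly once.
    """

    id: str
    events: tuple
    n_pops: int = 3
    size_params: tuple = ("N1", "N2", "N3")
    pop_names: tuple = ISLANDS

    def __post_init__(self):
        targets = [e.target for e in self.events]
        if len(set(targets)) != len(targets):
            raise ValueError("every target must be founded exactly once")

    @property
    def ancestral(self) -> int:
        founded = {e.target for e in self.events}
        anc = [p for p in range(self.n_pops) if p not in founded]
        if len(anc) != 1:
            raise ValueError("scenario must leave exactly one ancestral population")
        return anc[0]

    def parameter_names(self) -> list:
        names = set(self.size_params)
        for e in self.events:
            names.add(e.time)
            names.add(e.duration)
            if e.founder_size:
                names.add(e.founder_size)
            if isinstance(e, AdmixtureEvent):
                names.add(e.rate)
        return sorted(names)

    def describe(self) -> str:
        """Canonical one-line serialisation of the topology."""
        parts = [f"ancestral={self.pop_names[self.ancestral]}"]
        for e in self.events:
            t = self.pop_names[e.target]
            if isinstance(e, SplitEvent):
                parts.append(f"{e.time}:{self.pop_names[e.source]}->{t}")
            else:
                parts.append(f"{e.time}:{self.pop_names[e.source_a]}+"
                             f"{self.pop_names[e.source_b]}->{t}(r={e.rate})")
        return "; ".join(parts)


@dataclass
class PriorSpec:
    """Independent uniform priors over scenario parameters.

    Sizes, times and the bottleneck duration share the default 10.0-10000.0
    range; the admixture rate r_a is uniform on (0.001, 0.999). Draws are
    resampled until t2 >= t1; one d_b is shared by all events of a draw.
    """

    size_range: tuple = (10.0, 10000.0)
    time_range: tuple = (10.0, 10000.0)
    duration_range: tuple = (10.0, 10000.0)
    admixture_range: tuple = (0.001, 0.999)

    def __post_init__(self):
        for lo, hi in (self.size_range, self.time_range,
                       self.duration_range, self.admixture_range):
            if not (0 < lo < hi):
                raise ValueError("prior ranges need 0 < lower < upper")

    def sample(self, scenario: DemographicScenario, rng: np.random.Generator) -> dict:
        draw = {}
        for name in scenario.parameter_names():
            if name.startswith("N"):
                draw[name] = rng.uniform(*self.size_range)
            elif name.startswith("t"):
                draw[name] = rng.uniform(*self.time_range)
            elif name == "db":
                draw[name] = rng.uniform(*self.duration_range)
            elif name == "ra":
                draw[name] = rng.uniform(*self.admixture_range)
            else:
                raise ValueError(f"unknown parameter {name}")
        while "t1" in draw and "t2" in draw and draw["t2"] < draw["t1"]:
            draw["t1"] = rng.uniform(*self.time_range)
            draw["t2"] = rng.uniform(*self.time_range)
        return draw


def sample_priors(scenario: DemographicScenario, prior_spec: PriorSpec,
                  rng: np.random.Generator) -> dict:
    """Draw one parameter set for a scenario (uniforms, t2 >= t1 enforced)."""
    return prior_spec.sample(scenario, rng)


# ---------------------------------------------------------------------------
# scenario space
# ---------------------------------------------------------------------------

def build_scenario_space() -> list:
    """Enumerate the 14 colonisation scenarios of the three-island design.

    Scenarios 1-12: one island ancestral; the other two are founded by
    independent introductions (older event t2 from the ancestor, recent
    event t1 sourced either from the ancestor or from the first-founded
    island), each with a founder bottleneck. Scenarios 13-14: Santa Cruz
    founded at t1 by admixture of the other two islands, whose own history
    (which of them is ancestral) differs between the two.
    """
    isa, scz, scy = 0, 1, 2
    founder = {isa: "N1b", scz: "N2b", scy: "N3b"}
    out = []
    k = 0
    for anc in (isa, scz, scy):
        others = [p for p in (isa, scz, scy) if p != anc]
        for first in others:
            second = others[0] if others[1] == first else others[1]
            for src2 in (anc, first):
                k += 1
                ev = (SplitEvent("t1", second, src2, founder[second]),
                      SplitEvent("t2", first, anc, founder[first]))
                out.append(DemographicScenario(id=f"S{k:02d}", events=ev))
    for anc in (scy, isa):
        k += 1
        first = isa if anc == scy else scy
        ev = (AdmixtureEvent("t1", scz, isa, scy, founder_size=founder[scz]),
              SplitEvent("t2", first, anc, founder[first]))
        out.append(DemographicScenario(id=f"S{k:02d}", events=ev))
    assert len(out) == 14
    return out


def default_study_scenario(space=None) -> DemographicScenario:
    """The serial-introduction topology: ancestral San Cristobal seeds
    Isabela at the older event t2; Isabela seeds Santa Cruz at t1."""
    space = build_scenario_space() if space is None else space
    want = "ancestral=SCY; t1:ISA->SCZ; t2:SCY->ISA"
    for s in space:
        if s.describe() == want:
            return s
    raise RuntimeError("scenario space is missing the serial topology")


# ---------------------------------------------------------------------------
# core simulation
# ---------------------------------------------------------------------------

def _epoch_size(pop, t_mid, present_sizes, foundings, params):
    """Diploid size of pop at backward time t_mid (None if pop not yet
    founded looking forward, i.e. inactive in this epoch)."""
    if pop in foundings:
        t_found, n_b, d_b = foundings[pop]
        if t_mid >= t_found:
            return None
        if t_mid >= max(t_found - d_b, 0.0):
            return n_b
    return present_sizes[pop]


def simulate_locus_tree(scenario: DemographicScenario, params: dict,
                        sample_copies, rng: np.random.Generator):
    """Simulate one genealogy; returns (parent, node_times) arrays of length
    2*n_total - 1 (root has parent -1). Tips 0..n-1 are grouped by
    population in sample order."""
    n_pops = scenario.n_pops
    present = [float(params[scenario.size_params[p]]) for p in range(n_pops)]
    for p, n in enumerate(present):
        if n <= 0:
            raise ValueError(f"population {scenario.pop_names[p]} has size {n}")
    foundings = {}
    for e in scenario.events:
        t = float(params[e.time])
        d = float(params[e.duration])
        nb = float(params[e.founder_size]) if e.founder_size else present[e.target]
        if nb <= 0:
            raise ValueError(f"founder size {e.founder_size} <= 0 at event {e}")
        foundings[e.target] = (t, nb, min(d, t))
    events = sorted(scenario.events, key=lambda e: float(params[e.time]))

    n_total = int(sum(sample_copies))
    parent = np.full(2 * n_total - 1, -1, dtype=np.int64)
    node_time = np.zeros(2 * n_total - 1)
    lineages = {p: [] for p in range(n_pops)}
    tip = 0
    for p, sc in enumerate(sample_copies):
        lineages[p] = list(range(tip, tip + int(sc)))
        tip += int(sc)
    next_node = n_total

    # epoch breakpoints: bottleneck starts and event times
    breaks = sorted({max(t - d, 0.0) for (t, _, d) in foundings.values()}
                    | {t for (t, _, d) in foundings.values()})
    breaks = [b for b in breaks if b > 0]
    event_at = {}
    for e in events:
        event_at.setdefault(float(params[e.time]), []).append(e)

    def coalesce(pop, t0, t1, size):
        nonlocal next_node
        lins = lineages[pop]
        k = len(lins)
        if k < 2:
            return
        j = np.arange(k, 1, -1, dtype=float)
        waits = rng.exponential(1.0, size=k - 1) * (2.0 * size) / (j * (j - 1) / 2.0)
        times = t0 + np.cumsum(waits)
        if np.isfinite(t1):
            m = int(np.searchsorted(times, t1, side="right"))
        else:
            m = k - 1
        if m == 0:
            return
        sizes_now = np.arange(k, k - m, -1)
        pick_a = rng.integers(0, sizes_now)
        pick_b = rng.integers(0, sizes_now - 1)
        tm = times[:m]
        for i in range(m):
            a = int(pick_a[i])
            b = int(pick_b[i])
            if b >= a:
                b += 1
            if a > b:
                a, b = b, a
            node = next_node
            next_node += 1
            node_time[node] = tm[i]
            parent[lins[a]] = node
            parent[lins[b]] = node
            lins[a] = node
            lins[b] = lins[-1]
            lins.pop()

    t_prev = 0.0
    for t_break in breaks:
        for p in range(n_pops):
            size = _epoch_size(p, (t_prev + t_break) / 2.0, present, foundings, params)
            if size is not None and lineages[p]:
                coalesce(p, t_prev, t_break, size)
        for e in event_at.get(t_break, []):
            tgt = lineages[e.target]
            if isinstance(e, SplitEvent):
                lineages[e.source].extend(tgt)
            else:
                ra = float(params[e.rate])
                to_a = rng.random(len(tgt)) < ra
                for lin, a_side in zip(tgt, to_a):
                    lineages[e.source_a if a_side else e.source_b].append(lin)
            lineages[e.target] = []
        t_prev = t_break
    # ancestral epoch: only one population should still hold lineages
    active = [p for p in range(n_pops) if lineages[p]]
    if len(active) > 1:
        raise ValueError(f"lineages remain in {active} after all events")
    anc = active[0]
    coalesce(anc, t_prev, np.inf, present[anc])
    return parent, node_time


def mutate_tree(parent, node_time, mu: float, model: MutationModel,
                rng: np.random.Generator, n_tips: int) -> np.ndarray:
    """Drop Poisson mutations on branches and return tip repeat counts."""
    n_nodes = parent.shape[0]
    has_parent = parent >= 0
    blen = np.zeros(n_nodes)
    blen[has_parent] = node_time[parent[has_parent]] - node_time[has_parent]
    m = rng.poisson(mu * blen)
    net = np.zeros(n_nodes, dtype=np.int64)
    total = int(m.sum())
    if total:
        if model.kind == "SMM":
            ups = rng.binomial(m, 0.5)
            net = 2 * ups - m
        else:
            sizes = np.ones(total, dtype=np.int64)
            multi = rng.random(total) >= model.p_single
            if multi.any():
                sizes[multi] = rng.geometric(1.0 / model.geom_mean, int(multi.sum()))
            signs = np.where(rng.random(total) < 0.5, 1, -1)
            steps = sizes * signs
            idx = np.repeat(np.arange(n_nodes), m)
            net = np.bincount(idx, weights=steps, minlength=n_nodes).astype(np.int64)
    # propagate states root -> tips in decreasing node-time order
    order = np.argsort(node_time, kind="stable")[::-1].tolist()
    state = [0] * n_nodes
    par = parent.tolist()
    netl = net.tolist()
    for node in order:
        p = par[node]
        state[node] = ANCESTRAL_STATE + netl[node] if p < 0 else state[p] + netl[node]
    tips = np.asarray(state[:n_tips], dtype=np.int64)
    # keep labels positive (statistics are label-agnostic; the shift keeps
    # the repeat-count interpretation intact up to an offset)
    low = tips.min(initial=1)
    if low < 1:
        tips = tips + (1 - low)
    return tips


def simulate_dataset(scenario: DemographicScenario, params: dict,
                     sample_sizes=(95, 80, 94), n_loci: int = 11,
                     mut_model: MutationModel | None = None,
                     rng=None) -> GenotypeMatrix:
    """Simulate a diploid SSR dataset under a demographic scenario.

    sample_sizes are diploid individuals per population (in scenario pop
    order); loci are independent; diploid genotypes are formed by random
    pairing of gene copies within populations (no selfing here; mating-
    system effects belong to the synthetic-data post-processing).
    """
    model = mut_model or MutationModel()
    rng = np.random.default_rng(rng)
    sample_copies = [2 * int(s) for s in sample_sizes]
    n_ind = int(sum(sample_sizes))
    if model.rate_range is not None:
        mus = rng.uniform(model.rate_range[0], model.rate_range[1], n_loci)
    else:
        mus = np.full(n_loci, model.rate)
    alleles = np.empty((n_ind, n_loci, 2), dtype=np.int64)
    for j in range(n_loci):
        parent, node_time = simulate_locus_tree(scenario, params, sample_copies, rng)
        tips = mutate_tree(parent, node_time, mus[j], model, rng,
                           int(sum(sample_copies)))
        # pair copies within each population
        offset_c = 0
        offset_i = 0
        for p, s in enumerate(sample_sizes):
            block = tips[offset_c:offset_c + 2 * s]
            block = block[rng.permutation(2 * s)]
            alleles[offset_i:offset_i + s, j, :] = block.reshape(s, 2)
            offset_c += 2 * s
            offset_i += s
    pops = np.concatenate([[scenario.pop_names[p]] * s
                           for p, s in enumerate(sample_sizes)])
    individuals = [f"{pops[i]}_{i:04d}" for i in range(n_ind)]
    return GenotypeMatrix(individuals=individuals, loci=[f"L{j + 1:02d}" for j in range(n_loci)],
                          alleles=alleles, pop=np.asarray(pops, dtype=object))


def single_population_scenario(size_param: str = "N1") -> DemographicScenario:
    """Degenerate one-population scenario (equilibrium coalescent)."""
    return DemographicScenario(id="single", events=(), n_pops=1,
                               size_params=(size_param,), pop_names=("POP",))


def serialize_scenarios(space, path):
    """Write the scenario space as a human-readable event list."""
    with open(path, "w") as fh:
        for s in space:
            fh.write(f"{s.id}\t{s.describe()}\n")
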