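"""Structured serial coalescent simulation of multi-deme microsatellite data.

The simulator draws gene genealogies backward in time for samples spread
over a set of demes whose sizes follow piecewise-exponential trajectories
anchored at three epochs (present, 500 and 1,750 generations ago, i.e. the
mid-Holocene and the Last Glacial Maximum under a 12-year generation time).
Lineages coalesce within demes at rate ``1/(2N(t))`` per pair and migrate
under one of two rules:

* ``sink`` — every lineage outside deme 1 moves to deme 1 with probability
  0.01 per generation (all current demes descend from deme 1);
* ``island`` — every lineage moves to a uniformly chosen other deme with
  total probability 0.01 per generation (finite island model).

Six named demographic hypotheses parameterise the deme-size anchors
(N0, N500, N1750); see :data:`SCENARIOS`.  Mutations follow the strict
stepwise model (SMM): Poisson numbers of +-1 repeat changes per branch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .genotypes import GenotypeDataset

# --------------------------------------------------------------------------- #
# scenarios

#: Generations-before-present anchor times shared by all scenarios.
ANCHOR_TIMES = (0.0, 500.0, 1750.0)

#: Default deep horizon at which any still-separate lineages are pooled into
#: deme 1 so that the process is guaranteed to reach a single root.
DEFAULT_CAP_TIME = 50_000.0

# Size of each deme when the trajectory passes through N0=10,000 declining
# to N1750=1,000 under a single exponential over the whole 1,750 generations
# (the per-epoch anchor at 500 generations lies on that curve).
_N500_ON_21_0_DECLINE = 10_000.0 * (1_000.0 / 10_000.0) ** (500.0 / 1750.0)


@dataclass(frozen=True)
class DemographicScenario:
    """Per-deme size trajectory plus backward migration rule.

    ``anchors`` are diploid deme sizes at ``ANCHOR_TIMES``; between anchors
    the size follows an exponential curve (or stays at the older anchor when
    ``interpolation="instantaneous"``), and stays at ``N1750`` beyond the
    last anchor.  ``fusion_time`` (generations) relocates every surviving
    lineage into deme 1; every scenario also fuses at ``cap_time``.
    """

    name: str
    n_demes: int = 20
    anchors: tuple[float, float, float] = (10_000.0, 10_000.0, 10_000.0)
    anchor_times: tuple[float, float, float] = ANCHOR_TIMES
    migration_model: str = "sink"  # "sink" | "island" | "none"
    migration_rate: float = 0.01
    fusion_time: float | None = None
    cap_time: float = DEFAULT_CAP_TIME
    interpolation: str = "exponential"  # or "instantaneous"

    def __post_init__(self) -> None:
        if any(a < 1 for a in self.anchors):
            raise ValueError("anchor sizes must be >= 1")
        if not (0.0 <= self.migration_rate <= 1.0):
            raise ValueError("migration rate must lie in [0, 1]")
        t0, t1, t2 = self.anchor_times
        if not (t0 == 0.0 and t0 < t1 < t2):
            raise ValueError("anchor times must satisfy 0 < t500 < t1750")
        if self.migration_model not in ("sink", "island", "none"):
            raise ValueError(f"unknown migration model: {self.migration_model!r}")
        if self.interpolation not in ("exponential", "instantaneous"):
            raise ValueError(f"unknown interpolation mode: {self.interpolation!r}")
        if self.n_demes < 1:
            raise ValueError("n_demes must be >= 1")


#: The six demographic hypotheses.  Sizes are diploid individuals per deme;
#: all sink/island migration rates are 0.01 per lineage per generation.
SCENARIOS: dict[str, dict] = {
    # constant size throughout
    "Stability_21_0": dict(anchors=(10_000.0, 10_000.0, 10_000.0)),
    # constant to the mid-Holocene, then (backward) growth to 50,000 at the
    # LGM: forward in time the range shrank from 21 to 6 ka.  Lineages are
    # pooled into deme 1 at the LGM anchor ("shrink until extinction").
    "Retraction_21_6": dict(anchors=(10_000.0, 10_000.0, 50_000.0), fusion_time=1750.0),
    # single exponential decline (backward) from 10,000 now to 1,000 at LGM
    "Expansion_21_0": dict(anchors=(10_000.0, _N500_ON_21_0_DECLINE, 1_000.0)),
    # constant to the mid-Holocene, then decline to 1,000 at the LGM
    "Expansion_21_6": dict(anchors=(10_000.0, 10_000.0, 1_000.0)),
    # bottleneck at the mid-Holocene: 10,000 -> 1,000 -> back to 10,000
    "Expansion_6_0": dict(anchors=(10_000.0, 1_000.0, 10_000.0)),
    # finite island model, decline to 1,000 at the LGM
    "MultipleRefugia_21_0": dict(
        anchors=(10_000.0, _N500_ON_21_0_DECLINE, 1_000.0), migration_model="island"
    ),
}

SCENARIO_NAMES = tuple(SCENARIOS)


def build_scenario(name: str, **overrides) -> DemographicScenario:
    """Construct one of the six named demographic hypotheses.

    ``overrides`` may replace any :class:`DemographicScenario` field, e.g.
    ``n_demes=5`` for scaled-down experiments.
    """
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")
    params = dict(SCENARIOS[name])
    params.update(overrides)
    return DemographicScenario(name=name, **params)


def deme_size_at(scenario: DemographicScenario, t: float) -> float:
    """Diploid size of one deme ``t`` generations before present."""
    if t < 0:
        raise ValueError("t must be >= 0")
    n, _ = _size_and_rate(scenario, float(t))
    return n


def _size_and_rate(scenario: DemographicScenario, t: float) -> tuple[float, float]:
    """Deme size N(t) and backward exponential rate r within the epoch of t.

    Within epoch ``[ta, tb]`` the size is ``N(ta)*(N(tb)/N(ta))**((t-ta)/(tb-ta))``,
    i.e. ``N(ta)*exp(r*(t-ta))`` with ``r = ln(N(tb)/N(ta))/(tb-ta)``;
    constant at ``N1750`` beyond the last anchor.
    """
    t0, t1, t2 = scenario.anchor_times
    n0, n1, n2 = scenario.anchors
    if t >= t2:
        return n2, 0.0
    if t < t1:
        ta, tb, na, nb = t0, t1, n0, n1
    else:
        ta, tb, na, nb = t1, t2, n1, n2
    if scenario.interpolation == "instantaneous":
        return na, 0.0
    r = math.log(nb / na) / (tb - ta)
    return na * math.exp(r * (t - ta)), r


# --------------------------------------------------------------------------- #
# configuration and genealogy containers


@dataclass(frozen=True)
class SimulationConfig:
    """Sampling design and mutation parameters for one simulation."""

    sample_sizes: tuple[int, ...]  # diploid individuals per deme
    n_loci: int = 11
    mutation_rate: float = 0.01  # per allele per generation
    seed: int = 0
    ancestral_allele_size: int = 100

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_sizes", tuple(int(s) for s in self.sample_sizes))
        if any(s < 1 for s in self.sample_sizes):
            raise ValueError("sample sizes must be >= 1")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if not (0.0 < self.mutation_rate < 1.0):
            raise ValueError("mutation_rate must lie in (0, 1)")
        if self.ancestral_allele_size < 1:
            raise ValueError("ancestral allele size must be >= 1")


@dataclass
class Genealogy:
    """Rooted binary coalescent tree for one locus.

    Nodes ``0..n_tips-1`` are sampled gene copies at time 0; internal nodes
    are appended in coalescence order, so a parent always has a larger index
    (and later time) than its children.  ``migrations`` records
    ``(time, node, source_deme, dest_deme)`` lineage moves (fusion events
    included), with demes numbered from 1.
    """

    n_tips: int
    parent: np.ndarray  # (2*n_tips - 1,), -1 at the root
    time: np.ndarray  # node times, generations before present
    tip_demes: np.ndarray  # deme (1-based) of each sampled copy
    node_demes: np.ndarray  # deme in which each node was created
    migrations: list[tuple[float, int, int, int]] = field(default_factory=list)

    @property
    def root(self) -> int:
        return 2 * self.n_tips - 2

    @property
    def tmrca(self) -> float:
        return float(self.time[self.root])

    @property
    def total_branch_length(self) -> float:
        lengths = self.time[self.parent[: self.root]] - self.time[: self.root]
        return float(lengths.sum())


class _Streams:
    """Buffered scalar draws from a numpy Generator (hot-loop helper)."""

    def __init__(self, rng: np.random.Generator, block: int = 4096):
        self._rng = rng
        self._block = block
        self._exp = rng.exponential(size=block)
        self._uni = rng.random(size=block)
        self._ie = 0
        self._iu = 0

    def exp(self) -> float:
        if self._ie == self._block:
            self._exp = self._rng.exponential(size=self._block)
            self._ie = 0
        v = self._exp[self._ie]
        self._ie += 1
        return v

    def unif(self) -> float:
        if self._iu == self._block:
            self._uni = self._rng.random(size=self._block)
            self._iu = 0
        v = self._uni[self._iu]
        self._iu += 1
        return v


def _coal_wait(c_tot: float, n_t: float, r: float, e: float) -> float:
    """Waiting time to the next coalescence under exponential deme size.

    The total pair rate at lag ``s`` is ``c_tot / (2 * n_t * exp(r*s))``;
    inverts the integrated hazard against the Exp(1) draw ``e``.  Returns
    ``inf`` when the hazard integral never reaches ``e`` (growing demes).
    """
    if c_tot == 0.0:
        return math.inf
    if r == 0.0:
        return 2.0 * n_t * e / c_tot
    x = 1.0 - 2.0 * n_t * r * e / c_tot
    if x <= 0.0:
        return math.inf
    return -math.log(x) / r


def simulate_genealogy(
    config: SimulationConfig,
    scenario: DemographicScenario,
    locus_index: int = 0,
    max_time: float = 1e9,
) -> Genealogy:
    """Draw one per-locus genealogy under the structured serial coalescent.

    Deterministic given ``(config.seed, locus_index)``.  Raises
    ``RuntimeError`` if lineages can never meet (e.g. no migration, no
    fusion) or the hard ``max_time`` cap is exceeded.
    """
    if len(config.sample_sizes) != scenario.n_demes:
        raise ValueError(
            f"config has {len(config.sample_sizes)} sample sizes but the "
            f"scenario has {scenario.n_demes} demes"
        )
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), int(locus_index)]))
    st = _Streams(rng)

    n_demes = scenario.n_demes
    n_tips = 2 * sum(config.sample_sizes)
    n_nodes = 2 * n_tips - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    time = np.zeros(n_nodes)
    tip_demes = np.repeat(np.arange(1, n_demes + 1), [2 * s for s in config.sample_sizes])
    node_demes = np.zeros(n_nodes, dtype=np.int64)
    node_demes[:n_tips] = tip_demes
    migrations: list[tuple[float, int, int, int]] = []

    # active lineage ids per deme (0-based demes internally)
    active: list[list[int]] = [[] for _ in range(n_demes)]
    off = 0
    for d, s in enumerate(config.sample_sizes):
        active[d] = list(range(off, off + 2 * s))
        off += 2 * s

    boundaries = sorted(
        {scenario.anchor_times[1], scenario.anchor_times[2], scenario.cap_time}
        | ({scenario.fusion_time} if scenario.fusion_time is not None else set())
    )
    fusion_times = {scenario.cap_time}
    if scenario.fusion_time is not None:
        fusion_times.add(scenario.fusion_time)

    mig_rate = scenario.migration_rate
    model = scenario.migration_model
    t = 0.0
    n_active = n_tips
    next_node = n_tips
    counts = [len(a) for a in active]

    def _fuse(at: float) -> None:
        for d in range(1, n_demes):
            for node in active[d]:
                migrations.append((at, node, d + 1, 1))
            active[0].extend(active[d])
            active[d] = []
            counts[0] += counts[d]
            counts[d] = 0

    while n_active > 1:
        if t > max_time:
            raise RuntimeError("coalescent did not complete before the hard time cap")
        c_tot = 0.0
        for k in counts:
            if k > 1:
                c_tot += k * (k - 1) * 0.5
        if model == "sink":
            n_mig = n_active - counts[0]
        elif model == "island" and n_demes > 1:
            n_mig = n_active
        else:
            n_mig = 0
        m_tot = mig_rate * n_mig

        boundary = math.inf
        for b in boundaries:
            if b > t:
                boundary = b
                break
        if c_tot == 0.0 and m_tot == 0.0 and boundary == math.inf:
            raise RuntimeError("lineages can never meet: no coalescence, migration or fusion possible")

        n_t, r = _size_and_rate(scenario, t)
        s_coal = _coal_wait(c_tot, n_t, r, st.exp())
        s_mig = st.exp() / m_tot if m_tot > 0.0 else math.inf
        s_next = min(s_coal, s_mig)

        if t + s_next > boundary:
            t = boundary
            if boundary in fusion_times:
                _fuse(t)
            continue
        t += s_next

        if s_coal <= s_mig:
            # choose deme proportional to its pair count
            u = st.unif() * c_tot
            acc = 0.0
            d = 0
            for d in range(n_demes):
                k = counts[d]
                if k > 1:
                    acc += k * (k - 1) * 0.5
                    if u <= acc:
                        break
            lst = active[d]
            k = counts[d]
            i = int(st.unif() * k)
            j = int(st.unif() * (k - 1))
            if j >= i:
                j += 1
            c1, c2 = lst[i], lst[j]
            # swap-remove both children, then append the new parent
            hi, lo = (i, j) if i > j else (j, i)
            lst[hi] = lst[-1]
            lst.pop()
            lst[lo] = lst[-1]
            lst.pop()
            parent[c1] = next_node
            parent[c2] = next_node
            time[next_node] = t
            node_demes[next_node] = d + 1
            lst.append(next_node)
            counts[d] -= 1
            next_node += 1
            n_active -= 1
        else:
            if model == "sink":
                # uniform among lineages outside deme 1
                u = st.unif() * n_mig
                acc = 0.0
                src = 1
                for src in range(1, n_demes):
                    acc += counts[src]
                    if u <= acc:
                        break
                dst = 0
            else:  # island
                u = st.unif() * n_active
                acc = 0.0
                src = 0
                for src in range(n_demes):
                    acc += counts[src]
                    if u <= acc:
                        break
                dst = int(st.unif() * (n_demes - 1))
                if dst >= src:
                    dst += 1
            lst = active[src]
            i = int(st.unif() * counts[src])
            node = lst[i]
            lst[i] = lst[-1]
            lst.pop()
            active[dst].append(node)
            counts[src] -= 1
            counts[dst] += 1
            migrations.append((t, node, src + 1, dst + 1))

    return Genealogy(
        n_tips=n_tips,
        parent=parent,
        time=time,
        tip_demes=tip_demes,
        node_demes=node_demes,
        migrations=migrations,
    )


# --------------------------------------------------------------------------- #
# stepwise mutation model


def apply_smm_mutations(
    tree: Genealogy,
    mutation_rate: float,
    ancestral_allele_size: int = 100,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Tip allele sizes under the strict stepwise mutation model.

    Each branch receives a Poisson(rate * length) number of mutations, each
    of which changes the repeat count by +1 or -1 with equal probability.
    Sizes are floored at one repeat.
    """
    if ancestral_allele_size < 1:
        raise ValueError("ancestral allele size must be >= 1")
    if mutation_rate < 0:
        raise ValueError("mutation rate must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    root = tree.root
    lengths = tree.time[tree.parent[:root]] - tree.time[:root]
    counts = rng.poisson(mutation_rate * lengths)
    ups = rng.binomial(counts, 0.5)
    deltas = 2 * ups - counts
    values = np.empty(2 * tree.n_tips - 1, dtype=np.int64)
    values[root] = ancestral_allele_size
    for node in range(root - 1, -1, -1):
        values[node] = values[tree.parent[node]] + deltas[node]
    return np.maximum(values[: tree.n_tips], 1)


def simulate_dataset(config: SimulationConfig, scenario: DemographicScenario) -> GenotypeDataset:
    """Simulate a diploid microsatellite dataset under one scenario.

    Loci are independent: each gets its own genealogy and SMM mutations.
    The two consecutive gene copies sampled from a deme form one diploid
    individual.
    """
    n_loci = config.n_loci
    n_ind = sum(config.sample_sizes)
    alleles = np.empty((n_ind, n_loci, 2), dtype=np.int64)
    for locus in range(n_loci):
        tree = simulate_genealogy(config, scenario, locus_index=locus)
        mut_rng = np.random.default_rng(
            np.random.SeedSequence([int(config.seed), int(locus), 1])
        )
        sizes = apply_smm_mutations(
            tree, config.mutation_rate, config.ancestral_allele_size, mut_rng
        )
        alleles[:, locus, 0] = sizes[0::2]
        alleles[:, locus, 1] = sizes[1::2]
    pops = np.repeat(np.arange(len(config.sample_sizes)), config.sample_sizes)
    return GenotypeDataset(alleles=alleles, pops=pops)


def smm_equilibrium_heterozygosity(theta: float) -> float:
    """Expected gene diversity at SMM mutation-drift equilibrium.

    ``He = 1 - 1/sqrt(1 + 2*theta)`` with ``theta = 4*N*mu``.
    """
    if theta < 0:
        raise ValueError("theta must be >= 0")
    return 1.0 - 1.0 / math.sqrt(1.0 + 2.0 * theta)
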