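"""Forward simulator for replicated evolve-and-resequence Pool-seq studies.

The generator emulates the study design it is meant to stress: a founding
population assembled from a modest number of isofemale lines (each line
contributing a handful of wild haplotypes), split into replicate cage
populations of which half are exposed to the selective agent; allele
trajectories follow a diploid Wright-Fisher model with multiplicative
fitness at designated driver loci and crossover recombination; at sampled
generations a pool of whole flies is drawn and "sequenced" by drawing a
read depth per site and binomial read counts with a per-read miscall rate.

The output is exactly what the downstream statistics consume - a sync-format
count table plus a sample design table - together with a truth table of the
underlying population allele frequencies for validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import PooledCountsTable, make_design

_BASES = np.array(["A", "T", "C", "G"])
# for each true base index, the three other base indices a miscall can hit
_OTHERS = np.array([[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]])


@dataclass(frozen=True)
class SimulationConfig:
    """Scenario parameters; defaults follow the study design being emulated.

    ``driver_loci`` is a sequence of ``(site_index, s, h)`` triples: fitnesses
    are 1, 1+hs, 1+s for 0/1/2 copies of the derived allele, multiplied
    across driver loci, and act only in selected replicates from generation
    ``selection_onset`` onward.  ``depth_dispersion`` is the negative-binomial
    shape k (variance = m + m^2/k); ``math.inf`` gives Poisson depth.
    """

    n_lines: int = 27
    haploids_per_line: int = 4
    arms: tuple[tuple[str, int], ...] = (("2L", 1_000_000),)
    n_loci: int = 1000
    recomb_rate: float = 1e-8
    free_recombination: bool = False
    ne: int = 1000
    n_replicates_per_treatment: int = 3
    sampled_generations: tuple[int, ...] = (4, 17)
    driver_loci: tuple[tuple[int, float, float], ...] = ()
    selection_onset: int = 1
    pool_individuals: int = 100
    depth_mean: float = 80.0
    depth_dispersion: float = 10.0
    error_rate: float = 0.001
    line_identity: float = 0.75
    founder_ld_scale: float = 2_000_000.0
    sfs: str = "one_over_f"
    founder_mode: str = "isofemale_lines"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_lines", "haploids_per_line", "n_loci", "ne",
                     "n_replicates_per_treatment", "pool_individuals"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.arms:
            raise ValueError("arms must list at least one (name, length)")
        if any(length <= 0 for _, length in self.arms):
            raise ValueError("arm lengths must be positive")
        if not 0.0 <= self.error_rate < 0.25:
            raise ValueError("error_rate must be in [0, 0.25)")
        if self.recomb_rate < 0:
            raise ValueError("recomb_rate must be non-negative")
        if self.depth_mean <= 0 or self.depth_dispersion <= 0:
            raise ValueError("depth_mean and depth_dispersion must be "
                             "positive")
        if not 0.0 <= self.line_identity <= 1.0:
            raise ValueError("line_identity must be in [0, 1]")
        if self.pool_individuals > self.ne:
            raise ValueError("pool_individuals cannot exceed ne")
        for idx, s, h in self.driver_loci:
            if not 0 <= idx < self.n_loci:
                raise ValueError(f"driver site index {idx} out of range "
                                 f"[0, {self.n_loci})")
            if s <= -1:
                raise ValueError("selection coefficient s must exceed -1")
        if min(self.sampled_generations, default=1) < 1:
            raise ValueError("sampled generations must be >= 1")
        if self.founder_mode not in ("isofemale_lines",
                                     "linkage_equilibrium"):
            raise ValueError("founder_mode must be 'isofemale_lines' or "
                             "'linkage_equilibrium'")
        if self.founder_ld_scale <= 0:
            raise ValueError("founder_ld_scale must be positive")

    @property
    def n_haplotypes(self) -> int:
        return self.n_lines * self.haploids_per_line


@dataclass
class FounderPool:
    """Founder haplotypes and site metadata.

    ``haplotypes`` is (n_lines x haploids_per_line, n_loci) of 0/1 allele
    states; every site is segregating among the founders.
    """

    haplotypes: np.ndarray
    arms: np.ndarray          # arm name per site
    positions: np.ndarray     # 1-based bp per site, increasing within an arm
    ref_idx: np.ndarray       # reference base index (0..3) per site
    alt_idx: np.ndarray       # derived base index per site
    n_lines: int
    haploids_per_line: int

    @property
    def founder_frequencies(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)

    def __post_init__(self) -> None:
        f = self.founder_frequencies
        if ((f <= 0) | (f >= 1)).any():
            raise ValueError("every founder site must be segregating")
        for arm in np.unique(self.arms):
            pos = self.positions[self.arms == arm]
            if not (np.diff(pos) > 0).all():
                raise ValueError(f"positions must strictly increase on {arm}")


@dataclass
class TruthTable:
    """True population allele frequencies at the sampled generations."""

    driver_sites: np.ndarray
    # (treatment, replicate, generation) -> (n_loci,) frequency array
    trajectory: dict[tuple[str, int, int], np.ndarray] = field(
        default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (treatment, rep, gen), freqs in sorted(self.trajectory.items()):
            rows.append(pd.DataFrame({
                "treatment": treatment, "replicate": rep, "generation": gen,
                "site": np.arange(len(freqs)), "freq": freqs,
            }))
        return pd.concat(rows, ignore_index=True)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _site_positions(config: SimulationConfig, rng: np.random.Generator):
    """Distribute loci across arms proportional to length, unique sorted."""
    lengths = np.array([length for _, length in config.arms], dtype=float)
    if config.n_loci > lengths.sum():
        raise ValueError("n_loci exceeds the number of distinct bp positions "
                         "available on the configured arms")
    raw = lengths / lengths.sum() * config.n_loci
    alloc = np.floor(raw).astype(int)
    rem = config.n_loci - alloc.sum()
    order = np.argsort(-(raw - alloc))
    alloc[order[:rem]] += 1
    alloc = np.minimum(alloc, lengths.astype(int))
    while alloc.sum() < config.n_loci:  # spill if an arm saturated
        room = lengths.astype(int) - alloc
        alloc[np.argmax(room)] += 1
    arms, positions = [], []
    for (name, length), k in zip(config.arms, alloc):
        if k == 0:
            continue
        pos = np.sort(rng.choice(length, size=k, replace=False)) + 1
        arms.append(np.full(k, name, dtype=object))
        positions.append(pos)
    return np.concatenate(arms), np.concatenate(positions)


def _ar1_latents(rng: np.random.Generator, n_rows: int,
                 positions: np.ndarray, arms: np.ndarray,
                 scale: float) -> np.ndarray:
    """Stationary AR(1) Gaussian field along sites, one row per carrier unit.

    Correlation between sites decays as exp(-distance/scale); arm boundaries
    reset to independence.
    """
    L = len(positions)
    X = np.empty((n_rows, L))
    X[:, 0] = rng.standard_normal(n_rows)
    if L > 1:
        d = np.diff(positions).astype(float)
        same = arms[1:] == arms[:-1]
        rho = np.where(same, np.exp(-d / scale), 0.0)
        noise = rng.standard_normal((n_rows, L - 1))
        for j in range(1, L):
            r = rho[j - 1]
            X[:, j] = r * X[:, j - 1] + math.sqrt(1.0 - r * r) * noise[:, j - 1]
    return X


def build_founders(config: SimulationConfig,
                   rng: np.random.Generator | None = None) -> FounderPool:
    """Draw founder haplotypes from a configurable site-frequency spectrum.

    Default SFS: density proportional to 1/f truncated to
    [1/n_haplotypes, 0.5].  With probability ``line_identity`` a site is
    line-structured (all haplotypes of a carrier line identical, so the
    founder frequency is a multiple of 1/n_lines); otherwise carrier
    haplotypes are drawn at the haplotype level, mimicking residual
    within-line heterozygosity of wild-caught isofemale lines.

    Carrier lines/haplotypes are chosen as the top-ranked rows of a latent
    Gaussian field that is AR(1) along the chromosome with correlation
    length ``founder_ld_scale``, so founder LD between sites decays with
    distance - the haplotype-block structure that makes hitchhiking during
    the experiment spatially local.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    H = config.n_haplotypes
    if H < 2:
        raise ValueError("need at least two founder haplotypes for "
                         "segregating sites")
    f_min = 1.0 / H
    if f_min >= 0.5:
        raise ValueError("founder pool too small for the requested SFS: "
                         "1/n_haplotypes must be below 0.5")
    arms, positions = _site_positions(config, rng)
    L = config.n_loci
    if config.sfs == "one_over_f":
        u = rng.random(L)
        freqs = f_min * (0.5 / f_min) ** u
    elif config.sfs == "uniform":
        freqs = rng.uniform(f_min, 0.5, size=L)
    else:
        raise ValueError(f"unknown sfs {config.sfs!r}")

    hap = np.zeros((H, L), dtype=np.int8)
    line_of_hap = np.repeat(np.arange(config.n_lines),
                            config.haploids_per_line)
    line_structured = rng.random(L) < config.line_identity
    x_line = _ar1_latents(rng, config.n_lines, positions, arms,
                          config.founder_ld_scale)
    y_hap = _ar1_latents(rng, H, positions, arms, config.founder_ld_scale)
    b = config.line_identity
    x_hap = (math.sqrt(b) * x_line[line_of_hap]
             + math.sqrt(1.0 - b) * y_hap)
    for j in range(L):
        if line_structured[j]:
            m = int(np.clip(round(freqs[j] * config.n_lines), 1,
                            config.n_lines - 1))
            lines = np.argpartition(-x_line[:, j], m - 1)[:m]
            hap[np.isin(line_of_hap, lines), j] = 1
        else:
            k = int(np.clip(round(freqs[j] * H), 1, H - 1))
            carriers = np.argpartition(-x_hap[:, j], k - 1)[:k]
            hap[carriers, j] = 1

    ref_idx = rng.integers(0, 4, size=L)
    alt_idx = (ref_idx + rng.integers(1, 4, size=L)) % 4
    return FounderPool(haplotypes=hap, arms=arms, positions=positions,
                       ref_idx=ref_idx, alt_idx=alt_idx,
                       n_lines=config.n_lines,
                       haploids_per_line=config.haploids_per_line)


def _gap_recomb_fractions(founders: FounderPool,
                          config: SimulationConfig) -> np.ndarray:
    """Per-locus strand-switch probabilities for gamete formation.

    Entry 0 is 0.5 (the starting strand is random); entry j is the
    recombination fraction between loci j-1 and j (Haldane map from a
    Poisson crossover process), 0.5 across arm boundaries or under free
    recombination.
    """
    L = len(founders.positions)
    c = np.empty(L)
    c[0] = 0.5
    if L > 1:
        if config.free_recombination:
            c[1:] = 0.5
        else:
            d = np.diff(founders.positions).astype(float)
            same_arm = founders.arms[1:] == founders.arms[:-1]
            cc = 0.5 * (1.0 - np.exp(-2.0 * config.recomb_rate * d))
            c[1:] = np.where(same_arm, cc, 0.5)
    return c


def _fitness(pop: np.ndarray, drivers) -> np.ndarray:
    w = np.ones(pop.shape[0])
    for idx, s, h in drivers:
        g = pop[:, 0, idx].astype(np.int64) + pop[:, 1, idx]
        w = w * np.where(g == 2, 1.0 + s, np.where(g == 1, 1.0 + h * s, 1.0))
    return w


@dataclass
class ReplicateTrajectory:
    """One replicate's recorded states at the sampled generations."""

    freqs: dict[int, np.ndarray]
    populations: dict[int, np.ndarray]


def evolve_population(founders: FounderPool, config: SimulationConfig,
                      selected: bool,
                      rng: np.random.Generator | None = None,
                      record_populations: bool = True) -> ReplicateTrajectory:
    """Diploid Wright-Fisher forward simulation of one replicate cage.

    Each generation, parents are drawn with probability proportional to
    multiplicative fitness across driver loci (drivers contribute only when
    ``selected`` and the generation is at or past ``selection_onset``);
    each offspring receives one recombinant gamete from each of two parents.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    ne, L = config.ne, config.n_loci
    c_gap = _gap_recomb_fractions(founders, config)
    if config.founder_mode == "linkage_equilibrium":
        # founders describe only the site-frequency spectrum: the replicate
        # is seeded in linkage equilibrium, every locus independent (no
        # founder-haplotype LD shared between replicates)
        f = founders.founder_frequencies
        pop = (rng.random((ne, 2, L)) < f).astype(np.int8)
    else:
        H = founders.haplotypes.shape[0]
        pop = founders.haplotypes[rng.integers(0, H, size=(ne, 2))]
    sampled = set(config.sampled_generations)
    last = max(sampled)
    freqs: dict[int, np.ndarray] = {}
    pops: dict[int, np.ndarray] = {}
    for gen in range(1, last + 1):
        under_selection = (selected and config.driver_loci
                           and gen >= config.selection_onset)
        if under_selection:
            w = _fitness(pop, config.driver_loci)
            total = w.sum()
            if total <= 0:
                raise RuntimeError("population extinct: all fitnesses zero")
            parents = rng.choice(ne, size=(ne, 2), p=w / total)
        else:
            parents = rng.integers(0, ne, size=(ne, 2))
        switches = rng.random((ne, 2, L)) < c_gap
        strand = np.logical_xor.accumulate(switches, axis=2)
        par = pop[parents]                      # (ne, 2, 2, L)
        pop = np.where(strand, par[:, :, 1, :], par[:, :, 0, :])
        if gen in sampled:
            freqs[gen] = pop.mean(axis=(0, 1))
            if record_populations:
                pops[gen] = pop.copy()
    return ReplicateTrajectory(freqs=freqs, populations=pops)


def _multinomial3(n: np.ndarray, rng: np.random.Generator):
    """Split counts n uniformly over three categories, vectorized."""
    n1 = rng.binomial(n, 1.0 / 3.0)
    n2 = rng.binomial(n - n1, 0.5)
    return n1, n2, n - n1 - n2


def sequence_pool(pop: np.ndarray, founders: FounderPool,
                  config: SimulationConfig,
                  rng: np.random.Generator | None = None) -> np.ndarray:
    """Pool-seq one population state into a (n_loci, 6) count matrix.

    ``pool_individuals`` diploids are sampled without replacement and both
    chromosomes of each enter the pool.  Depth per site is negative-binomial
    with mean ``depth_mean`` and shape ``depth_dispersion`` (Poisson when the
    shape is infinite); reads are binomial in the pool allele fraction, and
    each read is miscalled to a uniformly random other nucleotide with
    probability ``error_rate``.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    ne = pop.shape[0]
    if config.pool_individuals > ne:
        raise ValueError("pool_individuals cannot exceed population size")
    take = rng.choice(ne, size=config.pool_individuals, replace=False)
    f = pop[take].mean(axis=(0, 1))             # pool alt fraction per site
    L = len(f)
    m = config.depth_mean
    if math.isinf(config.depth_dispersion):
        depth = rng.poisson(m, size=L)
    else:
        k = config.depth_dispersion
        depth = rng.negative_binomial(k, k / (k + m), size=L)
    alt_true = rng.binomial(depth, f)
    ref_true = depth - alt_true
    e = config.error_rate
    counts = np.zeros((L, 6), dtype=np.int64)
    sites = np.arange(L)
    for true_idx, n_true in ((founders.alt_idx, alt_true),
                             (founders.ref_idx, ref_true)):
        miscalled = rng.binomial(n_true, e) if e > 0 else np.zeros(L, int)
        np.add.at(counts, (sites, true_idx), n_true - miscalled)
        parts = _multinomial3(miscalled, rng)
        others = _OTHERS[true_idx]              # (L, 3)
        for slot in range(3):
            np.add.at(counts, (sites, others[:, slot]), parts[slot])
    return counts


def generate_experiment(config: SimulationConfig):
    """Simulate the full replicated experiment.

    Returns ``(PooledCountsTable, design DataFrame, TruthTable, FounderPool)``
    covering 2 treatments x n_replicates x len(sampled_generations) samples.
    """
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(1 + 2 * config.n_replicates_per_treatment)
    rng_founders = np.random.default_rng(streams[0])
    founders = build_founders(config, rng_founders)

    driver_sites = np.array(sorted({idx for idx, _, _ in config.driver_loci}),
                            dtype=int)
    truth = TruthTable(driver_sites=driver_sites)
    sample_ids, treatments, replicates, generations = [], [], [], []
    count_blocks = []
    stream = iter(streams[1:])
    for treatment, selected in (("selected", True), ("control", False)):
        for rep in range(1, config.n_replicates_per_treatment + 1):
            rng = np.random.default_rng(next(stream))
            traj = evolve_population(founders, config, selected, rng)
            for gen in config.sampled_generations:
                truth.trajectory[(treatment, rep, gen)] = traj.freqs[gen]
                counts = sequence_pool(traj.populations[gen], founders,
                                       config, rng)
                count_blocks.append(counts)
                prefix = "S" if selected else "C"
                sample_ids.append(f"{prefix}{rep}_g{gen}")
                treatments.append(treatment)
                replicates.append(rep)
                generations.append(gen)

    sites = pd.DataFrame({
        "arm": founders.arms, "pos": founders.positions,
        "ref": _BASES[founders.ref_idx],
    })
    table = PooledCountsTable(sites=sites, counts=np.stack(count_blocks),
                              samples=sample_ids)
    design = make_design(sample_ids, treatments, replicates, generations,
                         pool_chromosomes=2 * config.pool_individuals)
    return table, design, truth, founders


def selection_recursion(p0: float, s: float, h: float,
                        generations: int) -> float:
    """Deterministic one-locus viability-selection recursion.

    With genotype fitnesses 1, 1+hs, 1+s and mean fitness
    wbar = 1 + s(2hp(1-p) + p^2),

        p' = p + s p (1-p) (p + h(1 - 2p)) / wbar,

    iterated for the requested number of generations; the
    infinite-population expectation for driver trajectories.
    """
    p = p0
    for _ in range(generations):
        wbar = 1.0 + s * (2.0 * h * p * (1.0 - p) + p * p)
        p = p + s * p * (1.0 - p) * (p + h * (1.0 - 2.0 * p)) / wbar
    return p
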