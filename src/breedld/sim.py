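"""Forward Wright-Fisher simulator for multi-population SNP-chip data.

Discrete non-overlapping generations of diploid random mating with
recombination, population splits and single-generation admixture pulses.
The simulator produces phased haplotypes (the ground truth for LD oracles)
and, via :func:`to_genotypes`, unphased dose matrices with SNP-chip-like
missingness.

Model
-----
* Founder haplotypes are drawn site-wise independent with allele
  frequencies ~ Uniform(0.1, 0.9); equilibrium LD is built by running a
  burn-in (>= 4*Ne generations recommended) as part of the configured
  epoch spans.  There is no mutation after initialization.
* The genetic map is uniform (``cm_per_mb`` per chromosome) and
  crossovers are Poisson with no interference.  Transmission is exact at
  marker loci: the parental-haplotype indicator along a gamete is a
  two-state Markov chain whose switch probability between adjacent
  markers d Morgans apart is the Haldane probability of an odd crossover
  count, (1 - exp(-2d))/2; chromosome boundaries switch with probability
  1/2 (independent assortment).
* A split copies the parent population's haplotypes at the stated
  generation; the child then drifts independently.  An admixture pulse
  replaces a fraction of one generation's parents with migrants drawn
  from the source population.

Everything is driven by one :class:`numpy.random.Generator` seeded from
``SimConfig.seed``; identical config + seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix, MarkerMap, SampleTable

__all__ = [
    "SimConfig", "PhasedPopulation", "simulate", "to_genotypes",
    "true_haplotype_r2", "meiosis", "write_populations",
    "SimConfigError", "MonomorphicError",
]


class SimConfigError(ValueError):
    """Inconsistent simulation configuration (event ordering, sizes...)."""


class MonomorphicError(ValueError):
    """LD is undefined for a monomorphic marker."""


@dataclass
class SimConfig:
    """Configuration of a forward simulation.

    Parameters
    ----------
    n_chromosomes, chrom_length_mb, n_markers_per_chrom
        Genome layout; markers are placed on a jittered grid so the mean
        adjacent spacing is ``chrom_length_mb / n_markers_per_chrom``.
    ne_trajectory
        List of ``(generation_span, Ne)`` epochs, most ancient first; the
        total span sets the simulated history length (include the burn-in
        in the first epoch).  Applies to every population unless
        overridden in ``pop_ne``.
    split_events
        ``(generations_ago, parent, child)`` tuples.  A child is copied
        from its parent at the stated generation.
    admixture_events
        ``(generations_ago, target, source, proportion)``: the offspring
        generation born that many generations ago draws each parent from
        ``source`` with the given probability.
    sample_sizes
        Diploid individuals sampled per population at generation 0.
    missing_rate, cm_per_mb, seed
        Genotype missingness, genetic-map scale, RNG seed.
    pop_ne
        Optional per-population Ne trajectory overrides (same format,
        most ancient first; used from the population's creation onward).
    """

    n_chromosomes: int
    chrom_length_mb: float
    n_markers_per_chrom: int
    ne_trajectory: list[tuple[int, int]]
    sample_sizes: dict[str, int]
    split_events: list[tuple[int, str, str]] = field(default_factory=list)
    admixture_events: list[tuple[int, str, str, float]] = field(default_factory=list)
    missing_rate: float = 0.0
    cm_per_mb: float = 1.0
    seed: int = 0
    pop_ne: dict[str, list[tuple[int, int]]] | None = None

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.n_markers_per_chrom < 1:
            raise SimConfigError("need at least one chromosome and one marker")
        if not self.ne_trajectory:
            raise SimConfigError("empty ne_trajectory")
        for span, ne in self.ne_trajectory:
            if span < 1 or ne < 2:
                raise SimConfigError("every epoch needs span >= 1 and Ne >= 2")
        if not (0.0 <= self.missing_rate < 1.0):
            raise SimConfigError("missing_rate must be in [0, 1)")
        for g, tgt, src, prop in self.admixture_events:
            if not (0.0 <= prop <= 1.0):
                raise SimConfigError(f"admixture proportion {prop} outside [0, 1]")
        self._check_pedigree()

    # -- population pedigree -------------------------------------------------
    def _check_pedigree(self) -> None:
        children = [c for _, _, c in self.split_events]
        if len(set(children)) != len(children):
            raise SimConfigError("a population is created by two splits")
        pops = set(self.sample_sizes) | set(children) | {p for _, p, _ in self.split_events}
        roots = pops - set(children)
        if len(roots) != 1:
            raise SimConfigError(f"need exactly one root population, found {sorted(roots)}")
        self.root = roots.pop()
        birth = {self.root: self.total_generations}
        # resolve split times iteratively; a child must split while its parent exists
        pending = list(self.split_events)
        while pending:
            progress = False
            for ev in list(pending):
                g, parent, child = ev
                if parent in birth:
                    if g >= birth[parent]:
                        raise SimConfigError(
                            f"{child!r} splits from {parent!r} at {g} before the parent exists")
                    birth[child] = g
                    pending.remove(ev)
                    progress = True
            if not progress:
                raise SimConfigError(f"unresolvable split ordering: {pending}")
        for g, tgt, src, _ in self.admixture_events:
            for p in (tgt, src):
                if p not in birth:
                    raise SimConfigError(f"admixture references unknown population {p!r}")
                if g >= birth[p]:
                    raise SimConfigError(
                        f"admixture at {g} generations ago predates population {p!r}")
        self.birth_times = birth

    @property
    def total_generations(self) -> int:
        return sum(span for span, _ in self.ne_trajectory)

    def ne_at(self, pop: str, generations_ago: int) -> int:
        """Diploid Ne of ``pop`` at a given age (generations before present)."""
        traj = self.ne_trajectory
        if self.pop_ne and pop in self.pop_ne:
            traj = self.pop_ne[pop]
        age = 0
        for span, n in reversed(traj):  # most recent first
            if generations_ago < age + span:
                return n
            age += span
        return traj[0][1]  # beyond the trajectory: most ancient epoch


@dataclass
class PhasedPopulation:
    """Phased haplotypes of one sampled population.

    ``haplotypes`` is a (2*n_individuals, n_markers) 0/1 matrix; rows
    2i, 2i+1 are individual i's maternal/paternal haplotypes.
    """

    haplotypes: np.ndarray
    markers: MarkerMap
    label: str
    generation: int = 0

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[0] % 2:
            raise ValueError("haplotypes must be 2-D with an even row count")
        if self.haplotypes.shape[1] != len(self.markers):
            raise ValueError("haplotype columns != markers")

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0] // 2

    def allele_frequencies(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)


# ---------------------------------------------------------------------------
# core machinery
# ---------------------------------------------------------------------------

def _marker_map(config: SimConfig, rng: np.random.Generator) -> MarkerMap:
    """Jittered-grid marker positions, strictly increasing per chromosome."""
    chroms, poss, names = [], [], []
    length_bp = config.chrom_length_mb * 1e6
    m = config.n_markers_per_chrom
    spacing = length_bp / m
    for c in range(1, config.n_chromosomes + 1):
        jitter = rng.uniform(0.05, 0.95, size=m)
        pos = np.floor((np.arange(m) + jitter) * spacing).astype(np.int64) + 1
        chroms += [str(c)] * m
        poss.append(pos)
        names += [f"snp{c}_{k + 1}" for k in range(m)]
    return MarkerMap(np.array(chroms), np.concatenate(poss), np.array(names))


def _switch_probabilities(markers: MarkerMap, cm_per_mb: float) -> np.ndarray:
    """Haldane switch probability per adjacent-marker interval.

    Length n_markers - 1; intervals spanning a chromosome boundary get
    probability 1/2 (independent assortment).
    """
    d_morgan = np.diff(markers.pos) / 1e6 * cm_per_mb / 100.0
    p = 0.5 * (1.0 - np.exp(-2.0 * d_morgan))
    boundary = markers.chrom[1:] != markers.chrom[:-1]
    p[boundary] = 0.5
    return p


def meiosis(haplotypes: np.ndarray, n_gametes: int, switch_p: np.ndarray,
            rng: np.random.Generator,
            parent_index: np.ndarray | None = None) -> np.ndarray:
    """Draw ``n_gametes`` recombinant gametes from a diploid parent pool.

    Each gamete picks a uniform parent (or uses ``parent_index``), starts
    on a random parental haplotype and switches haplotype between
    adjacent markers with probability ``switch_p`` (Markov transmission,
    exact for Poisson crossovers at marker loci).
    """
    n_parents = haplotypes.shape[0] // 2
    n_markers = haplotypes.shape[1]
    if parent_index is None:
        parent_index = rng.integers(0, n_parents, size=n_gametes)
    flips = np.empty((n_gametes, n_markers), dtype=np.uint8)
    flips[:, 0] = rng.integers(0, 2, size=n_gametes, dtype=np.uint8)
    flips[:, 1:] = rng.random((n_gametes, n_markers - 1)) < switch_p
    phase = np.bitwise_xor.accumulate(flips, axis=1)
    h0 = haplotypes[2 * parent_index]
    h1 = haplotypes[2 * parent_index + 1]
    return np.where(phase == 0, h0, h1)


def simulate(config: SimConfig) -> dict[str, PhasedPopulation]:
    """Run the forward simulation; returns sampled populations by label.

    Time runs from ``config.total_generations`` generations ago down to
    the present (generation 0).  Sampling at generation 0 takes
    individuals without replacement when the request fits within the
    population, otherwise it draws offspring gametes from the final
    parental pool (one extra meiosis).
    """
    rng = np.random.default_rng(config.seed)
    markers = _marker_map(config, rng)
    switch_p = _switch_probabilities(markers, config.cm_per_mb)
    n_markers = len(markers)

    founder_freqs = rng.uniform(0.1, 0.9, size=n_markers)
    ne0 = config.ne_at(config.root, config.total_generations - 1)
    pops: dict[str, np.ndarray] = {
        config.root: (rng.random((2 * ne0, n_markers)) < founder_freqs).astype(np.uint8)
    }

    splits_at: dict[int, list[tuple[str, str]]] = {}
    for g, parent, child in config.split_events:
        splits_at.setdefault(g, []).append((parent, child))
    admix_at: dict[tuple[int, str], tuple[str, float]] = {
        (g, tgt): (src, prop) for g, tgt, src, prop in config.admixture_events}

    for t in range(config.total_generations, 0, -1):
        age = t - 1  # age of the offspring generation produced this step
        snapshot = pops
        new_pops: dict[str, np.ndarray] = {}
        for label in snapshot:
            n_off = 2 * config.ne_at(label, age)
            event = admix_at.get((age, label))
            if event is None:
                new_pops[label] = meiosis(snapshot[label], n_off, switch_p, rng)
            else:
                src, prop = event
                migrant = rng.random(n_off) < prop
                gametes = meiosis(snapshot[label], n_off, switch_p, rng)
                if migrant.any():
                    gametes[migrant] = meiosis(snapshot[src], int(migrant.sum()),
                                               switch_p, rng)
                new_pops[label] = gametes
        for parent, child in splits_at.get(age, ()):
            new_pops[child] = new_pops[parent].copy()
        pops = new_pops

    out: dict[str, PhasedPopulation] = {}
    for label in config.sample_sizes:
        n = config.sample_sizes[label]
        pool = pops[label]
        n_avail = pool.shape[0] // 2
        if n <= n_avail:
            chosen = rng.choice(n_avail, size=n, replace=False)
            rows = np.empty(2 * n, dtype=np.int64)
            rows[0::2] = 2 * chosen
            rows[1::2] = 2 * chosen + 1
            haps = pool[rows].copy()
        else:
            haps = meiosis(pool, 2 * n, switch_p, rng)
        out[label] = PhasedPopulation(haps, markers, label, generation=0)
    return out


def to_genotypes(pop: PhasedPopulation, missing_rate: float = 0.0,
                 seed: int | None = None) -> GenotypeMatrix:
    """Collapse phased haplotypes to unphased doses with missing noise.

    Dose = sum of the two haplotype alleles (counting the '1' allele,
    written allele "A"; the '0' allele is "B").  Missing entries are
    placed independently with probability ``missing_rate``.
    """
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError("missing_rate must be in [0, 1)")
    doses = (pop.haplotypes[0::2].astype(np.int8) + pop.haplotypes[1::2])
    if missing_rate > 0.0:
        rng = np.random.default_rng(seed)
        doses = doses.copy()
        doses[rng.random(doses.shape) < missing_rate] = MISSING
    n, m = doses.shape
    samples = SampleTable(
        np.array([f"{pop.label}_{i + 1}" for i in range(n)]),
        np.array([pop.label] * n))
    return GenotypeMatrix(doses, samples,
                          np.array(["A"] * m), np.array(["B"] * m))


def true_haplotype_r2(pop: PhasedPopulation, marker_i: int, marker_j: int) -> float:
    """Exact haplotype-frequency r² between two markers.

    r² = D² / (f(A) f(a) f(B) f(b)) with D = f(AB) - f(A) f(B), all
    frequencies counted directly from the known haplotypes.  This is the
    oracle against which the composite genotype estimator is validated.
    """
    hi = pop.haplotypes[:, marker_i].astype(np.float64)
    hj = pop.haplotypes[:, marker_j].astype(np.float64)
    fa, fb = hi.mean(), hj.mean()
    if fa in (0.0, 1.0) or fb in (0.0, 1.0):
        raise MonomorphicError(
            f"marker {marker_i if fa in (0.0, 1.0) else marker_j} is monomorphic")
    fab = (hi * hj).mean()
    d = fab - fa * fb
    return d * d / (fa * (1 - fa) * fb * (1 - fb))


def write_populations(pops: dict[str, PhasedPopulation], out_dir: str,
                      missing_rate: float = 0.0, seed: int = 0,
                      dialect: str = "bed") -> None:
    """Write each simulated population as a PLINK fileset plus metadata.

    One fileset per population (``<out_dir>/<label>.{bed,bim,fam}`` or
    ``.{ped,map}``) and a ``simulation.json`` recording the seed and
    missingness so the genotype realisation is reproducible.
    """
    import json
    import os

    from .genotype_io import write_plink

    os.makedirs(out_dir, exist_ok=True)
    meta = {"seed": seed, "missing_rate": missing_rate, "dialect": dialect,
            "populations": {}}
    for k, (label, pop) in enumerate(pops.items()):
        geno = to_genotypes(pop, missing_rate, seed=seed + k)
        write_plink(geno, pop.markers, geno.samples,
                    os.path.join(out_dir, label), dialect=dialect)
        meta["populations"][label] = {"n_individuals": pop.n_individuals,
                                      "n_markers": len(pop.markers),
                                      "genotype_seed": seed + k}
    with open(os.path.join(out_dir, "simulation.json"), "w") as fh:
        json.dump(meta, fh, indent=2)
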