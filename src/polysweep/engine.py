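"""Forward Wright-Fisher engine for diploid populations with linked loci.

Two selection regimes are supported on the same machinery:

* **sweep** — per-locus multiplicative fitness with codominance
  (genotype fitness 1, 1 + s/2, 1 + s), loci independent for fitness;
* **trait optimum** — additive trait ``z = sum a_i (dosage_i - 1)`` mapped to
  fitness through a Gaussian function of the (noisy) phenotype, so loci
  interact epistatically for fitness.

Recombination follows the Haldane model (Poisson crossovers, no
interference).  Because crossover counts in disjoint genetic intervals are
independent Poisson variates, the strand pattern at the tracked loci is
generated exactly by independent Bernoulli "switch" events between adjacent
loci with probability ``r = (1 - exp(-2 d)) / 2`` for inter-locus distance
``d`` Morgans (``r = 1/2`` across linkage-group boundaries), which is what
the vectorised gamete sampler implements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

from .founders import (
    CM_PER_MORGAN,
    HaplotypePool,
    Population,
    RecombinationMap,
    expand_to_population,
    generate_founder_haplotypes,
)

if TYPE_CHECKING:  # pragma: no cover
    from .scenarios import ScenarioSpec

__all__ = [
    "GaussianFitnessSpec",
    "SweepFitnessSpec",
    "TraitSpec",
    "ReplicateResult",
    "trait_value",
    "phenotype",
    "gaussian_fitness",
    "sweep_fitness",
    "environmental_variance_for_heritability",
    "adjusted_optimum",
    "recombine",
    "simulate_generation",
    "run_replicate",
    "simulate_binomial_drift",
    "replicate_rng",
    "inter_locus_switch_probs",
]


@dataclass(frozen=True)
class GaussianFitnessSpec:
    """Gaussian stabilising-selection map from phenotype to fitness.

    ``w(x) = (max_fit - min_fit) * exp(-(x - optimum)^2 / (2 sd^2)) + min_fit``
    i.e. the Gaussian density rescaled so its maximum is ``max_fit`` and its
    tails approach ``min_fit``.
    """

    optimum: float
    sd: float = 0.3
    min_fit: float = 0.5
    max_fit: float = 4.5

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be > 0")
        if not self.max_fit > self.min_fit > 0:
            raise ValueError("require max_fit > min_fit > 0")


@dataclass(frozen=True)
class SweepFitnessSpec:
    """Per-locus selection coefficients, codominant (h = 0.5), multiplicative."""

    selection_coefficients: np.ndarray
    dominance: float = 0.5

    def __post_init__(self) -> None:
        s = np.asarray(self.selection_coefficients, dtype=float)
        if (s < 0).any():
            raise ValueError("selection coefficients must be >= 0")
        object.__setattr__(self, "selection_coefficients", s)


@dataclass(frozen=True)
class TraitSpec:
    """Additive trait architecture: per-locus effects, no dominance deviation."""

    effect_sizes: np.ndarray
    heritability: float = 0.5

    def __post_init__(self) -> None:
        a = np.asarray(self.effect_sizes, dtype=float)
        if (a < 0).any():
            raise ValueError("effect sizes must be >= 0")
        if not 0.0 < self.heritability <= 1.0:
            raise ValueError("heritability must be in (0, 1]")
        object.__setattr__(self, "effect_sizes", a)


@dataclass
class ReplicateResult:
    """Time series of one replicate, recorded on a fixed generation grid."""

    generations: np.ndarray            # recorded generations, e.g. 0,10,...,140
    freq: np.ndarray                   # (T, L) "+"-allele frequencies
    pheno_median: np.ndarray           # (T,) median genotypic trait value (NaN in sweep/neutral)
    fitness_median: np.ndarray         # (T,) median individual fitness
    pheno_mean0: float                 # generation-0 mean genotypic trait value
    load_hist: np.ndarray              # (T, L+1) proportion of chromosomes with k "+" alleles
    final_population: Population | None = None

    def __post_init__(self) -> None:
        if self.freq.shape[0] != len(self.generations):
            raise ValueError("freq rows must match recorded generations")
        if ((self.freq < 0) | (self.freq > 1)).any():
            raise ValueError("frequencies must lie in [0, 1]")


def replicate_rng(root_seed: int, replicate: int) -> np.random.Generator:
    """Child generator for one replicate: seeded from ``(root_seed, replicate)``.

    Splitting rule: ``np.random.default_rng([root_seed, replicate])`` — the
    pair feeds a ``SeedSequence``, so replicate streams are independent,
    reproducible, and extensible without re-running earlier replicates.
    """
    return np.random.default_rng([root_seed, replicate])


# ---------------------------------------------------------------------------
# Fitness machinery


def trait_value(genotype_dosages: np.ndarray, trait: TraitSpec) -> np.ndarray | float:
    """Additive genotypic trait value: ``z = sum_i a_i * (dosage_i - 1)``.

    Per-locus genotypic values are +a / 0 / -a for the "+/+", "+/-", "-/-"
    genotypes, so the population mean under random mating is
    ``sum_i a_i (p_i - q_i)``.
    """
    dos = np.asarray(genotype_dosages)
    if dos.shape[-1] != len(trait.effect_sizes):
        raise ValueError("dosage vector length must match number of loci")
    return (dos - 1.0) @ trait.effect_sizes


def phenotype(z: np.ndarray | float, Ve: float,
              rng: np.random.Generator) -> np.ndarray | float:
    """Genotypic value plus Gaussian environmental noise with variance ``Ve``."""
    if Ve < 0:
        raise ValueError("Ve must be >= 0")
    if Ve == 0:
        return z
    return z + rng.normal(0.0, np.sqrt(Ve), size=np.shape(z))


def gaussian_fitness(x: np.ndarray | float,
                     spec: GaussianFitnessSpec) -> np.ndarray | float:
    return (spec.max_fit - spec.min_fit) * np.exp(
        -((np.asarray(x, dtype=float) - spec.optimum) ** 2) / (2.0 * spec.sd**2)
    ) + spec.min_fit


def sweep_fitness(genotype_dosages: np.ndarray,
                  spec: SweepFitnessSpec) -> np.ndarray | float:
    """Multiplicative fitness across loci: factor 1, 1+hs, 1+s per genotype."""
    dos = np.asarray(genotype_dosages)
    s = spec.selection_coefficients
    if dos.shape[-1] != len(s):
        raise ValueError("dosage vector length must match number of loci")
    log_het = np.log1p(spec.dominance * s)
    log_hom = np.log1p(s)
    logw = (dos == 1) @ log_het + (dos == 2) @ log_hom
    return np.exp(logw)


def environmental_variance_for_heritability(trait: TraitSpec,
                                            founder_freqs: np.ndarray) -> float:
    """``Ve = Vg0 (1 - h2) / h2`` with ``Vg0 = sum 2 p q a^2`` at generation 0.

    Calibrated once from the founder state and held fixed over the run.
    """
    p = np.asarray(founder_freqs, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("founder frequencies must be in [0, 1]")
    vg0 = float(np.sum(2.0 * p * (1.0 - p) * trait.effect_sizes**2))
    return vg0 * (1.0 - trait.heritability) / trait.heritability


def adjusted_optimum(trait: TraitSpec, founder_freqs: np.ndarray,
                     distance: float = 1.1) -> float:
    """Place the optimum a fixed distance above the founder mean trait value.

    This makes runs with different locus counts / effect sizes traverse the
    same phenotypic distance.  If the optimum exceeds the maximal attainable
    trait value (all loci fixed for "+"), a warning is issued and the value is
    returned anyway — that is the "optimum not reachable" regime.
    """
    if distance < 0:
        raise ValueError("distance must be >= 0")
    p = np.asarray(founder_freqs, dtype=float)
    mean0 = float(np.sum(trait.effect_sizes * (p - (1.0 - p))))
    optimum = mean0 + distance
    z_max = float(np.sum(trait.effect_sizes))
    if optimum > z_max:
        warnings.warn(
            f"trait optimum {optimum:.4g} exceeds the maximal trait value "
            f"{z_max:.4g}; the optimum cannot be reached",
            stacklevel=2,
        )
    return optimum


# ---------------------------------------------------------------------------
# Recombination and reproduction


def inter_locus_switch_probs(recombination_map: RecombinationMap,
                             loci) -> np.ndarray:
    """Per adjacent-locus strand-switch probabilities (length L-1).

    Within a linkage group the switch probability is Haldane's recombinant
    fraction for the inter-locus genetic distance; across group boundaries it
    is 1/2 (independent assortment).
    """
    groups = [l.linkage_group for l in loci]
    pos_cm = np.empty(len(loci))
    for g in recombination_map.groups:
        idx = [i for i, name in enumerate(groups) if name == g.name]
        if idx:
            pos_cm[idx] = g.genetic_position_cm(
                np.array([loci[i].position_bp for i in idx]))
    r = np.empty(max(len(loci) - 1, 0))
    for i in range(len(loci) - 1):
        if groups[i] != groups[i + 1]:
            r[i] = 0.5
        else:
            d_morgans = (pos_cm[i + 1] - pos_cm[i]) / CM_PER_MORGAN
            r[i] = 0.5 * (1.0 - np.exp(-2.0 * d_morgans))
    return r


def _gametes(haplotypes: np.ndarray, parent_idx: np.ndarray,
             switch_probs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One recombinant gamete per parent index, fully vectorised."""
    G = len(parent_idx)
    L = haplotypes.shape[1]
    start = rng.integers(0, 2, size=(G, 1), dtype=np.int64)
    if L > 1:
        switches = (rng.random((G, L - 1)) < switch_probs).astype(np.int64)
        strand = (start + np.cumsum(switches, axis=1, dtype=np.int64)) % 2
        strand = np.concatenate([start, strand], axis=1)
    else:
        strand = start
    pat = haplotypes[2 * parent_idx]
    mat = haplotypes[2 * parent_idx + 1]
    return np.where(strand == 0, pat, mat)


def recombine(parent: tuple[np.ndarray, np.ndarray],
              recombination_map: RecombinationMap, loci,
              rng: np.random.Generator) -> np.ndarray:
    """Single recombinant gamete from one parent's two chromosome rows."""
    pat, mat = (np.asarray(h, dtype=np.uint8) for h in parent)
    if pat.shape != mat.shape or pat.ndim != 1:
        raise ValueError("parent rows must be equal-length 1-D haplotypes")
    haps = np.stack([pat, mat])
    r = inter_locus_switch_probs(recombination_map, loci)
    return _gametes(haps, np.array([0]), r, rng)[0]


def _distinct_parent_pairs(N: int, probs: np.ndarray,
                           rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    support = np.flatnonzero(probs > 0)
    if len(support) == 1:
        # degenerate: a single individual carries all fitness mass, so no
        # distinct partner exists; it provides both gametes
        only = np.full(N, support[0])
        return only, only.copy()
    p1 = rng.choice(N, size=N, p=probs)
    p2 = rng.choice(N, size=N, p=probs)
    clash = np.flatnonzero(p1 == p2)
    while len(clash):
        p2[clash] = rng.choice(N, size=len(clash), p=probs)
        clash = clash[p1[clash] == p2[clash]]
    return p1, p2


def simulate_generation(pop: Population, fitness_values: np.ndarray,
                        recombination_map: RecombinationMap,
                        rng: np.random.Generator,
                        switch_probs: np.ndarray | None = None) -> Population:
    """One non-overlapping Wright-Fisher generation with fitness-proportional mating.

    Each of the N offspring draws two *distinct* parents with probability
    proportional to fitness (parents may be reused across offspring) and
    receives one recombinant gamete from each.
    """
    N = pop.n_diploids
    if N < 2:
        raise ValueError("need at least 2 diploids for distinct-parent mating")
    w = np.asarray(fitness_values, dtype=float)
    if w.shape != (N,):
        raise ValueError("fitness_values must have length N")
    if (w < 0).any():
        raise ValueError("fitness values must be >= 0")
    total = w.sum()
    if total <= 0:
        raise ValueError("all fitness values are zero")
    if switch_probs is None:
        switch_probs = inter_locus_switch_probs(recombination_map, pop.loci)
    p1, p2 = _distinct_parent_pairs(N, w / total, rng)
    child = np.empty_like(pop.haplotypes)
    child[0::2] = _gametes(pop.haplotypes, p1, switch_probs, rng)
    child[1::2] = _gametes(pop.haplotypes, p2, switch_probs, rng)
    return Population(child, pop.loci)


# ---------------------------------------------------------------------------
# Whole-replicate driver


def _load_histogram(haplotypes: np.ndarray, n_loci: int) -> np.ndarray:
    counts = np.bincount(haplotypes.sum(axis=1).astype(np.int64),
                         minlength=n_loci + 1)
    return counts / haplotypes.shape[0]


def run_replicate(scenario: "ScenarioSpec", seed: int | list[int],
                  pool: HaplotypePool | None = None,
                  keep_final_population: bool = True) -> ReplicateResult:
    """Run one replicate of a scenario; deterministic given (scenario, seed).

    The founder pool is shared across replicates when passed in (the scenario
    runner builds it once from the scenario seed); otherwise it is rebuilt
    here from ``scenario.root_seed`` so stand-alone calls still reuse
    identical founders across models sharing a seed.
    """
    if pool is None:
        pool = scenario.build_founders()
    rng = np.random.default_rng(seed)
    pop = expand_to_population(pool, scenario.N,
                               seed=int(rng.integers(2**31)))
    rmap = pool.recombination_map
    switch_probs = inter_locus_switch_probs(rmap, pool.loci)
    L = pool.n_loci

    model = scenario.model
    trait = sweep = gauss = None
    Ve = 0.0
    if model == "trait_optimum":
        trait = TraitSpec(
            np.full(L, scenario.effect_size), heritability=scenario.heritability)
        p0 = pool.allele_frequencies()
        Ve = environmental_variance_for_heritability(trait, p0)
        optimum = (scenario.optimum if scenario.optimum is not None
                   else adjusted_optimum(trait, p0, scenario.optimum_distance))
        gauss = GaussianFitnessSpec(optimum, scenario.fitness_sd,
                                    scenario.min_fit, scenario.max_fit)
    elif model == "sweep":
        sweep = SweepFitnessSpec(np.full(L, scenario.s))
    elif model != "neutral":
        raise ValueError(f"unknown model {model!r}")

    def fitness_and_trait(p: Population) -> tuple[np.ndarray, np.ndarray | None]:
        if model == "neutral":
            return np.ones(p.n_diploids), None
        dos = p.dosages()
        if model == "sweep":
            return sweep_fitness(dos, sweep), None
        z = trait_value(dos, trait)
        x = phenotype(z, Ve, rng)
        return gaussian_fitness(x, gauss), z

    record_gens = np.arange(0, scenario.generations + 1, scenario.record_interval)
    freq = np.empty((len(record_gens), L))
    pheno_median = np.full(len(record_gens), np.nan)
    fitness_median = np.empty(len(record_gens))
    load_hist = np.empty((len(record_gens), L + 1))

    pheno_mean0 = 0.0
    rec = 0
    for gen in range(scenario.generations + 1):
        w, z = fitness_and_trait(pop)
        if gen == 0 and z is not None:
            pheno_mean0 = float(np.mean(z))
        if rec < len(record_gens) and gen == record_gens[rec]:
            freq[rec] = pop.allele_frequencies()
            fitness_median[rec] = float(np.median(w))
            if z is not None:
                pheno_median[rec] = float(np.median(z))
            load_hist[rec] = _load_histogram(pop.haplotypes, L)
            rec += 1
        if gen < scenario.generations:
            pop = simulate_generation(pop, w, rmap, rng, switch_probs=switch_probs)

    return ReplicateResult(
        generations=record_gens,
        freq=freq,
        pheno_median=pheno_median,
        fitness_median=fitness_median,
        pheno_mean0=pheno_mean0,
        load_hist=load_hist,
        final_population=pop if keep_final_population else None,
    )


def simulate_binomial_drift(N: int, p0: float | np.ndarray, generations: int,
                            n_series: int, seed: int,
                            record_interval: int | None = None) -> np.ndarray:
    """Neutral single-locus Wright-Fisher drift via binomial sampling.

    Marginal allele-frequency dynamics at a neutral locus are exactly
    binomial(2N, p) per generation regardless of linkage, so this is the fast
    path for building neutral null distributions.  Returns the full recorded
    trajectory, shape (T, n_series), including generation 0.
    """
    rng = np.random.default_rng(seed)
    two_n = 2 * N
    p = np.broadcast_to(np.asarray(p0, dtype=float), (n_series,)).copy()
    if record_interval is None:
        record_interval = generations
    record_gens = np.arange(0, generations + 1, record_interval)
    out = np.empty((len(record_gens), n_series))
    rec = 0
    for gen in range(generations + 1):
        if gen == record_gens[rec]:
            out[rec] = p
            rec += 1
        if gen == generations:
            break
        p = rng.binomial(two_n, p) / two_n
    return out
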