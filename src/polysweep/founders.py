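"""Synthetic founder populations and recombination maps.

Emulates a typical evolve-and-resequence founder setup: a fixed number of
distinct phased haplotypes (default 189) carrying diallelic loci scattered
over two recombining linkage groups, each locus segregating a "+" (focal)
allele at a low starting frequency (default 0.05).  The founder pool is then
expanded to the experimental census size by cycling, so each haplotype is
present in multiple near-equal copies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Segment",
    "LinkageGroup",
    "RecombinationMap",
    "Locus",
    "HaplotypePool",
    "Population",
    "build_recombination_map",
    "generate_founder_haplotypes",
    "expand_to_population",
    "default_map",
    "write_map_tsv",
    "read_map_tsv",
    "write_pool_tsv",
    "read_pool_tsv",
    "read_pool_vcf",
]

CM_PER_MORGAN = 100.0


@dataclass(frozen=True)
class Segment:
    """Piecewise-constant recombination segment, half-open [start_bp, end_bp)."""

    start_bp: int
    end_bp: int
    rate_cm_per_mb: float

    def __post_init__(self) -> None:
        if self.end_bp <= self.start_bp:
            raise ValueError("segment must have positive length")
        if self.rate_cm_per_mb < 0:
            raise ValueError("recombination rate must be >= 0")

    @property
    def genetic_length_cm(self) -> float:
        return (self.end_bp - self.start_bp) / 1e6 * self.rate_cm_per_mb


@dataclass(frozen=True)
class LinkageGroup:
    name: str
    length_bp: int
    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError("linkage group length must be > 0")
        segs = sorted(self.segments, key=lambda s: s.start_bp)
        if segs[0].start_bp != 0 or segs[-1].end_bp != self.length_bp:
            raise ValueError("segments must tile [0, length_bp)")
        for a, b in zip(segs, segs[1:]):
            if a.end_bp != b.start_bp:
                raise ValueError("segments must tile without gaps or overlaps")
        if self.genetic_length_cm <= 0:
            raise ValueError("total genetic length per group must be > 0")
        object.__setattr__(self, "segments", tuple(segs))

    @property
    def genetic_length_cm(self) -> float:
        return sum(s.genetic_length_cm for s in self.segments)

    def genetic_position_cm(self, position_bp: int | np.ndarray) -> np.ndarray:
        """Map physical position(s) to cumulative genetic position in cM."""
        pos = np.atleast_1d(np.asarray(position_bp, dtype=float))
        out = np.zeros_like(pos)
        for seg in self.segments:
            covered_bp = np.clip(pos, seg.start_bp, seg.end_bp) - seg.start_bp
            out += covered_bp / 1e6 * seg.rate_cm_per_mb
        return out


@dataclass(frozen=True)
class RecombinationMap:
    """Linkage groups with piecewise-constant rates; free recombination between groups."""

    groups: tuple[LinkageGroup, ...]

    def __post_init__(self) -> None:
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise ValueError("linkage group names must be unique")
        object.__setattr__(self, "groups", tuple(self.groups))

    @property
    def total_genetic_length_cm(self) -> float:
        return sum(g.genetic_length_cm for g in self.groups)

    def group(self, name: str) -> LinkageGroup:
        for g in self.groups:
            if g.name == name:
                return g
        raise KeyError(name)


@dataclass(frozen=True)
class Locus:
    """One diallelic locus; allele 1 is the focal "+" allele."""

    id: int
    linkage_group: str
    position_bp: int
    role: Literal["selected", "neutral"] = "selected"
    effect_size: float = 0.0
    selection_coefficient: float = 0.0
    start_freq: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.start_freq <= 1.0:
            raise ValueError("start_freq must be in [0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")


@dataclass
class HaplotypePool:
    """Founder haplotype-by-locus 0/1 matrix plus locus metadata."""

    alleles: np.ndarray  # (n_haplotypes, L) uint8
    loci: list[Locus]
    recombination_map: RecombinationMap

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D matrix")
        if self.alleles.shape[1] != len(self.loci):
            raise ValueError("column count must match number of loci")
        if not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("allele matrix must be binary")
        for g_name in {l.linkage_group for l in self.loci}:
            pos = [l.position_bp for l in self.loci if l.linkage_group == g_name]
            if any(b <= a for a, b in zip(pos, pos[1:])):
                raise ValueError("positions must be strictly increasing within a group")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_loci(self) -> int:
        return self.alleles.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        return self.alleles.mean(axis=0)

    def with_effects(
        self,
        effect_size: float | None = None,
        selection_coefficient: float | None = None,
    ) -> "HaplotypePool":
        """Copy of the pool with per-locus effects replaced (same carriers/positions)."""
        loci = [
            replace(
                l,
                effect_size=effect_size if effect_size is not None else l.effect_size,
                selection_coefficient=(
                    selection_coefficient
                    if selection_coefficient is not None
                    else l.selection_coefficient
                ),
            )
            for l in self.loci
        ]
        return HaplotypePool(self.alleles.copy(), loci, self.recombination_map)


@dataclass
class Population:
    """2N phased chromosome rows; rows (2i, 2i+1) form diploid individual i."""

    haplotypes: np.ndarray  # (2N, L) uint8
    loci: list[Locus]

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.shape[0] % 2 != 0:
            raise ValueError("population must contain 2N chromosome rows")

    @property
    def n_diploids(self) -> int:
        return self.haplotypes.shape[0] // 2

    @property
    def n_loci(self) -> int:
        return self.haplotypes.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)

    def dosages(self) -> np.ndarray:
        """N x L genotype dosage matrix over {0, 1, 2}."""
        return (self.haplotypes[0::2].astype(np.int8)
                + self.haplotypes[1::2].astype(np.int8))


def build_recombination_map(
    group_specs: Sequence[tuple[str, int, float]],
    n_segments_per_group: int = 1,
    rate_jitter: float = 0.0,
    seed: int = 0,
) -> RecombinationMap:
    """Piecewise-constant map with exact per-group genetic lengths.

    Each group of physical length ``length_bp`` is split into
    ``n_segments_per_group`` equal segments.  With ``rate_jitter > 0`` segment
    rates are perturbed multiplicatively by Uniform(1-jitter, 1+jitter) and
    rescaled so the summed genetic length still equals ``genetic_length_cm``.
    """
    if not 0.0 <= rate_jitter < 1.0:
        raise ValueError("rate_jitter must be in [0, 1)")
    if n_segments_per_group < 1:
        raise ValueError("n_segments_per_group must be >= 1")
    rng = np.random.default_rng(seed)
    groups = []
    for name, length_bp, genetic_length_cm in group_specs:
        if length_bp <= 0 or genetic_length_cm <= 0:
            raise ValueError(f"group {name!r}: lengths must be > 0")
        bounds = np.linspace(0, length_bp, n_segments_per_group + 1).astype(np.int64)
        bounds[-1] = length_bp
        widths_mb = np.diff(bounds) / 1e6
        base_rate = genetic_length_cm / (length_bp / 1e6)
        rates = np.full(n_segments_per_group, base_rate)
        if rate_jitter > 0:
            rates = rates * rng.uniform(1 - rate_jitter, 1 + rate_jitter,
                                        size=n_segments_per_group)
        # rescale so the group genetic length matches the spec exactly
        rates *= genetic_length_cm / float(rates @ widths_mb)
        segments = tuple(
            Segment(int(bounds[i]), int(bounds[i + 1]), float(rates[i]))
            for i in range(n_segments_per_group)
        )
        groups.append(LinkageGroup(name, int(length_bp), segments))
    return RecombinationMap(tuple(groups))


def default_map(seed: int = 0) -> RecombinationMap:
    """Two-group default emulating a pair of large fly autosomes (~100 cM each)."""
    return build_recombination_map(
        [("2", 49_000_000, 100.0), ("3", 24_000_000, 100.0)], seed=seed
    )


def generate_founder_haplotypes(
    recombination_map: RecombinationMap,
    n_loci: int,
    target_freq: float = 0.05,
    n_haplotypes: int = 189,
    effect_spec: tuple[str, float] | None = None,
    seed: int = 0,
) -> HaplotypePool:
    """Place loci uniformly along the genome and assign "+" carriers.

    For each locus independently the number of carrier haplotypes ``k`` is
    ``target_freq * n_haplotypes`` stochastically rounded (floor or ceil with
    probability equal to the fractional part) so E[k] matches the target
    exactly.  Locus positions and carrier sets depend only on the geometry
    arguments and ``seed``, never on ``effect_spec`` — runs that share a seed
    reuse identical founders across sweep / trait-optimum / neutral models.

    ``effect_spec`` is one of ``("effect_size", a)``,
    ``("selection_coefficient", s)`` or ``None`` (neutral loci).
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    if not 0.0 < target_freq < 1.0:
        raise ValueError("target_freq must be in (0, 1)")
    if n_haplotypes < 2:
        raise ValueError("n_haplotypes must be >= 2")
    rng = np.random.default_rng(seed)

    lengths = np.array([g.length_bp for g in recombination_map.groups], dtype=float)
    group_of = rng.choice(len(lengths), size=n_loci, p=lengths / lengths.sum())
    positions = np.empty(n_loci, dtype=np.int64)
    for gi, g in enumerate(recombination_map.groups):
        idx = np.flatnonzero(group_of == gi)
        pos = rng.choice(g.length_bp, size=len(idx), replace=False)
        positions[idx] = np.sort(pos)
    order = np.lexsort((positions, group_of))
    group_of, positions = group_of[order], positions[order]

    expected = target_freq * n_haplotypes
    k_floor = int(np.floor(expected))
    frac = expected - k_floor
    carriers_n = k_floor + (rng.random(n_loci) < frac).astype(int)
    if (carriers_n < 1).any():
        warnings.warn(
            "target_freq * n_haplotypes rounded below one carrier; flooring at 1",
            stacklevel=2,
        )
        carriers_n = np.maximum(carriers_n, 1)

    alleles = np.zeros((n_haplotypes, n_loci), dtype=np.uint8)
    for j in range(n_loci):
        alleles[rng.choice(n_haplotypes, size=carriers_n[j], replace=False), j] = 1

    mode, value = effect_spec if effect_spec is not None else ("neutral", 0.0)
    if mode not in ("effect_size", "selection_coefficient", "neutral"):
        raise ValueError(f"unknown effect mode {mode!r}")
    loci = [
        Locus(
            id=j + 1,
            linkage_group=recombination_map.groups[group_of[j]].name,
            position_bp=int(positions[j]),
            role="neutral" if mode == "neutral" else "selected",
            effect_size=value if mode == "effect_size" else 0.0,
            selection_coefficient=value if mode == "selection_coefficient" else 0.0,
            start_freq=target_freq,
        )
        for j in range(n_loci)
    ]
    return HaplotypePool(alleles, loci, recombination_map)


def expand_to_population(pool: HaplotypePool, N: int, seed: int = 0) -> Population:
    """Expand the founder pool to 2N chromosomes by cycling, then pair randomly.

    Every haplotype receives either floor(2N / n) or ceil(2N / n) copies; the
    haplotypes receiving the extra copy are a random subset, and rows are then
    randomly permuted into N diploid pairs.  Population allele frequencies
    therefore match pool frequencies up to the cycling remainder.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    rng = np.random.default_rng(seed)
    n = pool.n_haplotypes
    full, rem = divmod(2 * N, n)
    copies = np.full(n, full, dtype=np.int64)
    if rem:
        copies[rng.choice(n, size=rem, replace=False)] += 1
    rows = np.repeat(np.arange(n), copies)
    rng.shuffle(rows)
    return Population(pool.alleles[rows], pool.loci)


# ---------------------------------------------------------------------------
# Plain-text interchange


def write_map_tsv(recombination_map: RecombinationMap, path: str | Path) -> None:
    rows = [
        {"chrom": g.name, "start": s.start_bp, "end": s.end_bp,
         "rate_cM_per_Mb": s.rate_cm_per_mb}
        for g in recombination_map.groups
        for s in g.segments
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_map_tsv(path: str | Path) -> RecombinationMap:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    groups = []
    for name, sub in df.groupby("chrom", sort=False):
        segs = tuple(
            Segment(int(r.start), int(r.end), float(r.rate_cM_per_Mb))
            for r in sub.itertuples()
        )
        groups.append(LinkageGroup(str(name), int(sub["end"].max()), segs))
    return RecombinationMap(tuple(groups))


def write_pool_tsv(pool: HaplotypePool, matrix_path: str | Path,
                   loci_path: str | Path) -> None:
    """Haplotype matrix TSV (rows = haplotypes, columns = locus ids) + loci TSV."""
    ids = [l.id for l in pool.loci]
    pd.DataFrame(pool.alleles, columns=ids).to_csv(matrix_path, sep="\t", index=False)
    pd.DataFrame(
        {
            "id": ids,
            "chrom": [l.linkage_group for l in pool.loci],
            "pos": [l.position_bp for l in pool.loci],
            "role": [l.role for l in pool.loci],
            "effect": [l.effect_size for l in pool.loci],
            "selection_coefficient": [l.selection_coefficient for l in pool.loci],
            "start_freq": [l.start_freq for l in pool.loci],
        }
    ).to_csv(loci_path, sep="\t", index=False)


def read_pool_tsv(matrix_path: str | Path, loci_path: str | Path,
                  recombination_map: RecombinationMap | None = None) -> HaplotypePool:
    alleles = pd.read_csv(matrix_path, sep="\t").to_numpy(dtype=np.uint8)
    ldf = pd.read_csv(loci_path, sep="\t", dtype={"chrom": str})
    loci = [
        Locus(
            id=int(r.id), linkage_group=str(r.chrom), position_bp=int(r.pos),
            role=str(r.role), effect_size=float(r.effect),
            selection_coefficient=float(getattr(r, "selection_coefficient", 0.0)),
            start_freq=float(r.start_freq),
        )
        for r in ldf.itertuples()
    ]
    if recombination_map is None:
        recombination_map = _map_spanning(loci)
    return HaplotypePool(alleles, loci, recombination_map)


def read_pool_vcf(path: str | Path,
                  recombination_map: RecombinationMap | None = None,
                  effect_spec: tuple[str, float] | None = None) -> HaplotypePool:
    """Import phased haplotypes from a VCF; ALT is the "+" allele.

    Requires the optional ``cyvcf2`` dependency.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("VCF import requires the optional dependency cyvcf2") from exc

    mode, value = effect_spec if effect_spec is not None else ("neutral", 0.0)
    columns: list[np.ndarray] = []
    loci: list[Locus] = []
    for j, var in enumerate(VCF(str(path))):
        gts = np.array([g[:2] for g in var.genotypes], dtype=np.int64)
        col = gts.reshape(-1)
        if not np.isin(col, (0, 1)).all():
            raise ValueError(f"non-diallelic genotype at {var.CHROM}:{var.POS}")
        columns.append(col.astype(np.uint8))
        loci.append(
            Locus(
                id=j + 1, linkage_group=str(var.CHROM), position_bp=int(var.POS) - 1,
                role="neutral" if mode == "neutral" else "selected",
                effect_size=value if mode == "effect_size" else 0.0,
                selection_coefficient=value if mode == "selection_coefficient" else 0.0,
                start_freq=float(col.mean()),
            )
        )
    alleles = np.column_stack(columns)
    if recombination_map is None:
        recombination_map = _map_spanning(loci)
    return HaplotypePool(alleles, loci, recombination_map)


def _map_spanning(loci: Iterable[Locus], rate_cm_per_mb: float = 2.0) -> RecombinationMap:
    """Uniform-rate fallback map covering all locus positions."""
    by_group: dict[str, int] = {}
    for l in loci:
        by_group[l.linkage_group] = max(by_group.get(l.linkage_group, 0), l.position_bp)
    return build_recombination_map(
        [(name, max_pos + 1_000_000,
          (max_pos + 1_000_000) / 1e6 * rate_cm_per_mb)
         for name, max_pos in by_group.items()]
    )
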