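"""Summary statistics contrasting sweep-like and polygenic adaptation.

All diagnostics operate on the recording grid of :class:`ReplicateResult`
objects: neutral allele-frequency-change (AFC) thresholds, selected-allele
site frequency spectra, pairwise Jaccard parallelism over replicate sets,
normalised phenotype trajectories, and beneficial-loci-per-haplotype
histograms.

AFC is the *signed increase* of the focal "+" allele, ``p_t - p_0``;
thresholds and selected-allele calls use the same signed convention.
Empirical quantiles are nearest-rank (inverse empirical CDF).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .engine import ReplicateResult, simulate_binomial_drift
from .founders import Population

__all__ = [
    "NeutralThresholds",
    "neutral_afc_threshold",
    "neutral_thresholds_from_drift",
    "select_alleles",
    "sfs_of_selected",
    "jaccard",
    "parallelism_series",
    "loci_per_haplotype",
    "normalized_phenotype",
    "time_to_optimum",
    "SFS_BIN_EDGES",
    "SWEEP_LIKE_FREQ",
]

#: 20 half-open frequency bins [x, x+0.05), last bin closed at 1.
SFS_BIN_EDGES = np.round(np.arange(0.0, 1.0001, 0.05), 10)

#: a selected allele at frequency >= 0.9 counts as a sweep-like signature
SWEEP_LIKE_FREQ = 0.9


def _nearest_rank_quantile(values: np.ndarray, q: float) -> float:
    """Smallest observed value whose empirical CDF reaches ``q``."""
    return float(np.quantile(np.asarray(values, dtype=float), q,
                             method="inverted_cdf"))


@dataclass
class NeutralThresholds:
    """Per-generation AFC cutoffs from the upper tail of the neutral null.

    ``thresholds[t]`` is the empirical ``quantile`` (default 95%) of the
    pooled signed frequency increases ``p_t - p_0`` over all loci and all
    neutral replicates.
    """

    generations: np.ndarray
    thresholds: np.ndarray
    quantile: float
    N: int | None = None
    n_neutral_replicates: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.generations = np.asarray(self.generations, dtype=int)
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if len(self.generations) != len(self.thresholds):
            raise ValueError("generations / thresholds length mismatch")

    def at(self, generation: int) -> float:
        idx = np.flatnonzero(self.generations == generation)
        if not len(idx):
            raise KeyError(f"generation {generation} not on the threshold grid")
        return float(self.thresholds[idx[0]])

    def require_grid(self, generations: np.ndarray, N: int | None = None) -> None:
        """Fail loudly when a selection run is scored against mismatched nulls."""
        if not np.array_equal(self.generations, np.asarray(generations)):
            raise ValueError(
                "neutral thresholds were computed on a different recording grid; "
                "re-run the `neutral-threshold` command with a matching scenario"
            )
        if N is not None and self.N is not None and N != self.N:
            raise ValueError(
                f"neutral thresholds were computed for N={self.N}, not N={N}; "
                "re-run the `neutral-threshold` command with a matching scenario"
            )

    # -- plain-text persistence with a provenance header --------------------

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#quantile\t{self.quantile}\n")
            for key in ("N", "n_neutral_replicates", "seed"):
                value = getattr(self, key)
                if value is not None:
                    fh.write(f"#{key}\t{value}\n")
            pd.DataFrame(
                {"generation": self.generations, "threshold": self.thresholds}
            ).to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "NeutralThresholds":
        meta: dict[str, float] = {}
        with open(path) as fh:
            lines = fh.readlines()
        body_start = 0
        for line in lines:
            if not line.startswith("#"):
                break
            key, value = line[1:].rstrip("\n").split("\t")
            meta[key] = float(value)
            body_start += 1
        from io import StringIO

        df = pd.read_csv(StringIO("".join(lines[body_start:])), sep="\t")
        return cls(
            generations=df["generation"].to_numpy(),
            thresholds=df["threshold"].to_numpy(),
            quantile=meta.get("quantile", 0.95),
            N=int(meta["N"]) if "N" in meta else None,
            n_neutral_replicates=(int(meta["n_neutral_replicates"])
                                  if "n_neutral_replicates" in meta else None),
            seed=int(meta["seed"]) if "seed" in meta else None,
        )


def neutral_afc_threshold(neutral_results: Sequence[ReplicateResult],
                          quantile: float = 0.95,
                          N: int | None = None,
                          seed: int | None = None) -> NeutralThresholds:
    """Pool signed frequency increases of all loci across all neutral replicates.

    For each recorded generation the threshold is the nearest-rank
    ``quantile`` of ``p_t - p_0`` pooled over loci and replicates.
    """
    results = list(neutral_results)
    if not results:
        raise ValueError("no neutral replicates supplied")
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must be in (0, 1)")
    grid = results[0].generations
    for r in results[1:]:
        if not np.array_equal(r.generations, grid):
            raise ValueError("neutral replicates must share a recording grid")
    deltas = np.stack([r.freq - r.freq[0] for r in results])  # (R, T, L)
    thresholds = np.array(
        [_nearest_rank_quantile(deltas[:, t, :].ravel(), quantile)
         for t in range(len(grid))]
    )
    return NeutralThresholds(grid, thresholds, quantile, N=N,
                             n_neutral_replicates=len(results), seed=seed)


def neutral_thresholds_from_drift(N: int, p0: float, generations: int,
                                  record_interval: int, n_series: int,
                                  seed: int, quantile: float = 0.95,
                                  ) -> NeutralThresholds:
    """Fast neutral null via exact binomial drift of independent locus series.

    Marginal neutral dynamics are binomial per generation irrespective of
    linkage, so ``n_series`` independent single-locus trajectories reproduce
    the pooled AFC null of full neutral replicates.
    """
    traj = simulate_binomial_drift(N, p0, generations, n_series, seed,
                                   record_interval=record_interval)
    grid = np.arange(0, generations + 1, record_interval)
    deltas = traj - traj[0]
    thresholds = np.array(
        [_nearest_rank_quantile(deltas[t], quantile) for t in range(len(grid))]
    )
    return NeutralThresholds(grid, thresholds, quantile, N=N,
                             n_neutral_replicates=n_series, seed=seed)


def select_alleles(freqs_t: np.ndarray, freqs_0: np.ndarray,
                   threshold: float) -> np.ndarray:
    """Indices whose signed frequency increase exceeds the neutral threshold."""
    ft = np.asarray(freqs_t, dtype=float)
    f0 = np.asarray(freqs_0, dtype=float)
    if ft.shape != f0.shape:
        raise ValueError("frequency vectors must have equal length")
    return np.flatnonzero(ft - f0 > threshold)


@dataclass
class SFSRow:
    """Binned site frequency spectrum of selected alleles at one time point."""

    bin_counts: np.ndarray      # 20 bins over [0, 1], step 0.05
    n_selected: int
    n_sweep_like: int           # selected alleles at frequency >= 0.9
    median_freq: float          # NaN when nothing is selected

    def __post_init__(self) -> None:
        if int(self.bin_counts.sum()) != self.n_selected:
            raise ValueError("bin counts must partition the selected alleles")
        if self.n_sweep_like > self.n_selected:
            raise ValueError("n_sweep_like cannot exceed n_selected")


def sfs_of_selected(freqs_t: np.ndarray, selected: np.ndarray) -> SFSRow:
    """Histogram selected-allele frequencies in 0.05 bins (last bin closed)."""
    freqs = np.asarray(freqs_t, dtype=float)[np.asarray(selected, dtype=int)]
    counts, _ = np.histogram(freqs, bins=SFS_BIN_EDGES)
    return SFSRow(
        bin_counts=counts,
        n_selected=len(freqs),
        n_sweep_like=int(np.sum(freqs >= SWEEP_LIKE_FREQ)),
        median_freq=float(np.median(freqs)) if len(freqs) else float("nan"),
    )


def jaccard(set_a: Iterable[int], set_b: Iterable[int]) -> float:
    """|a ∩ b| / |a ∪ b|; two empty sets score 0 (no detected parallelism)."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


@dataclass
class ParallelismSeries:
    """Mean (and SD) pairwise Jaccard index over replicate sets per generation."""

    generations: np.ndarray
    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        if ((self.mean < 0) | (self.mean > 1)).any():
            raise ValueError("Jaccard means must lie in [0, 1]")


def _selected_sets(results: Sequence[ReplicateResult],
                   thresholds: "NeutralThresholds") -> list[list[set[int]]]:
    """Per replicate, per generation: the selected-allele index set."""
    out = []
    for r in results:
        thresholds.require_grid(r.generations)
        out.append([
            set(select_alleles(r.freq[t], r.freq[0], thresholds.thresholds[t]))
            for t in range(len(r.generations))
        ])
    return out


def parallelism_series(replicate_sets: Sequence[Sequence[ReplicateResult]],
                       thresholds: "NeutralThresholds") -> ParallelismSeries:
    """Average pairwise Jaccard of selected-allele sets, per generation.

    ``replicate_sets`` is a collection of sets of replicates (canonically 50
    sets of 10).  Within each set all pairwise Jaccard indices are averaged;
    the mean and SD over sets are reported per recorded generation.
    """
    if not replicate_sets:
        raise ValueError("no replicate sets supplied")
    grid = replicate_sets[0][0].generations
    set_means = []
    for group in replicate_sets:
        sel = _selected_sets(group, thresholds)
        T = len(grid)
        means = np.empty(T)
        for t in range(T):
            vals = [
                jaccard(sel[i][t], sel[j][t])
                for i in range(len(group)) for j in range(i + 1, len(group))
            ]
            means[t] = float(np.mean(vals)) if vals else 0.0
        set_means.append(means)
    arr = np.stack(set_means)
    return ParallelismSeries(grid, arr.mean(axis=0), arr.std(axis=0, ddof=0))


def loci_per_haplotype(pop: Population | np.ndarray,
                       selected_loci: np.ndarray | None = None,
                       n_loci: int | None = None) -> np.ndarray:
    """Proportion of chromosome rows carrying k focal alleles, k = 0..L.

    ``selected_loci`` restricts the count to a subset of columns (default:
    all loci); the histogram is always reported over the full 0..L range so
    rows are comparable across time points.
    """
    haps = pop.haplotypes if isinstance(pop, Population) else np.asarray(pop)
    L = n_loci if n_loci is not None else haps.shape[1]
    cols = (np.asarray(selected_loci, dtype=int)
            if selected_loci is not None else slice(None))
    loads = haps[:, cols].sum(axis=1).astype(np.int64)
    counts = np.bincount(loads, minlength=L + 1)
    return counts / haps.shape[0]


def normalized_phenotype(result: ReplicateResult) -> np.ndarray:
    """Median genotypic phenotype shifted by the generation-0 population mean."""
    if not np.isfinite(result.pheno_median).any():
        raise ValueError("replicate carries no phenotype record "
                         "(sweep or neutral model)")
    return result.pheno_median - result.pheno_mean0


def time_to_optimum(series: Sequence[np.ndarray] | np.ndarray,
                    generations: np.ndarray,
                    optimum_distance: float,
                    tol: float = 0.0) -> int | None:
    """First recorded generation at which the across-replicate mean normalised
    phenotype reaches the optimum displacement; ``None`` if never reached.

    With equal per-locus effects ``a`` the genotypic trait is discrete with
    resolution ``a`` (one allele substitution), so the recorded median cannot
    approach the optimum closer than one quantum and equilibrates just below
    it.  Pass ``tol=a`` to count the optimum as reached once the mean is
    within one trait quantum of the displacement; the default ``tol=0``
    applies the strict inequality.
    """
    arr = np.asarray(series, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.shape[1] != len(generations):
        raise ValueError("series must lie on the recording grid")
    mean = arr.mean(axis=0)
    hit = np.flatnonzero(mean >= optimum_distance - tol)
    return int(generations[hit[0]]) if len(hit) else None
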