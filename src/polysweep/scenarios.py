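"""Scenario configuration and end-to-end experiment orchestration.

A :class:`ScenarioSpec` captures one cell of the experiment grid (model x
population size x locus count x effect strength).  :func:`run_scenario`
builds founders once per scenario seed — so sweep / trait-optimum / neutral
runs sharing a seed share identical founder carrier sets — runs the
replicates with derived child seeds, computes diagnostics against matching
neutral thresholds, and optionally serialises everything as a plain-text
results bundle.
"""

from __future__ import annotations

import json
import platform
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diagnostics import (
    NeutralThresholds,
    ParallelismSeries,
    loci_per_haplotype,
    normalized_phenotype,
    parallelism_series,
    select_alleles,
    sfs_of_selected,
    time_to_optimum,
)
from .engine import ReplicateResult, run_replicate
from .founders import (
    HaplotypePool,
    default_map,
    generate_founder_haplotypes,
    read_pool_tsv,
    write_map_tsv,
    write_pool_tsv,
)

__all__ = [
    "ScenarioSpec",
    "RunBundle",
    "run_scenario",
    "compare_models",
    "write_bundle",
    "read_bundle",
    "write_replicate_tsv",
    "read_replicate_tsv",
]

MODELS = ("sweep", "trait_optimum", "neutral")


@dataclass
class ScenarioSpec:
    """One simulation scenario; field names mirror the experiment-grid table."""

    model: str
    N: int
    n_loci: int = 100
    start_freq: float = 0.05
    s: float | None = None                 # sweep: per-locus selection coefficient
    effect_size: float | None = None       # trait optimum: per-locus effect
    optimum: float | None = None           # explicit optimum; None -> adjusted
    optimum_distance: float = 1.1          # displacement above the founder mean
    fitness_sd: float = 0.3
    min_fit: float = 0.5
    max_fit: float = 4.5
    heritability: float = 0.5
    generations: int = 140
    record_interval: int = 10
    n_replicates: int = 500
    root_seed: int = 0
    n_haplotypes: int = 189

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}")
        if self.model == "sweep" and self.s is None:
            raise ValueError("sweep model requires a selection coefficient `s`")
        if self.model == "trait_optimum" and self.effect_size is None:
            raise ValueError("trait_optimum model requires `effect_size`")
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if self.generations % self.record_interval != 0:
            raise ValueError("generations must be a multiple of record_interval")

    @property
    def record_generations(self) -> np.ndarray:
        return np.arange(0, self.generations + 1, self.record_interval)

    def effect_spec(self) -> tuple[str, float] | None:
        if self.model == "sweep":
            return ("selection_coefficient", float(self.s))
        if self.model == "trait_optimum":
            return ("effect_size", float(self.effect_size))
        return None

    def build_founders(self) -> HaplotypePool:
        """Founder pool from the scenario seed; carrier sets are identical for
        all models sharing (n_loci, start_freq, n_haplotypes, root_seed)."""
        rmap = default_map(seed=self.root_seed)
        return generate_founder_haplotypes(
            rmap,
            n_loci=self.n_loci,
            target_freq=self.start_freq,
            n_haplotypes=self.n_haplotypes,
            effect_spec=self.effect_spec(),
            seed=self.root_seed,
        )

    def replicate_seed(self, replicate: int) -> list[int]:
        """Documented splitting rule: replicate r is seeded by (root_seed, r)."""
        return [self.root_seed, replicate]

    # -- YAML round trip ----------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioSpec":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


@dataclass
class RunBundle:
    """Everything one scenario run produced, self-describing and re-runnable."""

    scenario: ScenarioSpec
    pool: HaplotypePool
    results: list[ReplicateResult]
    thresholds: NeutralThresholds | None = None
    diagnostics: dict[str, pd.DataFrame] = field(default_factory=dict)
    log: dict = field(default_factory=dict)

    @property
    def generations(self) -> np.ndarray:
        return self.results[0].generations


def run_scenario(spec: ScenarioSpec,
                 thresholds: NeutralThresholds | None = None,
                 n_replicates: int | None = None,
                 keep_final_population: bool = False,
                 out_dir: str | Path | None = None,
                 parallelism_set_size: int = 10,
                 load_hist_replicates: int = 50) -> RunBundle:
    """Run all replicates of a scenario and compute its diagnostics tables.

    ``thresholds`` must match the scenario's N and recording grid when the
    threshold-dependent diagnostics (SFS, parallelism) are wanted; without
    thresholds only the phenotype/fitness and haplotype-load tables are built.
    Neutral scenarios never require thresholds.
    """
    n_rep = n_replicates if n_replicates is not None else spec.n_replicates
    pool = spec.build_founders()
    t0 = time.time()
    results = [
        run_replicate(spec, seed=spec.replicate_seed(r), pool=pool,
                      keep_final_population=keep_final_population)
        for r in range(n_rep)
    ]
    wall = time.time() - t0

    if thresholds is not None:
        thresholds.require_grid(spec.record_generations, N=spec.N)
    diagnostics = _diagnostics_tables(
        spec, results, thresholds,
        set_size=parallelism_set_size, load_reps=load_hist_replicates)
    log = {
        "scenario": asdict(spec),
        "n_replicates_run": n_rep,
        "wall_seconds": round(wall, 3),
        "seed_rule": "replicate r seeded by numpy default_rng([root_seed, r])",
        "polysweep_version": __version__,
        "numpy_version": np.__version__,
        "platform": platform.platform(),
    }
    bundle = RunBundle(spec, pool, results, thresholds, diagnostics, log)
    if out_dir is not None:
        write_bundle(bundle, out_dir)
    return bundle


def _diagnostics_tables(spec: ScenarioSpec, results: list[ReplicateResult],
                        thresholds: NeutralThresholds | None,
                        set_size: int, load_reps: int) -> dict[str, pd.DataFrame]:
    grid = results[0].generations
    tables: dict[str, pd.DataFrame] = {}

    # phenotype / fitness trajectories
    rows = []
    for t, gen in enumerate(grid):
        fit = [r.fitness_median[t] for r in results]
        row = {
            "generation": int(gen),
            "fitness_median_mean": float(np.mean(fit)),
            "fitness_median_sd": float(np.std(fit)),
        }
        if spec.model == "trait_optimum":
            norm = [normalized_phenotype(r)[t] for r in results]
            row["norm_pheno_mean"] = float(np.mean(norm))
            row["norm_pheno_sd"] = float(np.std(norm))
        rows.append(row)
    tables["trajectory"] = pd.DataFrame(rows)

    if spec.model == "trait_optimum":
        series = np.stack([normalized_phenotype(r) for r in results])
        tto = time_to_optimum(series, grid, spec.optimum_distance,
                              tol=spec.effect_size)
        tables["trajectory"].attrs["time_to_optimum"] = tto

    # haplotype-load histograms (averaged over the first `load_reps` replicates)
    subset = results[:load_reps]
    load = np.mean([r.load_hist for r in subset], axis=0)  # (T, L+1)
    load_df = pd.DataFrame(load, columns=[f"k{k}" for k in range(load.shape[1])])
    load_df.insert(0, "generation", grid)
    tables["haplotype_load"] = load_df

    if thresholds is not None or spec.model == "neutral":
        thr = thresholds
        if thr is None:
            from .diagnostics import neutral_afc_threshold

            thr = neutral_afc_threshold(results, N=spec.N, seed=spec.root_seed)
        tables["sfs"] = _sfs_table(results, thr)
        set_size = min(set_size, len(results))
        sets = [results[i:i + set_size]
                for i in range(0, len(results) - set_size + 1, set_size)]
        if sets:
            ps = parallelism_series(sets, thr)
            tables["parallelism"] = pd.DataFrame(
                {"generation": ps.generations, "jaccard_mean": ps.mean,
                 "jaccard_sd": ps.sd})
    return tables


def _sfs_table(results: list[ReplicateResult],
               thresholds: NeutralThresholds) -> pd.DataFrame:
    """Per-generation SFS summary, averaged across replicates.

    The median selected-allele frequency is taken within each replicate over
    its own selected loci, then averaged over replicates that selected at
    least one locus.
    """
    grid = results[0].generations
    rows = []
    for t, gen in enumerate(grid):
        thr = thresholds.thresholds[t]
        sfs_rows = []
        for r in results:
            sel = select_alleles(r.freq[t], r.freq[0], thr)
            sfs_rows.append(sfs_of_selected(r.freq[t], sel))
        medians = [s.median_freq for s in sfs_rows if s.n_selected > 0]
        mean_bins = np.mean([s.bin_counts for s in sfs_rows], axis=0)
        row = {
            "generation": int(gen),
            "threshold": float(thr),
            "n_selected_mean": float(np.mean([s.n_selected for s in sfs_rows])),
            "n_sweep_like_mean": float(np.mean([s.n_sweep_like for s in sfs_rows])),
            "median_selected_freq_mean": (float(np.mean(medians))
                                          if medians else float("nan")),
        }
        for b, count in enumerate(mean_bins):
            row[f"bin_{b * 0.05:.2f}"] = float(count)
        rows.append(row)
    return pd.DataFrame(rows)


def compare_models(bundle_sweep: RunBundle, bundle_opt: RunBundle,
                   thresholds: NeutralThresholds | None = None) -> pd.DataFrame:
    """Tabulate the four discriminating features for a sweep / trait-optimum pair.

    Descriptive only — no classification verdict.  The late window starts at
    the trait-optimum bundle's time-to-optimum (falling back to the midpoint
    of the run when the optimum is never reached):

    * late-window slope of the mean median selected-allele frequency;
    * fitness / normalised-phenotype trajectory summaries;
    * parallelism (Jaccard) trend after time-to-optimum;
    * haplotype-load (mean "+" alleles per chromosome) late-window change.
    """
    grid = bundle_sweep.generations
    if not np.array_equal(grid, bundle_opt.generations):
        raise ValueError("bundles were recorded on different generation grids")
    if bundle_sweep.scenario.root_seed != bundle_opt.scenario.root_seed:
        raise ValueError("bundles do not share founders (different root seeds)")
    if bundle_sweep.scenario.N != bundle_opt.scenario.N:
        raise ValueError("bundles have different population sizes")

    tto = bundle_opt.diagnostics.get("trajectory", pd.DataFrame()).attrs.get(
        "time_to_optimum")
    window_start = int(tto) if tto is not None else int(grid[len(grid) // 2])
    t_start = int(np.flatnonzero(grid >= window_start)[0])
    t_end = len(grid) - 1
    span = float(grid[t_end] - grid[t_start]) or 1.0

    def features(bundle: RunBundle) -> dict[str, float]:
        out: dict[str, float] = {}
        sfs = bundle.diagnostics.get("sfs")
        if sfs is not None:
            med = sfs["median_selected_freq_mean"].to_numpy()
            out["median_selected_freq_change_late"] = float(
                med[t_end] - med[t_start])
            out["median_selected_freq_slope_late"] = float(
                (med[t_end] - med[t_start]) / span)
        traj = bundle.diagnostics["trajectory"]
        out["fitness_median_final"] = float(
            traj["fitness_median_mean"].iloc[t_end])
        if "norm_pheno_mean" in traj:
            out["norm_pheno_final"] = float(traj["norm_pheno_mean"].iloc[t_end])
        par = bundle.diagnostics.get("parallelism")
        if par is not None:
            jm = par["jaccard_mean"].to_numpy()
            out["parallelism_change_late"] = float(jm[t_end] - jm[t_start])
        load = bundle.diagnostics["haplotype_load"]
        k = np.arange(load.shape[1] - 1)
        mean_load = load.iloc[:, 1:].to_numpy() @ k
        out["haplotype_load_change_late"] = float(
            mean_load[t_end] - mean_load[t_start])
        return out

    df = pd.DataFrame(
        {"sweep": features(bundle_sweep), "trait_optimum": features(bundle_opt)}
    )
    df.attrs["window_start_generation"] = int(grid[t_start])
    df.attrs["window_end_generation"] = int(grid[t_end])
    return df


# ---------------------------------------------------------------------------
# Plain-text bundle serialisation


def write_replicate_tsv(result: ReplicateResult, prefix: str | Path) -> None:
    prefix = Path(prefix)
    freq_df = pd.DataFrame(result.freq,
                           columns=[f"locus_{j + 1}" for j in
                                    range(result.freq.shape[1])])
    freq_df.insert(0, "generation", result.generations)
    freq_df.to_csv(f"{prefix}_freq.tsv", sep="\t", index=False)

    summary = pd.DataFrame(
        {
            "generation": result.generations,
            "pheno_median": result.pheno_median,
            "fitness_median": result.fitness_median,
            "pheno_mean0": result.pheno_mean0,
        }
    )
    summary.to_csv(f"{prefix}_summary.tsv", sep="\t", index=False)

    load_df = pd.DataFrame(result.load_hist,
                           columns=[f"k{k}" for k in
                                    range(result.load_hist.shape[1])])
    load_df.insert(0, "generation", result.generations)
    load_df.to_csv(f"{prefix}_load.tsv", sep="\t", index=False)


def read_replicate_tsv(prefix: str | Path) -> ReplicateResult:
    prefix = Path(prefix)
    freq_df = pd.read_csv(f"{prefix}_freq.tsv", sep="\t")
    summary = pd.read_csv(f"{prefix}_summary.tsv", sep="\t")
    load_df = pd.read_csv(f"{prefix}_load.tsv", sep="\t")
    return ReplicateResult(
        generations=freq_df["generation"].to_numpy(),
        freq=freq_df.drop(columns="generation").to_numpy(),
        pheno_median=summary["pheno_median"].to_numpy(),
        fitness_median=summary["fitness_median"].to_numpy(),
        pheno_mean0=float(summary["pheno_mean0"].iloc[0]),
        load_hist=load_df.drop(columns="generation").to_numpy(),
    )


def write_bundle(bundle: RunBundle, out_dir: str | Path) -> None:
    out = Path(out_dir)
    (out / "replicates").mkdir(parents=True, exist_ok=True)
    (out / "diagnostics").mkdir(exist_ok=True)
    bundle.scenario.to_yaml(out / "scenario.yaml")
    write_map_tsv(bundle.pool.recombination_map, out / "map.tsv")
    write_pool_tsv(bundle.pool, out / "founders_matrix.tsv",
                   out / "founders_loci.tsv")
    for r, result in enumerate(bundle.results):
        write_replicate_tsv(result, out / "replicates" / f"rep_{r:04d}")
    for name, df in bundle.diagnostics.items():
        df.to_csv(out / "diagnostics" / f"{name}.tsv", sep="\t", index=False)
    if bundle.thresholds is not None:
        bundle.thresholds.to_tsv(out / "diagnostics" / "neutral_thresholds.tsv")
    with open(out / "log.json", "w") as fh:
        json.dump(bundle.log, fh, indent=2)


def read_bundle(out_dir: str | Path) -> RunBundle:
    out = Path(out_dir)
    spec = ScenarioSpec.from_yaml(out / "scenario.yaml")
    pool = read_pool_tsv(out / "founders_matrix.tsv", out / "founders_loci.tsv")
    prefixes = sorted(
        {p.name.rsplit("_", 1)[0] for p in (out / "replicates").glob("rep_*_freq.tsv")}
    )
    results = [read_replicate_tsv(out / "replicates" / p) for p in prefixes]
    diagnostics = {
        p.stem: pd.read_csv(p, sep="\t")
        for p in (out / "diagnostics").glob("*.tsv")
        if p.name != "neutral_thresholds.tsv"
    }
    thresholds = None
    thr_path = out / "diagnostics" / "neutral_thresholds.tsv"
    if thr_path.exists():
        thresholds = NeutralThresholds.from_tsv(thr_path)
    log = {}
    if (out / "log.json").exists():
        log = json.loads((out / "log.json").read_text())
    return RunBundle(spec, pool, results, thresholds, diagnostics, log)
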