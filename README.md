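# polysweep

Forward Wright–Fisher simulations of replicated evolve-and-resequence (E&R)
experiments, contrasting two modes of adaptation on identical founders:

* **selective sweep** — independent beneficial loci with multiplicative,
  codominant fitness (genotype fitness 1, 1 + s/2, 1 + s);
* **trait optimum** — a quantitative trait built additively from the same
  loci, mapped to fitness through a Gaussian stabilising-selection function
  after a sudden shift of the phenotypic optimum.

The package also implements the diagnostic statistics that tell the two
models apart in time-series data: neutral allele-frequency-change (AFC)
thresholds, selected-allele site frequency spectra and sweep-like counts,
normalised phenotype / fitness trajectories, pairwise Jaccard parallelism
across replicate sets, and beneficial-loci-per-haplotype distributions.

## Layout

| module                  | contents |
|-------------------------|----------|
| `polysweep.founders`    | recombination maps, synthetic founder haplotype pools (default: 189 haplotypes, loci at starting frequency 0.05 on two linkage groups), expansion to census size, TSV/VCF interchange |
| `polysweep.engine`      | fitness machinery, Haldane recombination, one-generation Wright–Fisher step, whole-replicate driver, fast binomial neutral drift |
| `polysweep.diagnostics` | neutral AFC thresholds, selected-allele SFS, Jaccard parallelism, haplotype-load histograms, normalised phenotype, time to optimum |
| `polysweep.scenarios`   | scenario YAML configs, replicate orchestration with derived seeds, diagnostics tables, plain-text result bundles, model comparison |
| `polysweep.cli`         | `polysweep` command-line interface |

## CLI

```bash
# neutral null distribution for a population size / recording grid
polysweep neutral-threshold --config examples/neutral_450.yaml --out thr.tsv

# run scenarios (sweep + trait optimum share founders via the same root_seed)
polysweep simulate --config examples/sweep_A450.yaml --out sweep_run/ --thresholds thr.tsv
polysweep simulate --config examples/opt_A450.yaml   --out opt_run/   --thresholds thr.tsv

# recompute individual diagnostics from a bundle
polysweep sfs            --bundle sweep_run/ --thresholds thr.tsv --out sfs.tsv
polysweep parallelism    --bundle sweep_run/ --thresholds thr.tsv --out par.tsv
polysweep haplotype-load --bundle sweep_run/ --out load.tsv
polysweep phenotype      --bundle opt_run/   --out pheno.tsv

# tabulate the discriminating features of a model pair
polysweep compare --sweep sweep_run/ --opt opt_run/ --out features.tsv
```

Example scenario configs live in `examples/`; `examples/opt_A450.yaml`
mirrors the default trait-optimum parameterisation (N = 450, 100 loci,
effect size 0.04, starting frequency 0.05, Gaussian fitness sd 0.3 with
range 0.5–4.5, heritability 0.5, optimum displaced 1.1 trait units above the
founder mean, i.e. −2.5 in absolute trait units).

## Notes on conventions

* AFC is the signed increase of the focal "+" allele; thresholds use the
  nearest-rank empirical quantile.
* Replicate `r` of a scenario is seeded by `default_rng([root_seed, r])`, so
  replicate sets are reproducible and extensible.
* Founder carrier sets depend only on the geometry arguments and the seed,
  never on the effect specification — sweep, trait-optimum and neutral runs
  sharing a `root_seed` use identical founders.
* The genotypic trait is discrete with resolution equal to the per-locus
  effect size; `time_to_optimum` accepts a tolerance of one trait quantum
  for the "optimum reached" read-off (wired in by the scenario runner).
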