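import numpy as np
import pytest

import polysweep as ps

ACCEPT_SEED = 20200418


@pytest.fixture(scope="session")
def small_map():
    return ps.build_recombination_map([("2", 10_000_000, 50.0)])


@pytest.fixture(scope="session")
def founder_pool():
    """Default-geometry founder pool: 100 loci, 189 haplotypes, p0 = 0.05."""
    return ps.generate_founder_haplotypes(
        ps.default_map(0), n_loci=100, target_freq=0.05, n_haplotypes=189,
        effect_spec=("effect_size", 0.04), seed=11,
    )


# --- heavy session-scoped runs shared between acceptance tests -------------


@pytest.fixture(scope="session")
def thresholds_450():
    return ps.neutral_thresholds_from_drift(
        N=450, p0=0.05, generations=140, record_interval=10,
        n_series=50_000, seed=ACCEPT_SEED)


@pytest.fixture(scope="session")
def thresholds_9000():
    return ps.neutral_thresholds_from_drift(
        N=9000, p0=0.05, generations=140, record_interval=10,
        n_series=50_000, seed=ACCEPT_SEED)


@pytest.fixture(scope="session")
def trait_bundle_450(thresholds_450):
    spec = ps.ScenarioSpec(model="trait_optimum", N=450, n_loci=100,
                           effect_size=0.04, root_seed=ACCEPT_SEED,
                           n_replicates=50)
    return ps.run_scenario(spec, thresholds=thresholds_450)


@pytest.fixture(scope="session")
def trait_bundle_9000(thresholds_9000):
    spec = ps.ScenarioSpec(model="trait_optimum", N=9000, n_loci=100,
                           effect_size=0.04, root_seed=ACCEPT_SEED,
                           n_replicates=20)
    return ps.run_scenario(spec, thresholds=thresholds_9000)


@pytest.fixture(scope="session")
def sweep_bundle_9000(thresholds_9000):
    spec = ps.ScenarioSpec(model="sweep", N=9000, n_loci=100, s=0.08,
                           root_seed=ACCEPT_SEED, n_replicates=10)
    return ps.run_scenario(spec, thresholds=thresholds_9000)
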