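import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import polysweep as ps
from polysweep.engine import (
    GaussianFitnessSpec,
    SweepFitnessSpec,
    TraitSpec,
    _gametes,
    adjusted_optimum,
    environmental_variance_for_heritability,
    gaussian_fitness,
    inter_locus_switch_probs,
    phenotype,
    recombine,
    simulate_generation,
    sweep_fitness,
    trait_value,
)
from polysweep.founders import (
    HaplotypePool,
    Locus,
    Population,
    build_recombination_map,
)

SCEN_A = TraitSpec(np.full(100, 0.04), heritability=0.5)


class TestTraitValue:
    def test_all_heterozygous_is_zero(self):
        assert trait_value(np.ones(100), SCEN_A) == pytest.approx(0.0)

    def test_all_minus_homozygous(self):
        assert trait_value(np.zeros(100), SCEN_A) == pytest.approx(-4.0)

    def test_founder_mean_closed_form(self):
        # E[z] at p = 0.05 equals 100 * 0.04 * (0.05 - 0.95) = -3.6
        rng = np.random.default_rng(0)
        dosages = rng.binomial(2, 0.05, size=(200_000, 100))
        zbar = np.mean(trait_value(dosages, SCEN_A))
        assert zbar == pytest.approx(-3.6, abs=0.005)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            trait_value(np.ones(5), SCEN_A)


class TestPhenotype:
    def test_zero_ve_identity(self):
        rng = np.random.default_rng(0)
        z = np.array([1.0, -2.0])
        assert phenotype(z, 0.0, rng) is z

    def test_noise_variance(self):
        rng = np.random.default_rng(1)
        z = np.zeros(100_000)
        x = phenotype(z, 0.25, rng)
        assert np.var(x - z) == pytest.approx(0.25, rel=0.05)

    def test_negative_ve(self):
        with pytest.raises(ValueError):
            phenotype(0.0, -1.0, np.random.default_rng(0))


class TestGaussianFitness:
    SPEC = GaussianFitnessSpec(optimum=-2.5, sd=0.3, min_fit=0.5, max_fit=4.5)

    def test_maximum_at_optimum(self):
        assert gaussian_fitness(-2.5, self.SPEC) == pytest.approx(4.5)

    def test_far_tail_approaches_min(self):
        assert gaussian_fitness(-2.5 + 3.0, self.SPEC) == pytest.approx(0.5, abs=1e-9)

    def test_one_sd_closed_form(self):
        expected = 4.0 * np.exp(-0.5) + 0.5  # ~2.9261
        assert gaussian_fitness(-2.2, self.SPEC) == pytest.approx(expected)
        assert expected == pytest.approx(2.9261, abs=1e-4)

    @given(st.floats(-10, 10), st.floats(0.01, 10))
    def test_reflection_symmetry(self, delta, _unused):
        spec = self.SPEC
        assert gaussian_fitness(spec.optimum + delta, spec) == pytest.approx(
            gaussian_fitness(spec.optimum - delta, spec))

    @given(st.floats(0, 8), st.floats(0.001, 8))
    def test_strictly_decreasing_in_distance(self, d1, extra):
        spec = self.SPEC
        w_near = gaussian_fitness(spec.optimum + d1, spec)
        w_far = gaussian_fitness(spec.optimum + d1 + extra, spec)
        assert w_far <= w_near
        # open lower bound mathematically; equality only via float underflow
        assert spec.min_fit <= w_near <= spec.max_fit

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            GaussianFitnessSpec(0.0, sd=0.0)
        with pytest.raises(ValueError):
            GaussianFitnessSpec(0.0, sd=1.0, min_fit=2.0, max_fit=1.0)


class TestSweepFitness:
    SPEC = SweepFitnessSpec(np.full(2, 0.08))

    def test_no_beneficial_alleles(self):
        assert sweep_fitness(np.zeros(2), self.SPEC) == pytest.approx(1.0)

    def test_single_heterozygote(self):
        assert sweep_fitness(np.array([1, 0]), self.SPEC) == pytest.approx(1.04)

    def test_two_homozygotes_multiplicative(self):
        assert sweep_fitness(np.array([2, 2]), self.SPEC) == pytest.approx(1.08**2)

    def test_negative_s_rejected(self):
        with pytest.raises(ValueError):
            SweepFitnessSpec(np.array([-0.1]))


class TestHeritabilityCalibration:
    def test_h2_one_gives_zero_ve(self):
        trait = TraitSpec(np.array([1.0]), heritability=1.0)
        assert environmental_variance_for_heritability(trait, np.array([0.5])) == 0.0

    def test_single_locus_closed_form(self):
        trait = TraitSpec(np.array([1.0]), heritability=0.5)
        ve = environmental_variance_for_heritability(trait, np.array([0.5]))
        assert ve == pytest.approx(0.5)  # Vg0 = 2 * 0.5 * 0.5 * 1 = 0.5

    def test_default_scenario_closed_form(self):
        ve = environmental_variance_for_heritability(SCEN_A, np.full(100, 0.05))
        assert ve == pytest.approx(0.0152)

    def test_zero_heritability_rejected(self):
        with pytest.raises(ValueError):
            TraitSpec(np.array([1.0]), heritability=0.0)


class TestAdjustedOptimum:
    def test_default_scenario(self):
        opt = adjusted_optimum(SCEN_A, np.full(100, 0.05), distance=1.1)
        assert opt == pytest.approx(-2.5)

    def test_unreachable_optimum_warns(self):
        trait = TraitSpec(np.full(10, 0.04), heritability=0.5)
        with pytest.warns(UserWarning, match="cannot be reached"):
            opt = adjusted_optimum(trait, np.full(10, 0.05), distance=1.1)
        assert opt == pytest.approx(-0.36 + 1.1)
        assert opt > 10 * 0.04

    def test_zero_distance_returns_founder_mean(self):
        opt = adjusted_optimum(SCEN_A, np.full(100, 0.05), distance=0.0)
        assert opt == pytest.approx(-3.6)


def _two_locus_setup(genetic_length_cm):
    m = build_recombination_map([("2", 1_000_000, genetic_length_cm)])
    loci = [Locus(id=1, linkage_group="2", position_bp=0),
            Locus(id=2, linkage_group="2", position_bp=999_999)]
    return m, loci


class TestRecombination:
    def test_negligible_genetic_length_keeps_strand(self):
        m, loci = _two_locus_setup(1e-9)
        rng = np.random.default_rng(0)
        pat, mat = np.array([0, 0], np.uint8), np.array([1, 1], np.uint8)
        for _ in range(50):
            gam = recombine((pat, mat), m, loci, rng)
            assert gam.tolist() in ([0, 0], [1, 1])

    def test_identical_strands_identity(self):
        m, loci = _two_locus_setup(80.0)
        rng = np.random.default_rng(0)
        h = np.array([1, 0], np.uint8)
        for _ in range(50):
            assert recombine((h, h), m, loci, rng).tolist() == [1, 0]

    def test_haldane_recombinant_fraction(self):
        # 1 Morgan between terminal loci: r = (1 - e^-2) / 2 ~ 0.4323
        m, loci = _two_locus_setup(100.0)
        r = inter_locus_switch_probs(m, loci)
        assert r[0] == pytest.approx(0.5 * (1 - np.exp(-2.0)), abs=1e-6)
        haps = np.array([[0, 0], [1, 1]], np.uint8)
        rng = np.random.default_rng(42)
        gams = _gametes(haps, np.zeros(100_000, int), r, rng)
        recomb_frac = np.mean(gams[:, 0] != gams[:, 1])
        assert recomb_frac == pytest.approx(0.4323, abs=0.01)

    def test_free_recombination_between_groups(self):
        m = build_recombination_map([("2", 1_000_000, 1e-9),
                                     ("3", 1_000_000, 1e-9)])
        loci = [Locus(id=1, linkage_group="2", position_bp=5),
                Locus(id=2, linkage_group="3", position_bp=5)]
        r = inter_locus_switch_probs(m, loci)
        assert r[0] == pytest.approx(0.5)


def _population_at_freq(N, p, L=1, seed=0):
    rng = np.random.default_rng(seed)
    haps = np.zeros((2 * N, L), dtype=np.uint8)
    k = int(round(2 * N * p))
    for j in range(L):
        haps[rng.choice(2 * N, k, replace=False), j] = 1
    m = build_recombination_map([("2", 1_000_000, 50.0)])
    loci = [Locus(id=j + 1, linkage_group="2", position_bp=1000 * (j + 1))
            for j in range(L)]
    return Population(haps, loci), m


class TestSimulateGeneration:
    def test_neutral_drift_mean_and_variance(self):
        # one-generation increments: mean 0, variance p(1-p)/2N
        N, p, runs = 50, 0.5, 4000
        pop, m = _population_at_freq(N, p, seed=1)
        rng = np.random.default_rng(7)
        w = np.ones(N)
        deltas = np.empty(runs)
        for i in range(runs):
            child = simulate_generation(pop, w, m, rng)
            deltas[i] = child.allele_frequencies()[0] - p
        expected_var = p * (1 - p) / (2 * N)
        se_mean = np.sqrt(expected_var / runs)
        assert abs(deltas.mean()) < 3 * se_mean
        assert np.var(deltas) == pytest.approx(expected_var, rel=0.10)

    def test_single_individual_rejected(self):
        pop, m = _population_at_freq(1, 0.5)
        with pytest.raises(ValueError):
            simulate_generation(pop, np.ones(1), m, np.random.default_rng(0))

    def test_all_zero_fitness_rejected(self):
        pop, m = _population_at_freq(5, 0.5)
        with pytest.raises(ValueError):
            simulate_generation(pop, np.zeros(5), m, np.random.default_rng(0))

    def test_fitness_concentrated_on_one_individual(self):
        pop, m = _population_at_freq(10, 0.5, L=3, seed=3)
        w = np.zeros(10)
        w[4] = 1.0
        child = simulate_generation(pop, w, m, np.random.default_rng(0))
        parental = {tuple(pop.haplotypes[8]), tuple(pop.haplotypes[9])}
        # gametes may recombine the two strands, but every allele column must
        # come from the winning individual's strands
        strands = np.stack([pop.haplotypes[8], pop.haplotypes[9]])
        for row in child.haplotypes:
            assert ((row == strands[0]) | (row == strands[1])).all()

    def test_population_size_constant(self):
        pop, m = _population_at_freq(20, 0.3, L=5, seed=2)
        child = simulate_generation(pop, np.ones(20), m,
                                    np.random.default_rng(0))
        assert child.haplotypes.shape == pop.haplotypes.shape


class TestRunReplicate:
    def test_bit_identical_determinism(self):
        spec = ps.ScenarioSpec(model="sweep", N=50, n_loci=10, s=0.08,
                               generations=30, root_seed=5, n_replicates=1)
        a = ps.run_replicate(spec, seed=[5, 0])
        b = ps.run_replicate(spec, seed=[5, 0])
        assert np.array_equal(a.freq, b.freq)
        assert np.array_equal(a.fitness_median, b.fitness_median)
        assert np.array_equal(a.final_population.haplotypes,
                              b.final_population.haplotypes)
        c = ps.run_replicate(spec, seed=[5, 1])
        assert not np.array_equal(a.freq, c.freq)

    def test_neutral_frequencies_unbiased(self):
        spec = ps.ScenarioSpec(model="neutral", N=100, n_loci=20,
                               generations=20, root_seed=3, n_replicates=1)
        finals = np.concatenate(
            [ps.run_replicate(spec, seed=[3, r]).freq[-1] for r in range(30)])
        # martingale: mean stays at the founder frequency
        p0 = spec.build_founders().allele_frequencies().mean()
        se = np.sqrt(p0 * (1 - p0) * (20 / 200) / len(finals))
        assert abs(finals.mean() - p0) < 4 * se

    def test_recording_grid(self):
        spec = ps.ScenarioSpec(model="neutral", N=20, n_loci=5,
                               generations=40, record_interval=20,
                               root_seed=1, n_replicates=1)
        res = ps.run_replicate(spec, seed=1)
        assert res.generations.tolist() == [0, 20, 40]
        assert res.freq.shape == (3, 5)
        assert res.load_hist.shape == (3, 6)
        assert np.allclose(res.load_hist.sum(axis=1), 1.0)

    def test_sweep_matches_deterministic_recursion(self):
        # unlinked single locus, N = 9,000: E[p_t] follows
        # p' = p (1 + s (p + (1-p) h)) / (1 + s p) with h = 0.5
        s, p0, gens, reps = 0.08, 0.05, 20, 12
        spec = ps.ScenarioSpec(model="sweep", N=9000, n_loci=1, s=s,
                               generations=gens, record_interval=gens,
                               n_haplotypes=20, root_seed=2, n_replicates=1)
        pool = spec.build_founders()
        # force exact founder frequency p0 on the single locus
        pool.alleles[:, 0] = 0
        pool.alleles[: int(p0 * 20), 0] = 1
        finals = [
            ps.run_replicate(spec, seed=[2, r], pool=pool,
                             keep_final_population=False).freq[-1, 0]
            for r in range(reps)
        ]
        p = p0
        for _ in range(gens):
            p = p * (1 + s * (p + (1 - p) * 0.5)) / (1 + s * p)
        se = np.sqrt(np.var(finals, ddof=1) / reps) + 1e-4
        assert np.mean(finals) == pytest.approx(p, abs=4 * se)

    def test_trait_phenotype_plateaus_at_optimum(self):
        spec = ps.ScenarioSpec(model="trait_optimum", N=450, n_loci=100,
                               effect_size=0.04, root_seed=9, n_replicates=1)
        res = ps.run_replicate(spec, seed=[9, 0], keep_final_population=False)
        norm = ps.normalized_phenotype(res)
        # non-decreasing until first reaching the optimum, then fluctuates
        # within 2 fitness-sd of it
        reach = np.flatnonzero(norm >= spec.optimum_distance - spec.effect_size)
        assert len(reach) > 0
        first = reach[0]
        assert (np.diff(norm[: first + 1]) > -0.05).all()
        assert (np.abs(norm[first:] - spec.optimum_distance)
                < 2 * spec.fitness_sd).all()
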