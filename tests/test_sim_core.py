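"""Monte Carlo engine: unit behaviour, invariants, and equivalence with a
plain-Python reference implementation."""

import numpy as np
import pytest

from hotspotsim import (
    ExtinctionError,
    Haplotype,
    Population,
    RunOptions,
    SimParams,
    allowed_positions,
    crossover,
    draw_event_count,
    homozygous_defect_count,
    init_population,
    make_gamete,
    make_offspring,
    mc_step,
    mutate_genes,
    run,
    selection,
    survival_probability,
    toggle_hotspot,
)
from hotspotsim.params import ConfigError

from conftest import make_hap, make_ind
from reference import ref_step


class TestInitPopulation:
    def test_founders_are_perfect_with_one_double_hotspot(self, rng):
        params = SimParams(N=40, L=64, seed=1)
        pop = init_population(params, rng)
        assert pop.N == 40
        assert not pop.genes.any()
        for i in range(pop.N):
            h1, h2 = pop.hotspots[i, 0], pop.hotspots[i, 1]
            assert h1.sum() == 1 and h2.sum() == 1
            assert np.array_equal(h1, h2)  # same site on both haplotypes

    def test_same_seed_identical_population(self):
        params = SimParams(N=30, L=32, seed=9)
        a = init_population(params, np.random.default_rng(42))
        b = init_population(params, np.random.default_rng(42))
        assert np.array_equal(a.hotspots, b.hotspots)

    def test_invalid_params_rejected(self):
        with pytest.raises(ConfigError):
            SimParams(N=1)
        with pytest.raises(ConfigError):
            SimParams(x=0.0)
        with pytest.raises(ConfigError):
            SimParams(M=-1)


class TestHomozygousDefects:
    def test_hand_examples(self):
        assert homozygous_defect_count(make_ind("000", "00", "000", "00")) == 0
        assert homozygous_defect_count(make_ind("110", "00", "011", "00")) == 1

    def test_matches_per_locus_loop(self, rng):
        for _ in range(20):
            L = int(rng.integers(2, 40))
            g1 = rng.integers(0, 2, L).astype(np.uint8)
            g2 = rng.integers(0, 2, L).astype(np.uint8)
            ind = make_ind("".join(map(str, g1)), "0" * (L - 1),
                           "".join(map(str, g2)), "0" * (L - 1))
            brute = sum(1 for i in range(L) if g1[i] == 1 and g2[i] == 1)
            assert homozygous_defect_count(ind) == brute


class TestSurvivalProbability:
    def test_values(self):
        p = SimParams(x=0.85)
        assert survival_probability(0, p) == pytest.approx(0.85)
        assert survival_probability(2, p) == pytest.approx(0.614125)

    def test_no_selection_limit(self):
        p = SimParams(x=1.0)
        assert all(survival_probability(d, p) == 1.0 for d in range(5))

    def test_strictly_decreasing_in_d(self):
        p = SimParams(x=0.85)
        probs = [survival_probability(d, p) for d in range(20)]
        assert all(a > b for a, b in zip(probs, probs[1:]))

    def test_neutral_mode_ignores_genotype(self):
        p = SimParams(x=0.85, neutral_mode=True)
        assert survival_probability(0, p) == survival_probability(50, p) == 0.85


class TestSelection:
    def test_certain_survival(self, rng):
        params = SimParams(N=50, L=16, x=1.0)
        pop = init_population(params, rng)
        survivors, n_deaths = selection(pop, params, rng)
        assert n_deaths == 0 and len(survivors) == 50

    def test_perfect_genomes_die_at_rate_1_minus_x(self):
        # Monte Carlo over 1e5 independent survival tosses
        params = SimParams(N=100_000, L=2, x=0.85)
        rng = np.random.default_rng(0)
        pop = init_population(params, rng)
        _, n_deaths = selection(pop, params, rng)
        rate = n_deaths / params.N
        se = np.sqrt(0.15 * 0.85 / params.N)
        assert rate == pytest.approx(0.15, abs=4 * se)

    def test_mixed_population_death_rate_matches_mean_survival(self):
        params = SimParams(N=30_000, L=8, x=0.8)
        rng = np.random.default_rng(1)
        pop = init_population(params, rng)
        # half the population homozygous defective at 2 loci
        pop.genes[: params.N // 2, :, :2] = 1
        d = pop.homozygous_defects()
        expected = 1 - np.mean(params.x ** (d + 1))
        _, n_deaths = selection(pop, params, rng)
        assert n_deaths / params.N == pytest.approx(expected, abs=0.01)

    def test_total_extinction_raises(self, rng):
        params = SimParams(N=2, L=2048, x=0.05)
        pop = init_population(params, rng)
        pop.genes[:] = 1  # survival ~ 0.05**2049
        with pytest.raises(ExtinctionError):
            for _ in range(100):
                selection(pop, params, rng)


class TestDrawEventCount:
    def test_zero_mean(self, rng):
        assert all(draw_event_count(0.0, rng) == 0 for _ in range(100))

    @pytest.mark.parametrize("mean", [0.3, 1.0, 2.5])
    def test_empirical_mean_and_support(self, mean):
        rng = np.random.default_rng(7)
        draws = np.array([draw_event_count(mean, rng) for _ in range(100_000)])
        se = draws.std() / np.sqrt(draws.size)
        assert draws.mean() == pytest.approx(mean, abs=3 * se)
        assert draws.min() >= 0 and draws.max() <= int(np.ceil(2 * mean))

    def test_negative_mean_rejected(self, rng):
        with pytest.raises(ValueError):
            draw_event_count(-1, rng)


class TestMutateGenes:
    def test_zero_mutations_identity(self, rng, small_params):
        hap = make_hap("0101", "000")
        out = mutate_genes(hap, 0, small_params, rng)
        assert np.array_equal(out.genes, hap.genes)

    def test_flip_both_directions_with_reversions(self, small_params):
        hap = make_hap("0000", "000")
        rng = np.random.default_rng(0)
        out = mutate_genes(hap, 50, small_params, rng)
        assert out.genes.sum() > 0  # some flips landed

    def test_reversions_off_cannot_clear_defects(self, rng):
        params = SimParams(N=2, L=4, gene_reversions=False)
        hap = make_hap("1111", "000")
        out = mutate_genes(hap, 200, params, rng)
        assert np.array_equal(out.genes, hap.genes)

    def test_reversions_off_still_adds_defects(self, rng):
        params = SimParams(N=2, L=8, gene_reversions=False)
        out = mutate_genes(make_hap("0" * 8, "0" * 7), 100, params, rng)
        assert out.genes.all()


class TestAllowedPositions:
    def test_double_hotspot_intersection(self, small_params):
        a = make_hap("0000", "101")
        b = make_hap("0000", "110")
        assert allowed_positions(a, b, small_params).tolist() == [0]

    def test_single_mode_uses_union(self):
        params = SimParams(single_hotspot_recomb=True)
        a = make_hap("0000", "000")
        b = make_hap("0000", "111")
        assert allowed_positions(a, b, params).tolist() == [0, 1, 2]
        default = SimParams()
        assert allowed_positions(a, b, default).size == 0

    def test_matches_brute_force_sets(self, rng, small_params):
        for _ in range(30):
            h1 = rng.integers(0, 2, 15).astype(np.uint8)
            h2 = rng.integers(0, 2, 15).astype(np.uint8)
            a = Haplotype(np.zeros(16, np.uint8), h1)
            b = Haplotype(np.zeros(16, np.uint8), h2)
            brute = {s for s in range(15) if h1[s] and h2[s]}
            assert set(allowed_positions(a, b, small_params).tolist()) == brute


class TestCrossover:
    def test_reciprocal_exchange(self):
        a = make_hap("1100", "000")
        b = make_hap("0011", "000")
        pa, pb = crossover(a, b, 1)  # between loci 1 and 2 (0-based)
        assert pa.genes.tolist() == [1, 1, 1, 1]
        assert pb.genes.tolist() == [0, 0, 0, 0]

    def test_identical_haplotypes_unchanged(self):
        a = make_hap("1010", "110")
        pa, pb = crossover(a, a.copy(), 2)
        assert np.array_equal(pa.genes, a.genes)
        assert np.array_equal(pb.hotspots, a.hotspots)

    def test_site_hotspot_travels_left(self):
        a = make_hap("0000", "100")
        b = make_hap("0000", "001")
        pa, pb = crossover(a, b, 0)
        # site 0 bit stays with the left segment of each product
        assert pa.hotspots.tolist() == [1, 0, 1]
        assert pb.hotspots.tolist() == [0, 0, 0]

    def test_per_locus_bit_conservation(self, rng):
        for _ in range(30):
            L = int(rng.integers(2, 30))
            a = Haplotype(rng.integers(0, 2, L).astype(np.uint8),
                          rng.integers(0, 2, L - 1).astype(np.uint8))
            b = Haplotype(rng.integers(0, 2, L).astype(np.uint8),
                          rng.integers(0, 2, L - 1).astype(np.uint8))
            site = int(rng.integers(0, L - 1))
            pa, pb = crossover(a, b, site)
            assert np.array_equal(pa.genes + pb.genes, a.genes + b.genes)
            assert np.array_equal(pa.hotspots + pb.hotspots,
                                  a.hotspots + b.hotspots)

    def test_out_of_range_site(self):
        a = make_hap("0000", "000")
        with pytest.raises(ValueError):
            crossover(a, a.copy(), 3)
        with pytest.raises(ValueError):
            crossover(a, a.copy(), -1)


class TestToggleHotspot:
    def test_creates_exactly_one_on_empty(self, rng):
        params = SimParams(N=2, L=8)
        out = toggle_hotspot(make_hap("0" * 8, "0" * 7), params, rng)
        assert out.hotspots.sum() == 1

    def test_disabled_is_identity(self, rng):
        params = SimParams(N=2, L=8, hotspot_mutation=False)
        hap = make_hap("0" * 8, "1010101")
        out = toggle_hotspot(hap, params, rng)
        assert np.array_equal(out.hotspots, hap.hotspots)

    def test_site_choice_uniform(self):
        params = SimParams(N=2, L=9)
        rng = np.random.default_rng(3)
        counts = np.zeros(8)
        hap = make_hap("0" * 9, "0" * 8)
        for _ in range(40_000):
            out = toggle_hotspot(hap, params, rng)
            counts[np.nonzero(out.hotspots)[0][0]] += 1
        from scipy.stats import chisquare
        assert chisquare(counts).pvalue > 1e-4


class TestMakeGamete:
    def test_inert_steps_leave_one_toggled_parent_copy(self, rng):
        params = SimParams(N=2, L=16, M=0, C=0)
        parent = make_ind("0011001100110011", "000000011111111",
                          "1100110011001100", "111111100000000")
        for _ in range(20):
            gam = make_gamete(parent, params, rng)
            src = [h for h in (parent.hap1, parent.hap2)
                   if np.array_equal(gam.genes, h.genes)]
            assert len(src) == 1
            assert (gam.hotspots != src[0].hotspots).sum() == 1

    def test_single_allowed_site_recombinant(self):
        params = SimParams(N=2, L=8, M=0, C=10, hotspot_mutation=False)
        # one double hotspot at site 3; C=10 forces k>=1 crossovers, all at
        # site 3 (without replacement: only the first happens)
        parent = make_ind("00001111", "0001000", "11110000", "0001000")
        rng = np.random.default_rng(5)
        seen = set()
        for _ in range(200):
            gam = make_gamete(parent, params, rng)
            seen.add("".join(map(str, gam.genes)))
        # crossover (k >= 1, overwhelmingly likely per gamete) recombines at
        # site 3 only; rare k=0 gametes pass a parental string through
        assert {"00000000", "11111111"} <= seen
        assert seen <= {"00000000", "11111111", "00001111", "11110000"}

    def test_crossover_sites_uniform_over_allowed(self):
        params = SimParams(N=2, L=9, M=0, C=0.5, hotspot_mutation=False)
        mask = "10101010"
        parent = make_ind("000000000", mask, "111111111", mask)
        allowed = [0, 2, 4, 6]
        rng = np.random.default_rng(11)
        counts = {s: 0 for s in allowed}
        n_single = 0
        for _ in range(40_000):
            gam = make_gamete(parent, params, rng)
            flips = np.nonzero(np.diff(gam.genes.astype(int)))[0]
            if flips.size == 1:  # exactly one crossover happened
                counts[int(flips[0])] += 1
                n_single += 1
        from scipy.stats import chisquare
        assert set(counts) == set(allowed)
        assert chisquare(list(counts.values())).pvalue > 1e-4

    def test_bootstrap_creates_site_when_none_allowed(self):
        params = SimParams(N=2, L=8, M=0, C=10, hotspot_mutation=False,
                           bootstrap_hotspots=True)
        parent = make_ind("00000000", "0000000", "11111111", "0000000")
        rng = np.random.default_rng(2)
        recombinants = 0
        for _ in range(200):
            gam = make_gamete(parent, params, rng)
            s = gam.genes.sum()
            if s not in (0, 8):
                recombinants += 1
                assert gam.hotspots.sum() == 1  # the bootstrap site
        assert recombinants > 0

    def test_no_bootstrap_no_recombination(self):
        params = SimParams(N=2, L=8, M=0, C=10, hotspot_mutation=False,
                           bootstrap_hotspots=False)
        parent = make_ind("00000000", "0000000", "11111111", "0000000")
        rng = np.random.default_rng(2)
        for _ in range(100):
            gam = make_gamete(parent, params, rng)
            assert gam.genes.sum() in (0, 8)


class TestMakeOffspring:
    def test_perfect_parents_give_perfect_child(self, rng):
        params = SimParams(N=4, L=32, M=0)
        pop = init_population(params, rng)
        child = make_offspring(pop[0], pop[1], params, rng)
        assert child.hap1.genes.sum() == 0 and child.hap2.genes.sum() == 0

    def test_hotspot_count_changes_by_at_most_one_per_haplotype(self, rng):
        params = SimParams(N=4, L=32, M=0, C=0)
        pop = init_population(params, rng)
        child = make_offspring(pop[0], pop[1], params, rng)
        for hap, parent in ((child.hap1, pop[0]), (child.hap2, pop[1])):
            parental = {parent.hap1.hotspots.sum(), parent.hap2.hotspots.sum()}
            assert any(abs(hap.hotspots.sum() - c) == 1 for c in parental)


class TestMcStepAndRun:
    def test_no_deaths_leaves_population_untouched(self, rng):
        params = SimParams(N=20, L=16, x=1.0)
        pop = init_population(params, rng)
        before = pop.genes.copy(), pop.hotspots.copy()
        pop, nd = mc_step(pop, params, rng)
        assert nd == 0
        assert np.array_equal(pop.genes, before[0])
        assert np.array_equal(pop.hotspots, before[1])
        assert pop.step == 1

    def test_population_size_constant(self, rng):
        params = SimParams(N=30, L=16, x=0.7)
        pop = init_population(params, rng)
        for _ in range(50):
            pop, nd = mc_step(pop, params, rng)
            assert pop.N == 30 and 0 <= nd <= 30

    @pytest.mark.parametrize("viable", [False, True])
    def test_engine_matches_reference_implementation(self, viable):
        """The compiled kernel and the literal plain-Python reference are
        the same algorithm, bit for bit, under both replacement rules."""
        params = SimParams(N=50, L=24, x=0.88, seed=3, viable_births=viable)
        rng_a = np.random.default_rng(77)
        rng_b = np.random.default_rng(77)
        pop = init_population(params, rng_a)
        ref_pop = init_population(params, rng_b)
        genes, hots = ref_pop.genes, ref_pop.hotspots
        for t in range(120):
            pop, nd = mc_step(pop, params, rng_a)
            nd_ref = ref_step(genes, hots, params, rng_b)
            assert nd == nd_ref
            assert np.array_equal(pop.genes, genes)
            assert np.array_equal(pop.hotspots, hots)

    @pytest.mark.parametrize("L", [24, 64, 65, 127])
    def test_packed_run_matches_byte_kernel(self, L):
        """run() executes on the bit-packed engine; it must visit exactly
        the same states as stepping the byte kernel with the same seed."""
        params = SimParams(N=25, L=L, x=0.82, n_steps=80, seed=31)
        res = run(params)
        rng = np.random.default_rng(31)
        pop = init_population(params, rng)
        for _ in range(80):
            pop, _ = mc_step(pop, params, rng)
        assert np.array_equal(res.population.genes, pop.genes)
        assert np.array_equal(res.population.hotspots, pop.hotspots)

    def test_run_zero_steps_records_initial_state(self):
        params = SimParams(N=10, L=8, n_steps=0, seed=1)
        res = run(params)
        assert len(res.trajectory) == 1
        assert res.trajectory.step.iloc[0] == 0

    def test_run_deterministic_under_seed(self):
        params = SimParams(N=30, L=32, x=0.8, n_steps=200, seed=13)
        r1 = run(params, RunOptions(thinning=20))
        r2 = run(params, RunOptions(thinning=20))
        assert r1.trajectory.equals(r2.trajectory)
        assert np.array_equal(r1.population.genes, r2.population.genes)

    def test_run_snapshot_and_resume_branches(self):
        params = SimParams(N=20, L=16, x=0.8, n_steps=50, seed=4)
        res = run(params, RunOptions(snapshot_steps=(30,)))
        assert 30 in res.snapshots
        snap = res.snapshots[30]
        assert snap.step == 30
        d1 = run(params.replace(seed=100, n_steps=20), init_pop=snap)
        d2 = run(params.replace(seed=200, n_steps=20), init_pop=snap)
        assert d1.population.step == d2.population.step == 50
        assert not np.array_equal(d1.population.hotspots,
                                  d2.population.hotspots)

    def test_extinction_reports_partial_trajectory(self):
        params = SimParams(N=4, L=256, x=0.02, M=50, n_steps=2000, seed=8,
                           viable_births=False, bootstrap_hotspots=True)
        res = run(params, RunOptions(thinning=1))
        assert res.status == "extinct"
        assert len(res.trajectory) >= 1

    def test_variant_flag_switch_freezes_hotspot_patterns(self):
        # after switching hotspot_mutation off (with C=0) the set of
        # distinct hotspot patterns can only shrink, never gain members
        params = SimParams(N=40, L=16, x=0.8, C=0, n_steps=120, seed=21)
        opts = RunOptions(thinning=10, variant_switch_step=20,
                          switch_flags=(("hotspot_mutation", False),))
        res = run(params, opts)
        assert res.status == "ok"
        final_patterns = {h.tobytes()
                          for ind in res.population.hotspots
                          for h in ind}
        # rerun to capture the pattern set at the switch point
        res2 = run(params, RunOptions(thinning=10, variant_switch_step=20,
                                      switch_flags=(("hotspot_mutation",
                                                     False),),
                                      snapshot_steps=(20,)))
        at_switch = {h.tobytes()
                     for ind in res2.snapshots[20].hotspots
                     for h in ind}
        assert final_patterns <= at_switch


class TestNeutralEquilibrium:
    def test_gene_and_hotspot_occupancy_converge_to_half(self):
        """Neutral turnover with reversible flips drives both the defective
        -allele fraction and hotspot occupancy to the symmetric 0.5 point."""
        params = SimParams(N=200, L=256, x=0.85, neutral_mode=True,
                           n_steps=30_000, seed=17)
        res = run(params, RunOptions(thinning=200))
        tail = res.trajectory[res.trajectory.step > 20_000]
        gene_frac = tail.frac_defective_alleles.mean()
        hot_frac = ((tail.mean_double * 2 + tail.mean_single).mean()
                    / (2 * (params.L - 1)))
        assert gene_frac == pytest.approx(0.5, abs=0.02)
        assert hot_frac == pytest.approx(0.5, abs=0.02)
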