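"""Forward-engine behaviour: conservation laws, neutral expectations,
selection and sweepstakes dynamics, demography, sampling and determinism."""

import numpy as np
import pytest

from mmcscan import (DemographyModel, SelectionModel, SimulationParams,
                     basic_stats)
from mmcscan.engine import (Population, apply_bottleneck, burn_in,
                            psi_generation, run_psi_phase, run_sweep,
                            sample_haplotypes, simulate_observed,
                            simulate_training_replicate, wf_generation)

EQ = DemographyModel()


def small_params(N=50, mu=0.0, L=1000, n_sample=10, seed=0, rho=0.0):
    return SimulationParams(N=N, mu=mu, rho=rho, L=L, n_sample=n_sample,
                            seed=seed)


class TestReproductionBasics:
    def test_haplotype_count_conserved(self):
        pop = Population(small_params(N=30, mu=1e-5), seed=1)
        for _ in range(5):
            wf_generation(pop)
            assert pop.matrix_view().shape[0] == 60

    def test_burn_in_counter_and_monomorphic_without_mutation(self):
        pop = Population(small_params(N=20, mu=0.0), seed=2)
        burn_in(pop)
        assert pop.generation == 200
        assert pop.n_sites == 0

    def test_neutral_drift_is_martingale(self):
        # mean next-generation frequency of a p0=0.5 allele stays 0.5
        pop = Population(small_params(N=50, mu=0.0), seed=3)
        col = pop.add_mutation(position=10, haplotype=0, track=True)
        pop.matrix_view()[:50, col] = 1  # p0 = 0.5
        pop._zero_tails()
        snap = pop.snapshot()
        freqs = []
        for _ in range(3000):
            pop.restore(snap)
            wf_generation(pop)
            freqs.append(pop.tracked_frequency())
        mean = np.mean(freqs)
        se = np.std(freqs) / np.sqrt(len(freqs))
        assert abs(mean - 0.5) < 4 * se

    def test_neutral_fixation_probability_one_over_2n(self):
        # diffusion prediction for a new neutral mutation
        N = 50
        pop = Population(small_params(N=N, mu=0.0), seed=4)
        snap = pop.snapshot()
        n_rep = 20_000
        fixed = 0
        for _ in range(n_rep):
            pop.restore(snap)
            pop.add_mutation(position=10, track=True)
            _, status = pop._epoch(10_000_000, stop_on_absorb=True)
            fixed += status == 1
        p = 1 / (2 * N)
        se = np.sqrt(p * (1 - p) / n_rep)
        assert abs(fixed / n_rep - p) < 3.5 * se


class TestSelection:
    def test_fixed_beneficial_stays_fixed(self):
        pop = Population(small_params(N=30, mu=0.0), seed=5)
        col = pop.add_mutation(position=10, haplotype=0, track=True)
        pop.matrix_view()[:, col] = 1
        pop._zero_tails()
        sel = SelectionModel(s=0.5, position=10)
        wf_generation(pop, selection=sel)
        assert pop.tracked_frequency() == 1.0

    def test_sweep_ends_fixed_and_stronger_is_faster(self):
        N = 100
        times = {}
        for two_ns in (100, 500):
            sel = SelectionModel.from_2ns(two_ns, N, position=500)
            lengths = []
            for r in range(50):
                pop = Population(small_params(N=N, mu=0.0), seed=600 + r)
                g0 = pop.generation
                run_sweep(pop, selection=sel)
                lengths.append(pop.generation - g0)
            times[two_ns] = np.mean(lengths)
        assert times[500] < times[100]

    def test_sweep_reduces_central_diversity(self):
        # hitchhiking: pi in the sweep-centered window below the
        # chromosome-wide median window pi in >=90% of replicates
        params = SimulationParams(N=200, mu=1e-6, rho=2e-6, L=50_000,
                                  n_sample=20, seed=0)
        sel = SelectionModel.from_2ns(250, params.N)
        wins = [(k * 5000, (k + 1) * 5000) for k in range(10)]
        hits = 0
        n_rep = 20
        for r in range(n_rep):
            m = simulate_observed(params, EQ, sel, seed=900 + r)
            pis = []
            for a, b in wins:
                sub = m.matrix[:, (m.positions >= a) & (m.positions < b)]
                pis.append(basic_stats(sub)[1])
            center = pis[5]  # window [25000, 30000) contains the sweep site
            hits += center < np.median(pis)
        assert hits >= 0.9 * n_rep


class TestPsi:
    def _pop_with_m2(self, N, carriers, seed):
        pop = Population(small_params(N=N, mu=0.0), seed=seed)
        col = pop.add_mutation(position=10, haplotype=0, track=True)
        pop.matrix_view()[:carriers, col] = 1
        pop._zero_tails()
        return pop

    def test_sweepstakes_parent_fills_exact_slot_count(self):
        # N=100, psi=0.08 -> round(2N*psi)=16 forced slots
        N, psi = 100, 0.08
        pop = self._pop_with_m2(N, carriers=2, seed=6)  # one carrier diploid
        psi_generation(pop, psi=psi)
        parents = pop.last_parents()
        assert (parents[:16] == 0).all()  # individual 0 is the only carrier

    def test_zero_slot_psi_equals_wf(self):
        # round(2N*psi)=0: no forced slots, plain WF reproduction
        N, psi = 50, 0.004
        assert round(2 * N * psi) == 0
        pop = self._pop_with_m2(N, carriers=10, seed=7)
        psi_generation(pop, psi=psi)
        assert pop.matrix_view().shape[0] == 2 * N

    def test_psi_requires_segregating_m2(self):
        pop = Population(small_params(N=20, mu=0.0), seed=8)
        with pytest.raises(ValueError):
            psi_generation(pop, psi=0.05)
        col = pop.add_mutation(position=5, haplotype=0, track=True)
        pop.matrix_view()[:, col] = 1
        pop._zero_tails()
        with pytest.raises(ValueError):
            psi_generation(pop, psi=0.05)

    def test_delta_p_positive_at_p_point_one(self):
        N = 100
        pop = self._pop_with_m2(N, carriers=20, seed=9)  # p = 0.1
        snap = pop.snapshot()
        deltas = []
        for _ in range(10_000):
            pop.restore(snap)
            psi_generation(pop, psi=0.08)
            deltas.append(pop.tracked_frequency() - 0.1)
        mean = np.mean(deltas)
        assert mean > 3 * np.std(deltas) / np.sqrt(len(deltas))

    def test_phase_conditions_on_fixation(self):
        pop = Population(small_params(N=50, mu=0.0), seed=10)
        pop2, outcome, length = run_psi_phase(pop, psi=0.3)
        assert outcome == "fixed"
        assert length > 0
        assert pop2.tracked == -1

    def test_phase_length_decreases_with_psi(self):
        N = 100
        means = {}
        for psi in (0.02, 0.08):
            lengths = []
            for r in range(200):
                pop = Population(small_params(N=N, mu=0.0), seed=2000 + r)
                _, _, length = run_psi_phase(pop, psi=psi)
                lengths.append(length)
            means[psi] = np.mean(lengths)
        assert means[0.08] < means[0.02]


class TestBottleneck:
    def test_equilibrium_beta_is_noop_guard(self):
        pop = Population(small_params(N=30, mu=0.0), seed=11)
        with pytest.raises(ValueError):
            apply_bottleneck(pop, demog=DemographyModel())

    def test_sizes_through_bottleneck(self):
        params = small_params(N=50, mu=1e-6, L=5000)
        pop = Population(params, seed=12)
        burn_in(pop)
        d = DemographyModel(kind="bottleneck", beta=0.1, duration=5)
        apply_bottleneck(pop, demog=d)
        assert pop.n_hap == 100  # recovered to 2N

    def test_post_recovery_tajimas_d_negative(self):
        # severe contraction + instantaneous recovery leaves an excess of
        # rare variants: mean Tajima's D < 0 shortly after recovery
        from mmcscan import tajimas_d
        params = SimulationParams(N=100, mu=5e-7, rho=0.0, L=10_000,
                                  n_sample=20, seed=0)
        d = DemographyModel(kind="bottleneck", beta=0.05, duration=10)
        vals = []
        for r in range(200):
            pop = Population(params, seed=3000 + r)
            burn_in(pop)
            apply_bottleneck(pop, demog=d)
            pop._epoch(50)
            m = sample_haplotypes(pop, 20)
            if m.S:
                vals.append(tajimas_d(m))
        mean = np.mean(vals)
        assert mean < 0
        assert mean < -2 * np.std(vals) / np.sqrt(len(vals))


class TestSampling:
    def test_monomorphic_population_gives_empty_matrix(self):
        pop = Population(small_params(N=20, mu=0.0), seed=13)
        m = sample_haplotypes(pop, 10)
        assert m.S == 0

    def test_census_sample_matches_population_frequencies(self):
        params = small_params(N=30, mu=1e-5, L=1000)
        pop = Population(params, seed=14)
        burn_in(pop)
        pop.compact()
        m = sample_haplotypes(pop, 2 * pop.N)
        view = pop.matrix_view()
        pop_freqs = sorted(view.sum(axis=0).tolist())
        samp_freqs = sorted(m.matrix.sum(axis=0).tolist())
        assert pop_freqs == samp_freqs

    def test_derived_counts_strictly_polymorphic(self):
        params = small_params(N=50, mu=1e-5, L=2000)
        pop = Population(params, seed=15)
        burn_in(pop)
        m = sample_haplotypes(pop, 12)
        c = m.matrix.sum(axis=0)
        assert ((c >= 1) & (c <= 11)).all()
        assert (np.diff(m.positions) > 0).all()

    def test_span_restriction(self):
        params = small_params(N=50, mu=1e-5, L=2000)
        pop = Population(params, seed=16)
        burn_in(pop)
        m = sample_haplotypes(pop, 12, span=(500, 1000))
        assert ((m.positions >= 500) & (m.positions < 1000)).all()


class TestScenarios:
    def test_determinism_bit_identical(self):
        params = small_params(N=60, mu=1e-6, L=5000, rho=1e-6)
        a = simulate_observed(params, EQ, None, seed=77)
        b = simulate_observed(params, EQ, None, seed=77)
        c = simulate_observed(params, EQ, None, seed=78)
        assert np.array_equal(a.matrix, b.matrix)
        assert np.array_equal(a.positions, b.positions)
        assert not (a.S == c.S and np.array_equal(a.matrix, c.matrix)
                    and np.array_equal(a.positions, c.positions))

    def test_sweep_site_absent_from_output(self):
        params = SimulationParams(N=100, mu=2e-7, rho=0.0, L=10_000,
                                  n_sample=10, seed=0)
        sel = SelectionModel.from_2ns(500, params.N)
        m = simulate_observed(params, EQ, sel, seed=21)
        assert 5000 not in set(m.positions.tolist())

    def test_tau_zero_samples_at_recovery(self):
        d = DemographyModel(kind="bottleneck", beta=0.1, duration=5,
                            tau_max=0)
        params = small_params(N=40, mu=1e-6, L=2000)
        m = simulate_observed(params, d, None, seed=22)
        assert m.matrix.shape[0] == params.n_sample

    def test_training_replicate_contract(self):
        from mmcscan import PsiModel
        params = small_params(N=40, mu=1e-6, L=2000, n_sample=10)
        prior = PsiModel(prior_low=0.004, prior_high=0.08)
        v, psi = simulate_training_replicate("kingman", EQ, params,
                                             prior, seed=23)
        assert v.shape == (11,) and psi is None
        v, psi = simulate_training_replicate("mmc", EQ, params, prior,
                                             seed=24)
        assert v.shape == (11,)
        assert 0.004 <= psi <= 0.08

    def test_psi_draws_stay_in_prior(self):
        from mmcscan import PsiModel
        params = small_params(N=30, mu=1e-6, L=1000, n_sample=10)
        prior = PsiModel(prior_low=0.004, prior_high=0.08)
        for r in range(20):
            _, psi = simulate_training_replicate("mmc", EQ, params, prior,
                                                 seed=400 + r)
            assert 0.004 <= psi <= 0.08


class TestNeutralCoalescentOracle:
    def test_s_and_pi_match_msprime(self):
        """Neutral-limit equivalence: engine (S, pi) vs an independent
        coalescent simulator at equal 4N*mu*L and 4N*rho*L."""
        import msprime
        from scipy import stats as sps

        N, L, mu = 100, 10_000, 2.5e-7
        rho = mu / 1.2
        params = SimulationParams(N=N, mu=mu, rho=rho, L=L, n_sample=15,
                                  seed=0)
        ours_S, ours_pi = [], []
        for r in range(150):
            m = simulate_observed(params, EQ, None, seed=5000 + r)
            ours_S.append(m.S)
            ours_pi.append(basic_stats(m.matrix)[1])
        ms_S, ms_pi = [], []
        for r in range(300):
            ts = msprime.sim_ancestry(
                samples=params.n_sample, ploidy=1, population_size=2 * N,
                sequence_length=L, recombination_rate=rho,
                random_seed=6000 + r)
            ts = msprime.sim_mutations(ts, rate=mu, random_seed=7000 + r,
                                       discrete_genome=False)
            ms_S.append(ts.num_sites)
            ms_pi.append(float(ts.diversity(span_normalise=False,
                                            mode="site")) )
        assert sps.ks_2samp(ours_S, ms_S).pvalue > 0.005
        assert sps.ks_2samp(ours_pi, ms_pi).pvalue > 0.005
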