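"""Synthetic-study generator: distributional contracts and determinism."""

import numpy as np
import pytest

from straysink.containers import MISSING
from straysink.simulate import (
    SimulationConfig,
    draw_base_frequencies,
    generate_study,
    inject_contamination,
    inject_missingness_and_strays,
    sample_genotype_matrix,
    simulate_microsatellites,
)
from straysink.sourcesink import sink_frequency_forecast


class TestBaseFrequencies:
    def test_point_mass_law_is_degenerate(self, rng):
        assert np.array_equal(draw_base_frequencies(3, (0.5, 0.5), rng), [0.5] * 3)

    def test_uniform_law_mean_and_bounds(self, rng):
        draws = draw_base_frequencies(100_000, (0.05, 0.95), rng)
        assert abs(draws.mean() - 0.50) < 0.01
        assert draws.min() >= 0.05 and draws.max() <= 0.95

    @pytest.mark.parametrize("bad", [(0.0, 0.95), (0.05, 1.0), (-0.1, 0.5)])
    def test_bounds_outside_open_interval_rejected(self, rng, bad):
        with pytest.raises(ValueError):
            draw_base_frequencies(5, bad, rng)

    def test_nonpositive_locus_count_rejected(self, rng):
        with pytest.raises(ValueError):
            draw_base_frequencies(0, (0.05, 0.95), rng)


class TestGenotypeSampling:
    def test_fixed_locus_is_monomorphic(self, rng):
        g = sample_genotype_matrix(np.array([1.0, 0.3]), 20, rng)
        assert np.all(g[:, 0] == 2)

    def test_heterozygote_fraction_at_half(self, rng):
        g = sample_genotype_matrix(np.array([0.5]), 10_000, rng)
        assert abs((g == 1).mean() - 0.500) < 0.015

    def test_shape(self, rng):
        assert sample_genotype_matrix(np.full(3, 0.4), 7, rng).shape == (7, 3)

    def test_frequency_out_of_range_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_genotype_matrix(np.array([1.2]), 5, rng)


class TestContamination:
    def test_opposite_homozygotes_mix_to_heterozygote(self, rng):
        # focal AA pooled with donor aa shows both alleles
        matrix = np.array([[2], [0]], dtype=np.int8)
        found = False
        for seed in range(20):
            r = np.random.default_rng(seed)
            apparent, flags = inject_contamination(matrix, 1.0, r)
            if flags[0]:
                assert apparent[0, 0] == 1
                found = True
        assert found

    def test_identical_homozygotes_stay_homozygous(self, rng):
        matrix = np.full((5, 4), 2, dtype=np.int8)
        apparent, flags = inject_contamination(matrix, 1.0, rng)
        assert np.all(apparent == 2) and flags.all()

    def test_apparent_heterozygosity_matches_four_allele_enumeration(self, rng):
        # 14 of the 16 equiprobable four-allele draws at p=0.5 are mixed
        g = sample_genotype_matrix(np.full(5, 0.5), 10_000, rng)
        apparent, flags = inject_contamination(g, 1.0, rng)
        assert abs((apparent[:, 0] == 1).mean() - 0.875) < 0.01

    def test_apparent_genotype_law_across_frequency_grid(self, rng):
        # contaminated extracts follow (p^4, 1-p^4-q^4, q^4) within 3 SE
        n = 20_000
        for p in (0.1, 0.3, 0.5, 0.7, 0.9):
            g = sample_genotype_matrix(np.array([p]), n, rng)
            apparent, _ = inject_contamination(g, 1.0, rng)
            q = 1 - p
            for code, expect in ((2, p**4), (1, 1 - p**4 - q**4), (0, q**4)):
                obs = (apparent[:, 0] == code).mean()
                se = max(np.sqrt(expect * (1 - expect) / n), 1e-4)
                assert abs(obs - expect) < 3 * se + 1e-9

    def test_single_fish_collection_cannot_be_contaminated(self):
        with pytest.raises(ValueError):
            inject_contamination(np.array([[1]], dtype=np.int8), 1.0, np.random.default_rng(0))


class TestMissingnessAndStrays:
    def test_zero_rates_are_identity(self, rng):
        g = sample_genotype_matrix(np.full(10, 0.5), 20, rng)
        out, stray = inject_missingness_and_strays(g, 0.0, 0.0, np.full(10, 0.5), rng)
        assert np.array_equal(out, g) and not stray.any()

    def test_missing_fraction(self, rng):
        g = sample_genotype_matrix(np.full(135, 0.5), 10_000, rng)
        out, _ = inject_missingness_and_strays(g, 0.1, 0.0, np.full(135, 0.5), rng)
        assert abs((out == MISSING).mean() - 0.100) < 0.005

    def test_all_strays_from_fixed_source(self, rng):
        g = sample_genotype_matrix(np.full(4, 0.2), 30, rng)
        out, stray = inject_missingness_and_strays(g, 0.0, 1.0, np.full(4, 1.0), rng)
        assert np.all(out == 2) and stray.all()


class TestMicrosatellites:
    def test_clean_individuals_show_at_most_two_alleles(self, rng):
        freqs = [np.full(10, 0.1)] * 7
        obs = simulate_microsatellites(
            50, freqs, np.zeros(50, bool), np.full(50, -1), rng
        )
        assert all(1 <= len(s) <= 2 for row in obs for s in row)

    def test_disjoint_heterozygote_mixture_shows_four_alleles(self):
        # deterministic construction: focal {0,1}, donor {2,3}
        rng = np.random.default_rng(0)
        freqs = [np.full(4, 0.25)]
        for _ in range(200):
            obs = simulate_microsatellites(
                2, freqs, np.array([True, False]), np.array([1, -1]), rng
            )
            own = obs[1][0]
            mixed = obs[0][0]
            if len(own) == 2 and len(mixed - own) == 2:
                assert len(mixed) == 4
                return
        raise AssertionError("never sampled disjoint heterozygous genotypes")

    def test_contaminated_extracts_nearly_always_detectable(self, rng):
        # 7 ten-allele loci: overlap collapsing every locus is vanishingly rare
        freqs = [np.full(10, 0.1)] * 7
        n = 2_000
        donors = np.arange(1, n + 1) % n
        obs = simulate_microsatellites(n, freqs, np.ones(n, bool), donors, rng)
        detect = np.mean([any(len(s) > 2 for s in row) for row in obs])
        assert detect >= 0.99

    def test_frequencies_must_sum_to_one(self, rng):
        with pytest.raises(ValueError):
            simulate_microsatellites(
                5, [np.array([0.5, 0.4])], np.zeros(5, bool), np.full(5, -1), rng
            )


class TestGenerateStudy:
    def test_no_introgression_leaves_sink_frequencies_unchanged(self):
        cfg = SimulationConfig(
            n_loci=20, n_sinks=2, m_true=(0.0, 0.0), n_source=20,
            n_historical=15, n_contemporary=20, contamination_rate=0.0, seed=3,
        )
        study = generate_study(cfg)
        assert np.array_equal(study.truth.qn, study.truth.q0)

    def test_same_seed_is_bit_identical_and_seeds_differ(self):
        cfg = SimulationConfig(n_loci=15, n_sinks=2, m_true=(0.1, 0.2),
                               n_source=20, n_historical=15, n_contemporary=20, seed=9)
        a, b = generate_study(cfg), generate_study(cfg)
        for ca, cb in zip(a.collections, b.collections):
            assert np.array_equal(ca.genotypes, cb.genotypes)
        c = generate_study(SimulationConfig(**{**cfg.__dict__, "seed": 10}))
        assert any(
            not np.array_equal(ca.genotypes, cc.genotypes)
            for ca, cc in zip(a.collections, c.collections)
        )

    def test_default_design_shape_and_contamination_fraction(self):
        study = generate_study(SimulationConfig(seed=1))
        assert len(study.collections) == 9  # 1 source + 4 sinks x 2 eras
        flags = np.concatenate(
            [study.truth.contaminated[c.name]
             for c in study.collections.by_role("sink-historical")]
        )
        assert abs(flags.mean() - 0.50) < 0.05

    def test_truth_forecast_is_exact_and_between_endpoints(self):
        cfg = SimulationConfig(n_loci=30, n_sinks=2, m_true=(0.15, 0.02),
                               n_source=20, n_historical=15, n_contemporary=20, seed=4)
        t = generate_study(cfg).truth
        expect = sink_frequency_forecast(t.q0, t.Q, t.m_true[:, None], t.n_generations)
        assert np.allclose(t.qn, expect, atol=1e-15)
        lo = np.minimum(t.q0, t.Q[None, :])
        hi = np.maximum(t.q0, t.Q[None, :])
        assert np.all(t.qn >= lo - 1e-12) and np.all(t.qn <= hi + 1e-12)

    def test_forecast_monotone_in_generations_toward_source(self):
        cfg = dict(n_loci=25, n_sinks=1, m_true=(0.2,), n_source=10,
                   n_historical=10, n_contemporary=10)
        gaps = []
        for n_gen in (1, 3, 6, 12):
            t = generate_study(SimulationConfig(**cfg, n_generations=n_gen, seed=7)).truth
            gaps.append(np.abs(t.Q[None, :] - t.qn))
        for a, b in zip(gaps, gaps[1:]):
            assert np.all(b <= a + 1e-12)
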