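"""Simulator: population trajectories, Mendelian transmission, QTL
architectures, effect distributions and variance scaling."""

import dataclasses

import numpy as np
import pytest

import genoconnect as gc
from genoconnect.simulate import TARGET_PARTITIONS

from conftest import mendelian_violations, random_genotypes


class TestHistoricalPopulation:
    def test_bottleneck_trajectory(self):
        gmap = gc.GenomeMap.from_design(1, 100.0, 20)
        pool = gc.simulate_historical_population(
            gmap, n0=1000, n_final=220, n_generations=100, seed=1)
        assert pool.generation_sizes[0] == 1000
        assert pool.generation_sizes[-1] == 220
        assert len(pool.generation_sizes) == 101
        assert pool.haplotypes.shape == (440, 20)

    def test_zero_generations_identity(self):
        gmap = gc.GenomeMap.from_design(1, 100.0, 30)
        pool = gc.simulate_historical_population(
            gmap, n0=100, n_final=50, n_generations=0, seed=2)
        assert list(pool.generation_sizes) == [100]
        # exact-count initialization: frequency is exactly 0.5 per locus
        np.testing.assert_allclose(pool.allele_freqs, 0.5)

    def test_wright_fisher_drift_variance(self):
        """Neutral drift oracle: E[(p_t - p_0)^2] = p0 q0 (1-(1-1/2N)^t).

        Widely spaced loci on many chromosomes approximate independent
        Wright-Fisher replicates.
        """
        n, t = 50, 20
        gmap = gc.GenomeMap.from_design(50, 100.0, 10)  # 500 loci, 10 cM apart
        pool = gc.simulate_historical_population(
            gmap, n0=n, n_final=n, n_generations=t, mutation_rate=0.0, seed=3)
        expected = 0.25 * (1.0 - (1.0 - 1.0 / (2 * n)) ** t)
        observed = float(np.mean((pool.allele_freqs - 0.5) ** 2))
        assert observed == pytest.approx(expected, rel=0.2)

    def test_all_fixed_raises(self):
        gmap = gc.GenomeMap.from_design(1, 100.0, 4)
        with pytest.raises(RuntimeError, match="fixed"):
            gc.simulate_historical_population(
                gmap, n0=2, n_final=2, n_generations=400,
                mutation_rate=0.0, seed=4)


class TestRecentPopulation:
    def test_totals_match_design(self):
        """200 dams x 2 offspring x 5 generations = 2000 individuals,
        split 1200 / 800 across generations 1-3 / 4-5."""
        gmap = gc.GenomeMap.from_design(2, 100.0, 20)
        pool = gc.simulate_historical_population(
            gmap, n0=300, n_final=220, n_generations=10, seed=5)
        geno, ped = gc.simulate_recent_population(
            pool, n_dams=200, n_sires=10, n_generations=5, seed=6,
            expected_total=2000)
        gens = ped.table["generation"]
        assert (gens >= 1).sum() == 2000
        assert len(ped.ids_in_generations([1, 2, 3])) == 1200
        assert len(ped.ids_in_generations([4, 5])) == 800
        assert geno.n_individuals == 2000 + 210

    def test_zero_generations_founders_only(self, toy_gmap):
        pool = gc.simulate_historical_population(
            toy_gmap, n0=100, n_final=60, n_generations=5, seed=7)
        geno, ped = gc.simulate_recent_population(
            pool, n_dams=20, n_sires=4, n_generations=0, seed=8)
        assert (ped.table["generation"] == 0).all()
        assert (ped.table[["sire", "dam"]] == 0).all().all()
        assert geno.n_individuals == 24

    def test_inconsistent_litter_design_raises(self, toy_gmap):
        pool = gc.simulate_historical_population(
            toy_gmap, n0=100, n_final=60, n_generations=5, seed=9)
        with pytest.raises(ValueError, match="litter"):
            gc.simulate_recent_population(pool, n_dams=20, n_sires=4,
                                          n_generations=3, seed=10,
                                          expected_total=999)

    def test_mendelian_consistency(self, toy_population):
        _, ped, geno_all = toy_population
        assert mendelian_violations(geno_all, ped) == 0

    def test_bit_reproducible(self, toy_gmap):
        pool = gc.simulate_historical_population(
            toy_gmap, n0=80, n_final=60, n_generations=5, seed=11)
        g1, p1 = gc.simulate_recent_population(pool, 10, 3, 2, seed=12)
        g2, p2 = gc.simulate_recent_population(pool, 10, 3, 2, seed=12)
        np.testing.assert_array_equal(g1.dosages, g2.dosages)
        assert p1.table.equals(p2.table)


class TestQtlArchitecture:
    @pytest.mark.parametrize("n_chrom,epi,expected_pairs", [
        (29, 5, 10_440),   # 145 epistatic QTL genome-wide
        (1, 2, 1),
        (3, 3, 36),        # 9 * 8 / 2, verified by enumeration
    ])
    def test_pair_counts(self, n_chrom, epi, expected_pairs):
        gmap = gc.GenomeMap.from_design(n_chrom, 100.0, 12)
        geno = random_genotypes(30, gmap.n_loci, seed=13, gmap=gmap)
        arch = gc.sample_qtl_architecture(gmap, geno, "ADE",
                                          qtl_per_chrom=8,
                                          epi_qtl_per_chrom=epi, seed=14)
        assert arch.n_pairs == expected_pairs
        from itertools import combinations
        assert expected_pairs == len(list(
            combinations(range(n_chrom * epi), 2)))

    def test_epi_nested_and_sorted(self, toy_gmap, toy_population):
        geno, _, _ = toy_population
        arch = gc.sample_qtl_architecture(toy_gmap, geno, "AD", 10, 4, seed=15)
        assert np.isin(arch.epi_qtl_index, arch.qtl_index).all()
        assert len(np.unique(arch.qtl_index)) == arch.n_qtl
        assert (arch.pairs[:, 0] < arch.pairs[:, 1]).all()

    def test_epi_exceeding_qtl_raises(self, toy_gmap, toy_population):
        geno, _, _ = toy_population
        with pytest.raises(ValueError, match="epi"):
            gc.sample_qtl_architecture(toy_gmap, geno, "AD", 5, 6, seed=16)


@pytest.fixture(scope="module")
def big_draw():
    n = 100_000
    arch = gc.TraitArchitecture(
        scenario="ADE", qtl_index=np.arange(n),
        epi_qtl_index=np.arange(10),
        pairs=np.tile([0, 1], (n, 1)), a=np.zeros(n), d=np.zeros(n),
        delta=np.zeros(n), ad_effects=np.zeros(n),
        targets=(0.2, 0.1, 0.1, 0.4))
    return gc.draw_qtl_effects(arch, seed=17)


class TestEffectDistributions:
    def test_additive_magnitude_gamma_moments(self, big_draw):
        # Gamma(0.42, 8.282): mean = 3.478, checked within 4 SE
        mean_abs = np.abs(big_draw.a).mean()
        assert mean_abs == pytest.approx(0.42 * 8.282, abs=0.07)

    def test_signs_symmetric(self, big_draw):
        assert big_draw.a.mean() == pytest.approx(0.0, abs=0.065)

    def test_dominance_is_delta_times_abs_a(self, big_draw):
        np.testing.assert_allclose(big_draw.d,
                                   big_draw.delta * np.abs(big_draw.a))

    def test_epistatic_effect_moments(self, big_draw):
        assert big_draw.ad_effects.mean() == pytest.approx(0.02, abs=0.003)
        assert big_draw.ad_effects.var() == pytest.approx(0.03, rel=0.03)

    def test_scenario_zeroing(self, toy_gmap, toy_population):
        geno, _, _ = toy_population
        for scen, zeroed in (("PE", ("a", "d")), ("AD", ("ad_effects",))):
            arch = gc.sample_qtl_architecture(toy_gmap, geno, scen, 10, 3,
                                              seed=18)
            arch = gc.draw_qtl_effects(arch, seed=19)
            for attr in zeroed:
                assert not np.any(getattr(arch, attr))


class TestVarianceScaling:
    @pytest.mark.parametrize("scenario,h2", sorted(TARGET_PARTITIONS))
    def test_realized_variances_hit_targets(self, toy_gmap, toy_population,
                                            scenario, h2):
        geno, _, _ = toy_population
        arch = gc.sample_qtl_architecture(toy_gmap, geno, scenario, 10, 3,
                                          h2=h2, seed=20)
        arch = gc.draw_qtl_effects(arch, seed=21)
        arch = gc.scale_to_target_variances(arch, geno)
        t_a, t_d, t_e = TARGET_PARTITIONS[(scenario, h2)]
        real = arch.variances["realized"]
        assert real["additive"] == pytest.approx(t_a, abs=1e-9)
        assert real["dominance"] == pytest.approx(t_d, abs=1e-9)
        assert real["epistatic"] == pytest.approx(t_e, abs=1e-9)

    def test_table1_partition_values(self):
        assert TARGET_PARTITIONS[("AD", 0.4)] == (0.3, 0.1, 0.0)
        assert TARGET_PARTITIONS[("ADE", 0.8)] == (0.4, 0.2, 0.2)

    def test_scaling_invariant_to_prescaling(self, toy_gmap, toy_population):
        geno, _, _ = toy_population
        arch = gc.sample_qtl_architecture(toy_gmap, geno, "AD", 10, 3, seed=22)
        arch = gc.draw_qtl_effects(arch, seed=23)
        doubled = dataclasses.replace(arch, a=2 * arch.a,
                                      d=arch.delta * np.abs(2 * arch.a))
        s1 = gc.scale_to_target_variances(arch, geno)
        s2 = gc.scale_to_target_variances(doubled, geno)
        np.testing.assert_allclose(s1.a, s2.a)
        np.testing.assert_allclose(s1.d, s2.d)


class TestPhenotypes:
    def test_zero_residual_means_y_equals_g(self, toy_population, toy_gmap):
        geno, _, _ = toy_population
        arch = gc.sample_qtl_architecture(toy_gmap, geno, "AD", 10, 3,
                                          seed=24, targets=(0.7, 0.3, 0.0))
        arch = gc.draw_qtl_effects(arch, seed=25)
        arch = gc.scale_to_target_variances(arch, geno)
        assert arch.targets[3] == pytest.approx(1.0)
        phen = gc.simulate_phenotypes(geno, arch, seed=26)
        np.testing.assert_allclose(phen.y, phen.g_true)

    def test_unit_phenotypic_variance(self):
        """Mean realized var(y) over 10 residual draws is ~1 at n=2000.

        Components are scaled individually, so total genetic variance (and
        hence var(y)) deviates from target only through in-sample
        covariance between components, which vanishes with QTL count.
        """
        gmap = gc.GenomeMap.from_design(10, 100.0, 100)
        pool = gc.simulate_historical_population(
            gmap, n0=500, n_final=220, n_generations=30, seed=201)
        geno_all, ped = gc.simulate_recent_population(
            pool, n_dams=200, n_sires=10, n_generations=5, seed=202)
        geno = geno_all.subset_individuals(ped.ids_in_generations(range(1, 6)))
        arch = gc.sample_qtl_architecture(gmap, geno, "AD", 30, 5,
                                          h2=0.4, seed=203)
        arch = gc.scale_to_target_variances(
            gc.draw_qtl_effects(arch, seed=204), geno)
        vs = [np.var(gc.simulate_phenotypes(geno, arch, seed=s).y)
              for s in range(10)]
        assert np.mean(vs) == pytest.approx(1.0, abs=0.05)

    def test_components_sum_to_g(self, toy_trait):
        _, phen = toy_trait
        total = sum(phen.components.values())
        np.testing.assert_allclose(total, phen.g_true)

    def test_additive_effects_recoverable_unlinked(self):
        """On an unlinked panel, regressing the additive component on the
        centered QTL design returns the scaled effects (least squares)."""
        geno = random_genotypes(400, 30, seed=27)
        arch = gc.TraitArchitecture(
            scenario="AD", qtl_index=np.arange(30),
            epi_qtl_index=np.array([], int),
            pairs=np.zeros((0, 2), int), a=np.zeros(30), d=np.zeros(30),
            delta=np.zeros(30), ad_effects=np.zeros(0),
            targets=(0.3, 0.1, 0.0, 0.4))
        arch = gc.draw_qtl_effects(arch, seed=28)
        arch = gc.scale_to_target_variances(arch, geno)
        comp = gc.genetic_components(geno, arch)["additive"]
        p = geno.allele_freqs
        Wa = geno.dosages.astype(float) - 2 * p
        est, *_ = np.linalg.lstsq(Wa, comp, rcond=None)
        np.testing.assert_allclose(est, arch.a, atol=1e-8)
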