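import numpy as np
import pandas as pd
import pytest

import genoconnect as gc


def random_genotypes(n, m, seed, p_range=(0.1, 0.9), gmap=None):
    """Unlinked dosage panel with allele frequencies drawn per locus."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(*p_range, m)
    dos = rng.binomial(2, p, size=(n, m)).astype(np.uint8)
    return gc.GenotypeMatrix(dos, np.arange(1, n + 1), gmap)


def mendelian_violations(genotypes, pedigree):
    """Count parent-offspring genotype combinations that violate
    gamete transmission (offspring 2 needs both parents >= 1, offspring 0
    needs both parents <= 1)."""
    tab = pedigree.table
    pos = pd.Index(genotypes.ids)
    bad = 0
    for _, row in tab.iterrows():
        if row["sire"] == 0:
            continue
        o = genotypes.dosages[pos.get_loc(row["id"])]
        for parent in (row["sire"], row["dam"]):
            g = genotypes.dosages[pos.get_loc(parent)]
            bad += int(np.sum((o == 2) & (g == 0)) + np.sum((o == 0) & (g == 2)))
    return bad


@pytest.fixture(scope="session")
def toy_gmap():
    return gc.GenomeMap.from_design(4, 100.0, 40)


@pytest.fixture(scope="session")
def toy_population(toy_gmap):
    """Small pedigreed population shared across tests: ~120 cohort
    individuals, 160 loci with bottleneck LD."""
    pool = gc.simulate_historical_population(
        toy_gmap, n0=300, n_final=120, n_generations=40, seed=101)
    geno_all, ped = gc.simulate_recent_population(
        pool, n_dams=20, n_sires=4, n_generations=3, seed=102)
    cohort = ped.ids_in_generations([1, 2, 3])
    return geno_all.subset_individuals(cohort), ped, geno_all


@pytest.fixture(scope="session")
def toy_trait(toy_gmap, toy_population):
    geno, ped, _ = toy_population
    arch = gc.sample_qtl_architecture(toy_gmap, geno, "AD",
                                      qtl_per_chrom=10, epi_qtl_per_chrom=3,
                                      h2=0.4, seed=103)
    arch = gc.draw_qtl_effects(arch, seed=104)
    arch = gc.scale_to_target_variances(arch, geno)
    phen = gc.simulate_phenotypes(geno, arch, seed=105)
    return arch, phen
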