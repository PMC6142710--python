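"""Forward-in-time simulation of genotypes, pedigree and phenotypes.

The generator emulates a livestock-style population: a bottlenecked
historical population (random union of gametes, Haldane recombination,
symmetric mutation) establishes linkage disequilibrium and an allele
frequency spread; a small recent pedigree (few sires, many dams, discrete
generations) creates family structure; and a quantitative trait is built
from QTL carrying additive, dominance and pairwise additive-by-dominance
epistatic effects, rescaled so the realized variance components hit a
requested partition of a unit phenotypic variance.

Default constants correspond to the simulated design this package studies:
29 chromosomes of 100 cM, 1885 SNPs and 65 QTL per chromosome, a
1000 -> 220 historical bottleneck over 100 generations, and a recent
pedigree of 200 dams x 10 sires mated for 5 generations (2000 offspring).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from numpy.random import SeedSequence, default_rng

logger = logging.getLogger(__name__)

#: Variance partitions (h2_additive, h2_dominance, h2_epistatic) for each
#: (gene-action scenario, broad-sense heritability) cell of the simulated
#: design.  Phenotypic variance is 1, so heritabilities are variances.
TARGET_PARTITIONS = {
    ("AD", 0.4): (0.3, 0.1, 0.0),
    ("ADE", 0.4): (0.2, 0.1, 0.1),
    ("PE", 0.4): (0.0, 0.0, 0.4),
    ("AD", 0.8): (0.6, 0.2, 0.0),
    ("ADE", 0.8): (0.4, 0.2, 0.2),
    ("PE", 0.8): (0.0, 0.0, 0.8),
}

SCENARIOS = ("AD", "ADE", "PE")


def _rng(seed):
    """Accept an int, SeedSequence, Generator or None."""
    if isinstance(seed, np.random.Generator):
        return seed
    return default_rng(seed)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeMap:
    """Genetic map: ordered cM positions of bi-allelic loci per chromosome."""

    chrom_length_cm: float
    positions: tuple  # tuple of 1-D float arrays, one per chromosome

    def __post_init__(self):
        for pos in self.positions:
            if len(pos) and (np.any(np.diff(pos) <= 0)):
                raise ValueError("map positions must be strictly increasing")
            if len(pos) and (pos[0] < 0 or pos[-1] > self.chrom_length_cm):
                raise ValueError("map positions outside [0, chrom_length_cm]")

    @classmethod
    def from_design(cls, n_chromosomes: int, chrom_length_cm: float,
                    n_loci_per_chrom: int) -> "GenomeMap":
        """Equally spaced loci on every chromosome (the simulated design)."""
        pos = np.arange(1, n_loci_per_chrom + 1) * (
            chrom_length_cm / (n_loci_per_chrom + 1))
        return cls(chrom_length_cm, tuple(pos.copy() for _ in range(n_chromosomes)))

    @property
    def n_chromosomes(self) -> int:
        return len(self.positions)

    @property
    def n_loci(self) -> int:
        return sum(len(p) for p in self.positions)

    @property
    def loci_per_chrom(self) -> np.ndarray:
        return np.array([len(p) for p in self.positions])

    @property
    def chrom_index(self) -> np.ndarray:
        """Chromosome id (0-based) of every global locus column."""
        return np.repeat(np.arange(self.n_chromosomes), self.loci_per_chrom)

    @property
    def flat_positions(self) -> np.ndarray:
        return np.concatenate(self.positions) if self.positions else np.array([])

    def subset(self, cols: np.ndarray) -> "GenomeMap":
        """Map restricted to the given (sorted) global locus columns."""
        cols = np.sort(np.asarray(cols))
        chrom = self.chrom_index[cols]
        flat = self.flat_positions[cols]
        return GenomeMap(self.chrom_length_cm,
                         tuple(flat[chrom == c] for c in range(self.n_chromosomes)))


@dataclass
class HaplotypePool:
    """Phased binary haplotypes of the final historical generation."""

    haplotypes: np.ndarray           # (2N, L) uint8, phased 0/1 alleles
    gmap: GenomeMap
    generation_sizes: np.ndarray     # population size trajectory, [n0 ... n_final]

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0] // 2

    @property
    def allele_freqs(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)


@dataclass
class Pedigree:
    """Pedigree records; parent id 0 means unknown, sex 1=male / 2=female."""

    table: pd.DataFrame  # columns: id, sire, dam, sex, generation

    REQUIRED = ("id", "sire", "dam", "sex", "generation")

    def __post_init__(self):
        missing = set(self.REQUIRED) - set(self.table.columns)
        if missing:
            raise ValueError(f"pedigree missing columns: {sorted(missing)}")

    @property
    def ids(self) -> np.ndarray:
        return self.table["id"].to_numpy()

    def ids_in_generations(self, generations) -> np.ndarray:
        gens = set(np.atleast_1d(list(generations)).ravel())
        mask = self.table["generation"].isin(gens)
        return self.table.loc[mask, "id"].to_numpy()

    def topo_sort(self) -> "Pedigree":
        """Parents-before-offspring order; raises on cycles."""
        import graphlib

        tab = self.table
        ts = graphlib.TopologicalSorter()
        parents = dict(zip(tab["id"], zip(tab["sire"], tab["dam"])))
        for iid, (s, d) in parents.items():
            preds = [p for p in (s, d) if p != 0]
            ts.add(iid, *preds)
        try:
            order = list(ts.static_order())
        except graphlib.CycleError as err:
            raise ValueError(f"cyclic pedigree: {err.args[1]}") from err
        order = [i for i in order if i in parents]
        sorted_tab = tab.set_index("id").loc[order].reset_index()
        return Pedigree(sorted_tab)

    def validate(self) -> None:
        tab = self.topo_sort().table  # raises on cycles
        known = set(tab["id"])
        for col, sex in (("sire", 1), ("dam", 2)):
            ps = tab[col][tab[col] != 0]
            unknown = set(ps) - known
            if unknown:
                raise ValueError(f"{col} ids not in pedigree: {sorted(unknown)[:5]}")
            sexes = tab.set_index("id").loc[list(set(ps)), "sex"]
            if (sexes != sex).any():
                bad = sexes.index[sexes != sex].tolist()[:5]
                raise ValueError(f"{col}s with wrong sex: {bad}")


@dataclass
class GenotypeMatrix:
    """Individuals x loci allele-dosage codes in {0, 1, 2}.

    ``dosages[i, k]`` counts copies of the tracked allele of locus *k* in
    individual *i*.  ``freqs`` may be injected (e.g. training-set
    frequencies); otherwise frequencies are estimated from the matrix.
    """

    dosages: np.ndarray
    ids: np.ndarray
    gmap: Optional[GenomeMap] = None
    freqs: Optional[np.ndarray] = None

    def __post_init__(self):
        d = self.dosages
        if d.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x loci)")
        if not np.isin(np.unique(d), [0, 1, 2]).all():
            raise ValueError("dosage values must be in {0, 1, 2}")
        if len(self.ids) != d.shape[0]:
            raise ValueError("ids do not match number of rows")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    @property
    def allele_freqs(self) -> np.ndarray:
        if self.freqs is not None:
            return self.freqs
        return self.dosages.mean(axis=0) / 2.0

    @property
    def monomorphic(self) -> np.ndarray:
        p = self.allele_freqs
        return (p <= 0.0) | (p >= 1.0)

    def _id_positions(self, ids) -> np.ndarray:
        index = pd.Index(self.ids)
        pos = index.get_indexer(np.asarray(ids))
        if (pos < 0).any():
            raise KeyError("unknown individual ids requested")
        return pos

    def subset_individuals(self, ids) -> "GenotypeMatrix":
        pos = self._id_positions(ids)
        return GenotypeMatrix(self.dosages[pos], np.asarray(ids).copy(),
                              self.gmap, self.freqs)

    def subset_loci(self, cols) -> "GenotypeMatrix":
        cols = np.sort(np.asarray(cols))
        gmap = self.gmap.subset(cols) if self.gmap is not None else None
        freqs = self.freqs[cols] if self.freqs is not None else None
        return GenotypeMatrix(self.dosages[:, cols], self.ids.copy(), gmap, freqs)

    def drop_loci(self, cols) -> "GenotypeMatrix":
        keep = np.setdiff1d(np.arange(self.n_loci), np.asarray(cols))
        return self.subset_loci(keep)


@dataclass
class TraitArchitecture:
    """QTL positions and effects of one simulated trait.

    ``targets`` is the (h2_A, h2_D, h2_E, H2) variance partition the effects
    are rescaled to; ``variances`` records realized and analytic component
    variances once :func:`scale_to_target_variances` has run.
    """

    scenario: str
    qtl_index: np.ndarray          # global locus columns used as QTL
    epi_qtl_index: np.ndarray      # subset of qtl_index carrying epistasis
    pairs: np.ndarray              # (P, 2) unordered epistatic pairs, k < k'
    a: np.ndarray                  # additive effects, one per QTL
    d: np.ndarray                  # dominance effects, d_k = delta_k * |a_k|
    delta: np.ndarray              # degrees of dominance
    ad_effects: np.ndarray         # (P,) per-pair epistatic effects
    targets: tuple                 # (h2_A, h2_D, h2_E, H2)
    scaled: bool = False
    variances: dict = field(default_factory=dict)

    @property
    def n_qtl(self) -> int:
        return len(self.qtl_index)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


@dataclass
class PhenotypeSet:
    """Phenotypes, total genetic values and their simulated components."""

    ids: np.ndarray
    y: np.ndarray
    g_true: np.ndarray
    components: dict               # 'additive', 'dominance', 'epistatic'
    sigma2_eps: float


# ---------------------------------------------------------------------------
# Meiosis / historical population
# ---------------------------------------------------------------------------


def _meiosis(haplotypes: np.ndarray, parent_index: np.ndarray,
             gmap: GenomeMap, rng) -> np.ndarray:
    """One gamete per requested parent, with Haldane recombination.

    Crossover between adjacent loci at distance d cM occurs with
    r = (1 - exp(-2 d/100)) / 2; parental phase is a Markov chain of
    switch indicators, vectorized across gametes via a cumulative XOR.
    """
    h1 = haplotypes[2 * parent_index]
    h2 = haplotypes[2 * parent_index + 1]
    n = len(parent_index)
    phase = np.empty((n, gmap.n_loci), dtype=bool)
    col = 0
    for pos in gmap.positions:
        L = len(pos)
        block = np.empty((n, L), dtype=bool)
        block[:, 0] = rng.random(n) < 0.5
        if L > 1:
            r = 0.5 * (1.0 - np.exp(-2.0 * np.diff(pos) / 100.0))
            block[:, 1:] = rng.random((n, L - 1)) < r
            np.logical_xor.accumulate(block, axis=1, out=block)
        phase[:, col:col + L] = block
        col += L
    return np.where(phase, h2, h1)


def _size_trajectory(n0: int, n_final: int, n_generations: int,
                     kind: str) -> np.ndarray:
    if n_generations == 0:
        return np.array([n0])
    if kind == "linear":
        sizes = np.linspace(n0, n_final, n_generations + 1)
    elif kind == "geometric":
        sizes = n0 * (n_final / n0) ** (np.arange(n_generations + 1) / n_generations)
    else:
        raise ValueError(f"unknown trajectory '{kind}'")
    return np.rint(sizes).astype(int)


def simulate_historical_population(gmap: GenomeMap, n0: int = 1000,
                                   n_final: int = 220,
                                   n_generations: int = 100,
                                   mutation_rate: float = 2.5e-5,
                                   seed=None, initial_freq: float = 0.5,
                                   trajectory: str = "linear",
                                   n_eq_generations: int = 0) -> HaplotypePool:
    """Random-mating Wright-Fisher population with a shrinking size.

    Starts every locus at ``initial_freq`` (allele counts fixed at
    ``round(2*n0*initial_freq)`` and randomly assigned, so the initial
    frequency is exact) and lets drift, recombination and symmetric
    per-locus mutation shape the final haplotype pool.

    ``n_eq_generations`` prepends constant-size generations before the
    bottleneck.  The initial haplotypes are in linkage equilibrium, so
    marker-QTL LD (and with it the tagging of QTL by a SNP panel) builds
    up only over the simulated generations; the pre-phase lets short-range
    LD approach drift-recombination equilibrium, as in a population with a
    deep history.

    Raises ``RuntimeError`` if every locus is fixed at the end.
    """
    if not (n0 >= n_final >= 2):
        raise ValueError("need n0 >= n_final >= 2")
    rng = _rng(seed)
    L = gmap.n_loci
    k = int(round(2 * n0 * initial_freq))
    base = np.zeros((2 * n0, L), dtype=np.uint8)
    base[:k] = 1
    haps = rng.permuted(base, axis=0)
    sizes = _size_trajectory(n0, n_final, n_generations, trajectory)
    if n_eq_generations:
        sizes = np.concatenate([np.full(n_eq_generations, n0), sizes])
    for g in range(1, len(sizes)):
        n = sizes[g]
        n_prev = haps.shape[0] // 2
        dads = rng.integers(0, n_prev, n)
        moms = rng.integers(0, n_prev, n)
        clash = moms == dads
        while clash.any():
            moms[clash] = rng.integers(0, n_prev, clash.sum())
            clash = moms == dads
        gam1 = _meiosis(haps, dads, gmap, rng)
        gam2 = _meiosis(haps, moms, gmap, rng)
        haps = np.empty((2 * n, L), dtype=np.uint8)
        haps[0::2] = gam1
        haps[1::2] = gam2
        if mutation_rate > 0:
            haps ^= (rng.random((2 * n, L)) < mutation_rate).astype(np.uint8)
    p = haps.mean(axis=0)
    if np.all((p <= 0) | (p >= 1)):
        raise RuntimeError(
            "all loci fixed after drift; increase mutation_rate or n_final")
    return HaplotypePool(haps, gmap, sizes)


# ---------------------------------------------------------------------------
# Recent pedigreed population
# ---------------------------------------------------------------------------


def _balanced_sexes(n: int, rng) -> np.ndarray:
    """Random permutation of an exactly half-male / half-female vector."""
    sexes = np.full(n, 2, dtype=np.int8)
    sexes[: n // 2] = 1
    return rng.permuted(sexes)


def simulate_recent_population(pool: HaplotypePool, n_dams: int = 200,
                               n_sires: int = 10, n_generations: int = 5,
                               offspring_per_dam: int = 2, seed=None,
                               expected_total: Optional[int] = None):
    """Discrete-generation pedigree from founders sampled out of the pool.

    Generation 0 founders (``n_sires`` males, ``n_dams`` females) are drawn
    without replacement from the historical pool.  In every subsequent
    generation each dam produces ``offspring_per_dam`` offspring by one
    randomly drawn sire (a litter); dams and sires are resampled from the
    previous generation's offspring.  Offspring sexes are an exactly
    balanced random permutation, which keeps the mating design feasible.

    Returns ``(GenotypeMatrix, Pedigree)`` covering founders *and*
    offspring; the analysis cohort is ``pedigree.ids_in_generations(1..)``.
    """
    n_off_per_gen = n_dams * offspring_per_dam
    total_offspring = n_off_per_gen * n_generations
    if expected_total is not None and expected_total != total_offspring:
        raise ValueError(
            f"litter design yields {total_offspring} offspring, "
            f"not the requested {expected_total}")
    if n_off_per_gen // 2 < max(n_dams, n_sires) and n_generations > 1:
        raise ValueError("litter design cannot sustain the parent counts")
    n_founders = n_dams + n_sires
    if pool.n_individuals < n_founders:
        raise ValueError("historical pool smaller than the founder sample")

    rng = _rng(seed)
    gmap = pool.gmap
    L = gmap.n_loci

    founder_pick = rng.choice(pool.n_individuals, n_founders, replace=False)
    hap_rows = np.empty((2 * n_founders, L), dtype=np.uint8)
    hap_rows[0::2] = pool.haplotypes[2 * founder_pick]
    hap_rows[1::2] = pool.haplotypes[2 * founder_pick + 1]
    haps = [hap_rows]

    sex0 = np.concatenate([np.full(n_sires, 1, np.int8),
                           np.full(n_dams, 2, np.int8)])
    sex0 = rng.permuted(sex0)
    records = [(i + 1, 0, 0, int(sex0[i]), 0) for i in range(n_founders)]
    next_id = n_founders + 1
    # index (into the growing haplotype store) of current candidate parents
    cur = np.arange(n_founders)
    cur_sex = sex0

    for gen in range(1, n_generations + 1):
        males = cur[cur_sex == 1]
        females = cur[cur_sex == 2]
        if len(females) < n_dams or len(males) < n_sires:
            raise ValueError("not enough candidate parents in generation "
                             f"{gen - 1}")
        dams = rng.choice(females, n_dams, replace=False)
        sires_pool = rng.choice(males, n_sires, replace=False)
        sire_of_dam = sires_pool[rng.integers(0, n_sires, n_dams)]
        dam_idx = np.repeat(dams, offspring_per_dam)
        sire_idx = np.repeat(sire_of_dam, offspring_per_dam)

        store = np.concatenate(haps, axis=0)
        gam_s = _meiosis(store, sire_idx, gmap, rng)
        gam_d = _meiosis(store, dam_idx, gmap, rng)
        new = np.empty((2 * n_off_per_gen, L), dtype=np.uint8)
        new[0::2] = gam_s
        new[1::2] = gam_d
        haps.append(new)

        sexes = _balanced_sexes(n_off_per_gen, rng)
        offset = store.shape[0] // 2
        ids = np.arange(next_id, next_id + n_off_per_gen)
        for j in range(n_off_per_gen):
            records.append((int(ids[j]), int(sire_idx[j]) + 1,
                            int(dam_idx[j]) + 1, int(sexes[j]), gen))
        next_id += n_off_per_gen
        cur = offset + np.arange(n_off_per_gen)
        cur_sex = sexes

    all_haps = np.concatenate(haps, axis=0)
    dosages = all_haps[0::2] + all_haps[1::2]
    ped = Pedigree(pd.DataFrame(records,
                                columns=["id", "sire", "dam", "sex", "generation"]))
    geno = GenotypeMatrix(dosages, ped.ids.copy(), gmap)
    assert (ped.table["generation"] >= 1).sum() == total_offspring
    return geno, ped


# ---------------------------------------------------------------------------
# Trait architecture
# ---------------------------------------------------------------------------


def sample_qtl_architecture(gmap: GenomeMap, genotypes: GenotypeMatrix,
                            scenario: str, qtl_per_chrom: int = 65,
                            epi_qtl_per_chrom: int = 5, h2: float = 0.4,
                            seed=None, targets=None) -> TraitArchitecture:
    """Sample QTL (and a nested epistatic subset) per chromosome.

    QTL are drawn without replacement from the segregating loci of each
    chromosome; all unordered pairs of the epistatic QTL are enumerated
    genome-wide.  ``targets`` defaults to the Table-1 partition for
    ``(scenario, h2)``.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"scenario must be one of {SCENARIOS}")
    if epi_qtl_per_chrom > qtl_per_chrom:
        raise ValueError("epi_qtl_per_chrom cannot exceed qtl_per_chrom")
    if targets is None:
        try:
            h2a, h2d, h2e = TARGET_PARTITIONS[(scenario, h2)]
        except KeyError:
            raise ValueError(
                f"no default partition for ({scenario}, {h2}); pass targets=")
    else:
        h2a, h2d, h2e = targets
    rng = _rng(seed)
    p = genotypes.allele_freqs
    chrom = gmap.chrom_index
    qtl, epi = [], []
    for c in range(gmap.n_chromosomes):
        cand = np.where((chrom == c) & (p > 0) & (p < 1))[0]
        if len(cand) < qtl_per_chrom:
            raise ValueError(
                f"chromosome {c}: only {len(cand)} segregating loci "
                f"for {qtl_per_chrom} QTL")
        picked = np.sort(rng.choice(cand, qtl_per_chrom, replace=False))
        qtl.append(picked)
        epi.append(np.sort(rng.choice(picked, epi_qtl_per_chrom, replace=False)))
    qtl_index = np.concatenate(qtl)
    epi_index = np.concatenate(epi)
    pairs = np.array(list(combinations(np.sort(epi_index), 2)), dtype=int)
    if pairs.size == 0:
        pairs = pairs.reshape(0, 2)
    n = len(qtl_index)
    return TraitArchitecture(
        scenario=scenario, qtl_index=qtl_index, epi_qtl_index=epi_index,
        pairs=pairs, a=np.zeros(n), d=np.zeros(n), delta=np.zeros(n),
        ad_effects=np.zeros(len(pairs)),
        targets=(h2a, h2d, h2e, h2a + h2d + h2e))


def draw_qtl_effects(arch: TraitArchitecture, seed=None,
                     gamma_shape: float = 0.42, gamma_scale: float = 8.282,
                     epi_mean: float = 0.02, epi_var: float = 0.03
                     ) -> TraitArchitecture:
    """Draw raw (unscaled) QTL effects.

    |a_k| ~ Gamma(0.42, 8.282) with a random sign; the degree of dominance
    delta_k ~ N(0, 1) sets d_k = delta_k |a_k|; pair epistatic effects are
    N(0.02, 0.03).  Components a scenario does not use stay zero (PE: a=d=0;
    AD: ad=0).
    """
    rng = _rng(seed)
    n = arch.n_qtl
    a = rng.gamma(gamma_shape, gamma_scale, n) * rng.choice([-1.0, 1.0], n)
    delta = rng.normal(0.0, 1.0, n)
    ad = rng.normal(epi_mean, np.sqrt(epi_var), arch.n_pairs)
    if arch.scenario == "PE":
        a = np.zeros(n)
        delta = np.zeros(n)
    if arch.scenario == "AD":
        ad = np.zeros(arch.n_pairs)
    d = delta * np.abs(a)
    return dataclasses.replace(arch, a=a, d=d, delta=delta, ad_effects=ad,
                               scaled=False)


def _qtl_designs(genotypes: GenotypeMatrix, arch: TraitArchitecture):
    """Centered additive and dominance-deviation design codes at the QTL.

    Additive code: dosage - 2p.  Dominance code (orthogonal to the additive
    code under Hardy-Weinberg): {-2p^2, 2pq, -2q^2} for dosages {0, 1, 2}.
    """
    p_all = genotypes.allele_freqs
    cols = arch.qtl_index
    W = genotypes.dosages[:, cols].astype(float)
    p = p_all[cols]
    q = 1.0 - p
    Wa = W - 2.0 * p
    Wd = np.where(W == 0, -2.0 * p ** 2,
                  np.where(W == 1, 2.0 * p * q, -2.0 * q ** 2))
    return Wa, Wd, p


def _epi_component(genotypes: GenotypeMatrix, arch: TraitArchitecture,
                   Wa: np.ndarray, Wd: np.ndarray) -> np.ndarray:
    """Sum over pairs (k < k') of ad_{kk'} * w_a(k) * w_d(k')."""
    if arch.n_pairs == 0:
        return np.zeros(genotypes.n_individuals)
    qtl_pos = {c: i for i, c in enumerate(arch.qtl_index)}
    epi_cols = np.array([qtl_pos[c] for c in np.sort(arch.epi_qtl_index)])
    epos = {c: i for i, c in enumerate(np.sort(arch.epi_qtl_index))}
    E = len(epi_cols)
    ad_mat = np.zeros((E, E))
    for (k, kp), eff in zip(arch.pairs, arch.ad_effects):
        ad_mat[epos[k], epos[kp]] = eff
    Wa_e = Wa[:, epi_cols]
    Wd_e = Wd[:, epi_cols]
    # component = rowsum_i of wa_i * (sum_{j>i} ad_ij wd_j)
    return np.einsum("ne,ne->n", Wa_e, Wd_e @ ad_mat.T)


def genetic_components(genotypes: GenotypeMatrix, arch: TraitArchitecture):
    """Per-individual additive, dominance and epistatic genetic values."""
    Wa, Wd, _ = _qtl_designs(genotypes, arch)
    return {
        "additive": Wa @ arch.a,
        "dominance": Wd @ arch.d,
        "epistatic": _epi_component(genotypes, arch, Wa, Wd),
    }


def analytic_variances(arch: TraitArchitecture, genotypes: GenotypeMatrix) -> dict:
    """Closed-form component variances under Hardy-Weinberg / linkage
    equilibrium, as diagnostics alongside the realized variances.

    sigma2_a = sum_k 2 p q alpha_k^2 with alpha = a + d(q - p);
    sigma2_d = sum_k (2 p q d_k)^2;
    sigma2_ad = 2 sum_{k<k'} p_k^2 p_k' q_k' (alpha_k d_k')^2 (as printed in
    the source design; empirical variances are the authoritative check).
    """
    _, _, p = _qtl_designs(genotypes, arch)
    q = 1.0 - p
    alpha = arch.a + arch.d * (q - p)
    s2a = float(np.sum(2 * p * q * alpha ** 2))
    s2d = float(np.sum((2 * p * q * arch.d) ** 2))
    s2ad = 0.0
    if arch.n_pairs:
        qtl_pos = {c: i for i, c in enumerate(arch.qtl_index)}
        i1 = np.array([qtl_pos[k] for k, _ in arch.pairs])
        i2 = np.array([qtl_pos[kp] for _, kp in arch.pairs])
        s2ad = float(2.0 * np.sum(
            p[i1] ** 2 * p[i2] * q[i2] * (alpha[i1] * arch.d[i2]) ** 2))
    return {"additive": s2a, "dominance": s2d, "epistatic": s2ad}


def scale_to_target_variances(arch: TraitArchitecture,
                              genotypes: GenotypeMatrix) -> TraitArchitecture:
    """Rescale each effect class so realized component variances hit targets.

    Two-pass scheme: additive effects are scaled first (dominance effects
    follow through d = delta |a|), then the degrees of dominance are scaled
    to fix the dominance variance, then the pair effects.  Variances are the
    empirical variances of the simulated components on this cohort, so the
    targets are met exactly for the sample at hand (LD and Hardy-Weinberg
    departures included).
    """
    t_a, t_d, t_e, H2 = arch.targets
    a = arch.a.copy()
    delta = arch.delta.copy()
    ad = arch.ad_effects.copy()
    Wa, Wd, _ = _qtl_designs(genotypes, arch)

    if t_a > 0:
        v = float(np.var(Wa @ a))
        if v <= 0:
            raise ValueError("additive target > 0 but additive variance is 0")
        a *= np.sqrt(t_a / v)
    else:
        a[:] = 0.0
    d = delta * np.abs(a)
    if t_d > 0:
        v = float(np.var(Wd @ d))
        if v <= 0:
            raise ValueError("dominance target > 0 but dominance variance is 0")
        delta *= np.sqrt(t_d / v)
        d = delta * np.abs(a)
    else:
        delta[:] = 0.0
        d[:] = 0.0
    scaled = dataclasses.replace(arch, a=a, d=d, delta=delta, ad_effects=ad)
    if t_e > 0:
        comp = _epi_component(genotypes, scaled, Wa, Wd)
        v = float(np.var(comp))
        if v <= 0:
            raise ValueError("epistatic target > 0 but epistatic variance is 0")
        ad = ad * np.sqrt(t_e / v)
    else:
        ad = np.zeros_like(ad)
    scaled = dataclasses.replace(scaled, ad_effects=ad, scaled=True)
    comps = genetic_components(genotypes, scaled)
    scaled.variances = {
        "realized": {k: float(np.var(v)) for k, v in comps.items()},
        "analytic": analytic_variances(scaled, genotypes),
        "targets": {"additive": t_a, "dominance": t_d, "epistatic": t_e},
    }
    return scaled


def simulate_phenotypes(genotypes: GenotypeMatrix, arch: TraitArchitecture,
                        seed=None) -> PhenotypeSet:
    """y = additive + dominance + epistatic + N(0, 1 - H2) residual."""
    if not arch.scaled:
        logger.warning("simulating phenotypes from unscaled effects")
    comps = genetic_components(genotypes, arch)
    g = comps["additive"] + comps["dominance"] + comps["epistatic"]
    H2 = arch.targets[3]
    s2e = max(1.0 - H2, 0.0)
    rng = _rng(seed)
    eps = rng.normal(0.0, np.sqrt(s2e), genotypes.n_individuals) if s2e > 0 \
        else np.zeros(genotypes.n_individuals)
    return PhenotypeSet(genotypes.ids.copy(), g + eps, g, comps, s2e)
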