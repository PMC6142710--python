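"""Declarative run configuration with the simulated design as defaults.

The default constants are the full-scale simulated design:
29 chromosomes x 100 cM carrying 1885 SNPs and 65 QTL each, a 1000 -> 220
historical bottleneck over 100 generations, a 200-dam x 10-sire recent
pedigree mated for 5 generations (2000 offspring), the design's variance
partitions at broad-sense heritabilities 0.4 and 0.8, exchange rates
0..50% and the Gaussian-kernel smoothing grid 0.22/0.5/0.9/1.6.
``ci_profile`` is a scaled-down version (600 individuals, 10 chromosomes
x 200 SNPs, 3 replicates) for fast, qualitative runs.
"""

from __future__ import annotations

import hashlib
import json
from typing import List, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    # genome
    n_chromosomes: int = Field(29, ge=1)
    chrom_length_cm: float = Field(100.0, gt=0)
    n_snp_per_chrom: int = Field(1885, ge=1)
    n_qtl_per_chrom: int = Field(65, ge=1)
    n_epi_qtl_per_chrom: int = Field(5, ge=0)

    # historical population
    hist_n0: int = Field(1000, ge=2)
    hist_n_final: int = Field(220, ge=2)
    hist_generations: int = Field(100, ge=0)
    #: constant-size generations before the bottleneck; the initial
    #: haplotypes are in linkage equilibrium, so this pre-phase builds the
    #: short-range LD a deep-history population (and a SNP chip worth of
    #: marker-QTL tagging) would have
    hist_eq_generations: int = Field(400, ge=0)
    mutation_rate: float = Field(2.5e-5, ge=0)
    trajectory: str = "linear"

    # recent pedigreed population
    n_dams: int = Field(200, ge=1)
    n_sires: int = Field(10, ge=1)
    recent_generations: int = Field(5, ge=1)
    offspring_per_dam: int = Field(2, ge=1)

    # trait architecture
    gene_actions: List[str] = ["AD", "ADE", "PE"]
    heritabilities: List[float] = [0.4, 0.8]
    gamma_shape: float = Field(0.42, gt=0)
    gamma_scale: float = Field(8.282, gt=0)
    epi_mean: float = 0.02
    epi_var: float = Field(0.03, gt=0)

    # kernels
    theta_grid: List[float] = [0.22, 0.5, 0.9, 1.6]
    gk_scaling: str = "mean"

    # management units
    exchange_rates: List[float] = [0.0, 0.1, 0.2, 0.3, 0.4, 0.5]
    kmeans_restarts: int = Field(25, ge=1)
    exchange_mode: str = "swap"
    nested_exchange: bool = False

    # mixed model
    reml_max_iter: int = Field(200, ge=1)
    reml_tol: float = Field(1e-6, gt=0)
    #: CD model carries the management units as fixed effects (classical
    #: connectedness setting); prediction folds always use intercept-only
    cd_unit_fixed_effect: bool = True

    # evaluation
    n_replicates: int = Field(10, ge=1)
    master_seed: int = 1234

    @field_validator("exchange_rates")
    @classmethod
    def _rates_in_range(cls, v):
        bad = [r for r in v if not (0.0 <= r <= 0.5)]
        if bad:
            raise ValueError(f"exchange rates outside [0, 0.5]: {bad}")
        return v

    @field_validator("heritabilities")
    @classmethod
    def _h2_in_range(cls, v):
        bad = [h for h in v if not (0.0 < h <= 1.0)]
        if bad:
            raise ValueError(f"heritabilities outside (0, 1]: {bad}")
        return v

    @field_validator("gene_actions")
    @classmethod
    def _known_scenarios(cls, v):
        bad = [g for g in v if g not in ("AD", "ADE", "PE")]
        if bad:
            raise ValueError(f"unknown gene actions: {bad}")
        return v

    @field_validator("theta_grid")
    @classmethod
    def _theta_positive(cls, v):
        bad = [t for t in v if t <= 0]
        if bad:
            raise ValueError(f"theta values must be > 0: {bad}")
        return v

    @field_validator("gk_scaling")
    @classmethod
    def _scaling_known(cls, v):
        if v not in ("mean", "raw"):
            raise ValueError("gk_scaling must be 'mean' or 'raw'")
        return v

    @field_validator("exchange_mode")
    @classmethod
    def _mode_known(cls, v):
        if v not in ("swap", "move"):
            raise ValueError("exchange_mode must be 'swap' or 'move'")
        return v

    # -- profiles ----------------------------------------------------------

    @classmethod
    def full_profile(cls, **overrides) -> "RunConfig":
        """Full-scale design (n = 2000, 29 chromosomes, 10 replicates)."""
        return cls(**overrides)

    @classmethod
    def ci_profile(cls, **overrides) -> "RunConfig":
        """Scaled-down profile: 600 individuals, 10 chrom x 200 SNPs.

        Chromosomes shrink to 10.6 cM so the marker panel keeps the
        full design's SNP density (and with it the marker-QTL tagging
        that dominance capture hinges on).
        """
        base = dict(n_chromosomes=10, n_snp_per_chrom=200,
                    chrom_length_cm=10.6, n_dams=60, n_sires=10,
                    n_replicates=3)
        base.update(overrides)
        return cls(**base)

    # -- (de)serialization -------------------------------------------------

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


def load_config(path) -> RunConfig:
    """Read a YAML config; missing keys fall back to the design defaults.

    Unknown keys or out-of-range values raise with every violation listed
    (pydantic validation).  An empty file yields the full defaults.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)


def dump_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(), fh, sort_keys=True)
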