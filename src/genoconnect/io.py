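"""Readers and writers for the plain-text formats the pipeline touches.

Genotypes travel as PLINK ``.raw``-style dosage tables or VCF (GT only);
pedigrees as 5-column CSV (0 = unknown parent); phenotypes and results as
TSV.  The simulator is map-native (cM); VCF export fabricates 1-based
base-pair positions proportional to the cM position, which is documented
here and in the header of every file written.
"""

from __future__ import annotations

import json
import logging
from typing import Optional

import numpy as np
import pandas as pd

from .config import RunConfig
from .simulate import GenomeMap, GenotypeMatrix, Pedigree, PhenotypeSet

logger = logging.getLogger(__name__)

#: bp fabricated per cM on VCF export
BP_PER_CM = 10_000


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


def write_plink_raw(genotypes: GenotypeMatrix, path,
                    pedigree: Optional[Pedigree] = None,
                    phenotypes: Optional[PhenotypeSet] = None) -> None:
    """PLINK .raw-style whitespace table (FID IID PAT MAT SEX PHENOTYPE
    then one dosage column per SNP)."""
    n = genotypes.n_individuals
    ped_cols = {"PAT": np.zeros(n, int), "MAT": np.zeros(n, int),
                "SEX": np.zeros(n, int)}
    if pedigree is not None:
        tab = pedigree.table.set_index("id")
        sub = tab.loc[genotypes.ids]
        ped_cols = {"PAT": sub["sire"].to_numpy(),
                    "MAT": sub["dam"].to_numpy(),
                    "SEX": sub["sex"].to_numpy()}
    pheno = np.full(n, -9.0)
    if phenotypes is not None:
        pos = pd.Index(phenotypes.ids).get_indexer(genotypes.ids)
        pheno = phenotypes.y[pos]
    out = pd.DataFrame({"FID": genotypes.ids, "IID": genotypes.ids,
                        **ped_cols, "PHENOTYPE": pheno})
    snp_names = [f"snp{k + 1}_A" for k in range(genotypes.n_loci)]
    out = pd.concat([out, pd.DataFrame(genotypes.dosages, columns=snp_names,
                                       index=out.index)], axis=1)
    out.to_csv(path, sep=" ", index=False)


def read_plink_raw(path) -> GenotypeMatrix:
    """Read a PLINK .raw-style table; missing dosages imputed to 2p."""
    df = pd.read_csv(path, sep=r"\s+")
    meta = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    snp_cols = [c for c in df.columns if c not in meta]
    dos = df[snp_cols].to_numpy(dtype=float)
    dos = _impute_missing(dos)
    return GenotypeMatrix(dos.astype(np.uint8), df["IID"].to_numpy())


def _impute_missing(dosages: np.ndarray) -> np.ndarray:
    """Mean-impute (to 2p, rounded to a legal code) missing dosages."""
    missing = ~np.isfinite(dosages)
    if missing.any():
        logger.info("imputing %d missing genotypes to 2p", int(missing.sum()))
        col_mean = np.nanmean(np.where(missing, np.nan, dosages), axis=0)
        col_mean = np.nan_to_num(col_mean)
        fill = np.clip(np.rint(col_mean), 0, 2)
        dosages = np.where(missing, fill[None, :], dosages)
    bad = ~np.isin(dosages, [0.0, 1.0, 2.0])
    if bad.any():
        raise ValueError("dosage values outside {0, 1, 2}")
    return dosages


def write_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Unphased GT-only VCF; the tracked (dosage-counted) allele is ALT.

    Simulation-native cM positions are fabricated to 1-based bp at
    10 kb per cM, made strictly increasing where rounding collides.
    """
    gmap = genotypes.gmap
    if gmap is None:
        gmap = GenomeMap(float(genotypes.n_loci + 1),
                         (np.arange(1, genotypes.n_loci + 1, dtype=float),))
    gt_strings = np.array(["0/0", "0/1", "1/1"])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=genoconnect (bp fabricated as round(cM*1e4)+1)\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in range(gmap.n_chromosomes):
            fh.write(f"##contig=<ID=chr{c + 1}>\n")
        sample_cols = "\t".join(str(i) for i in genotypes.ids)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + sample_cols + "\n")
        col = 0
        for c, pos_cm in enumerate(gmap.positions):
            bp = np.rint(np.asarray(pos_cm) * BP_PER_CM).astype(int) + 1
            bp = np.maximum.accumulate(bp + np.arange(len(bp)) * 0)  # sorted cM
            last = 0
            for j, p in enumerate(bp):
                p = max(p, last + 1)
                last = p
                gts = "\t".join(gt_strings[genotypes.dosages[:, col]])
                fh.write(f"chr{c + 1}\t{p}\tsnp{col + 1}\tA\tG\t.\tPASS\t.\t"
                         f"GT\t{gts}\n")
                col += 1


def read_vcf(path) -> GenotypeMatrix:
    """Read dosages (ALT-allele counts) from a VCF via cyvcf2.

    Non-biallelic records are skipped with a logged count; missing
    genotypes are imputed to the rounded mean dosage.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    ids = np.array([_maybe_int(s) for s in vcf.samples])
    rows = []
    skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            skipped += 1
            continue
        g = rec.gt_types.astype(float)  # 0/1/2 ALT copies, 3 = missing
        g[g == 3] = np.nan
        rows.append(g)
    if skipped:
        logger.info("skipped %d non-biallelic VCF records", skipped)
    dos = _impute_missing(np.asarray(rows).T)
    return GenotypeMatrix(dos.astype(np.uint8), ids)


def read_genotypes(path, format: str = "plink_raw") -> GenotypeMatrix:
    """Dispatch on format: 'plink_raw', 'vcf' or 'tsv' (ids x loci table)."""
    if format == "plink_raw":
        return read_plink_raw(path)
    if format == "vcf":
        return read_vcf(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        dos = _impute_missing(df.to_numpy(dtype=float))
        return GenotypeMatrix(dos.astype(np.uint8),
                              np.array([_maybe_int(i) for i in df.index]))
    raise ValueError(f"unknown genotype format '{format}'")


def maf_filter(genotypes: GenotypeMatrix, min_maf: float = 0.05) -> GenotypeMatrix:
    """Drop loci whose minor allele frequency is below the threshold."""
    p = genotypes.allele_freqs
    maf = np.minimum(p, 1.0 - p)
    keep = np.where(maf >= min_maf)[0]
    logger.info("MAF filter at %.3f: keeping %d of %d loci", min_maf,
                len(keep), genotypes.n_loci)
    return genotypes.subset_loci(keep)


def _maybe_int(x):
    try:
        return int(x)
    except (TypeError, ValueError):
        return x


# ---------------------------------------------------------------------------
# Pedigree / phenotypes
# ---------------------------------------------------------------------------


def write_pedigree(pedigree: Pedigree, path) -> None:
    pedigree.table[["id", "sire", "dam", "sex", "generation"]].to_csv(
        path, index=False)


def read_pedigree(path) -> Pedigree:
    """Validated, topologically ordered pedigree from 5-column CSV."""
    df = pd.read_csv(path)
    ped = Pedigree(df).topo_sort()   # raises naming the cycle if cyclic
    ped.validate()
    return ped


def write_phenotypes(phenotypes: PhenotypeSet, path) -> None:
    df = pd.DataFrame({"id": phenotypes.ids, "y": phenotypes.y,
                       "g_true": phenotypes.g_true,
                       **{k: v for k, v in phenotypes.components.items()}})
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_phenotypes(path) -> pd.DataFrame:
    """Phenotype table; 'NA' marks missing records (excluded from training
    by callers)."""
    return pd.read_csv(path, sep="\t", na_values=["NA"])


# ---------------------------------------------------------------------------
# Run manifest
# ---------------------------------------------------------------------------


def make_manifest(config: RunConfig, seed: int, path=None) -> dict:
    """Machine-readable record sufficient to reproduce a run bit-for-bit."""
    import numpy
    import scipy
    import sklearn

    manifest = {
        "config": config.model_dump(),
        "config_hash": config.config_hash(),
        "seed": int(seed),
        "versions": {"numpy": numpy.__version__,
                     "scipy": scipy.__version__,
                     "sklearn": sklearn.__version__},
    }
    if path is not None:
        with open(path, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
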