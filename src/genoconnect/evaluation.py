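"""Two-fold cross-validation accuracy and scenario-grid orchestration.

``run_experiment`` runs the full simulation grid at a
configurable scale: for each replicate it draws a recent pedigreed
population from a fixed historical pool, builds trait architectures for
each gene-action scenario and heritability, constructs the marker kernels,
clusters the cohort into two management units, applies the S1..S6 exchange
scenarios, and records the CD of the unit contrast (full-data variance
components) together with two-fold cross-validated prediction accuracy
(variance components re-estimated inside every training fold).
"""

from __future__ import annotations

import logging
import warnings
from itertools import product
from typing import Optional

import numpy as np
import pandas as pd
from numpy.random import SeedSequence

from . import simulate as sim
from .config import RunConfig
from .connectedness import cd_of_contrast
from .kernels import (KernelMatrix, additive_kernel, dominance_kernel,
                      gaussian_kernel, hadamard_kernel, numerator_relationship)
from .mixed_model import (ModelSpec, _collapse, fit_blup,
                          prediction_error_variance, reml_estimate)
from .units import UnitAssignment, cluster_units, contrast_vector, scenario_grid

logger = logging.getLogger(__name__)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        warnings.warn("constant predictions; accuracy undefined")
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def twofold_cv(y: np.ndarray, kernels, assignment: UnitAssignment,
               g_true: Optional[np.ndarray] = None, X: Optional[np.ndarray] = None,
               reml_kwargs: Optional[dict] = None,
               reml_start=None) -> dict:
    """Two-fold cross-validation across the management units.

    Fold 1 trains on MU1 and evaluates predictions on MU2; fold 2 is the
    reverse.  Accuracy is cor(g_true, g_hat) on the test individuals when
    the simulated truth is supplied, cor(y, g_hat) otherwise.  Variance
    components are re-estimated on each training fold (``reml_start``
    optionally warm-starts the iterations, e.g. from full-data estimates).
    """
    reml_kwargs = reml_kwargs or {}
    ids = kernels[0].ids
    order = pd.Index(assignment.ids).get_indexer(ids)
    if (order < 0).any():
        raise ValueError("assignment does not cover all kernel individuals")
    units = assignment.units[order]
    y = np.asarray(y, float)
    target = np.asarray(g_true, float) if g_true is not None else y
    folds = []
    for train_unit in (1, 2):
        train = units == train_unit
        test = ~train
        spec = ModelSpec(y=y[train], kernels=kernels,
                         X=X[train] if X is not None else None,
                         obs_ids=ids[train])
        vc = reml_estimate(spec, start=reml_start, **reml_kwargs)
        fit = fit_blup(spec, vc)
        pa = _pearson(target[test], fit.u_hat[test])
        folds.append({"train_unit": train_unit, "pa": pa, "vc": vc})
    pas = [f["pa"] for f in folds]
    return {"pa_fold": pas, "pa_mean": float(np.nanmean(pas)), "folds": folds}


def _kernel_configs(gene_action: str, markers, config: RunConfig):
    """Kernel model list benchmarked for one gene-action scenario."""
    G = additive_kernel(markers)
    if gene_action == "AD":
        D = dominance_kernel(markers)
        return [("G", [G]), ("G+D", [G, D])]
    if gene_action == "ADE":
        D = dominance_kernel(markers)
        GxD = hadamard_kernel(G, D)
        return [("G", [G]), ("G+D", [G, D]), ("G+D+GxD", [G, D, GxD])]
    if gene_action == "PE":
        configs = [("G", [G])]
        for theta in config.theta_grid:
            gk = gaussian_kernel(markers, theta, scaling=config.gk_scaling)
            configs.append((f"GK({theta})", [gk]))
        return configs
    raise ValueError(f"unknown gene action '{gene_action}'")


def run_experiment(config: RunConfig, seed: Optional[int] = None,
                   progress: bool = False) -> pd.DataFrame:
    """Run the full (scenario x heritability x kernel x exchange) grid.

    Returns one tidy row per (gene_action, H2, unit scenario, kernel
    configuration, replicate) holding prediction accuracy, CD and PEVD of
    the unit contrast, and the estimated variance components.  Fully
    deterministic given (config, seed); failures of individual cells are
    logged and skipped.
    """
    master = seed if seed is not None else config.master_seed
    ss = SeedSequence(master)
    s_pool, s_reps = ss.spawn(2)
    gmap = sim.GenomeMap.from_design(
        config.n_chromosomes, config.chrom_length_cm,
        config.n_snp_per_chrom + config.n_qtl_per_chrom)
    pool = sim.simulate_historical_population(
        gmap, config.hist_n0, config.hist_n_final, config.hist_generations,
        config.mutation_rate, seed=s_pool, trajectory=config.trajectory,
        n_eq_generations=config.hist_eq_generations)

    rows = []
    rep_seeds = s_reps.spawn(config.n_replicates)
    for rep, rseed in enumerate(rep_seeds):
        s_recent, s_cluster, s_exch, s_cells = rseed.spawn(4)
        geno_all, ped = sim.simulate_recent_population(
            pool, config.n_dams, config.n_sires, config.recent_generations,
            config.offspring_per_dam, seed=s_recent)
        cohort = ped.ids_in_generations(
            range(1, config.recent_generations + 1))
        geno = geno_all.subset_individuals(cohort)
        A = numerator_relationship(ped).subset(cohort)
        base = cluster_units(A, seed=s_cluster,
                             n_restarts=config.kmeans_restarts)
        scen = scenario_grid(base, config.exchange_rates, seed=s_exch,
                             nested=config.nested_exchange,
                             mode=config.exchange_mode)
        contrasts = {s: contrast_vector(a) for s, a in scen.items()}

        cells = list(product(config.gene_actions, config.heritabilities))
        cell_seeds = s_cells.spawn(len(cells))
        for (ga, h2), cseed in zip(cells, cell_seeds):
            s_arch, s_eff, s_phen = cseed.spawn(3)
            try:
                arch = sim.sample_qtl_architecture(
                    gmap, geno, ga, config.n_qtl_per_chrom,
                    config.n_epi_qtl_per_chrom, h2=h2, seed=s_arch)
                arch = sim.draw_qtl_effects(
                    arch, seed=s_eff, gamma_shape=config.gamma_shape,
                    gamma_scale=config.gamma_scale, epi_mean=config.epi_mean,
                    epi_var=config.epi_var)
                arch = sim.scale_to_target_variances(arch, geno)
                phen = sim.simulate_phenotypes(geno, arch, seed=s_phen)
                markers = geno.drop_loci(arch.qtl_index)
                configs = _kernel_configs(ga, markers, config)
            except Exception:
                logger.exception("cell (%s, %s, rep %d) failed during "
                                 "simulation; skipping", ga, h2, rep)
                continue
            for label, ks in configs:
                try:
                    rows.extend(_evaluate_cell(
                        ga, h2, rep, label, ks, phen, scen, contrasts, config))
                except Exception:
                    logger.exception("cell (%s, %s, %s, rep %d) failed; "
                                     "skipping", ga, h2, label, rep)
            if progress:
                print(f"replicate {rep}: {ga} H2={h2} done")
    return pd.DataFrame(rows)


def _evaluate_cell(ga, h2, rep, label, ks, phen, scen, contrasts, config):
    """CD and two-fold CV for one kernel configuration.

    Variance components come from one full-data REML fit (intercept-only
    model) and are shared by all exchange scenarios.  The CD model carries
    the management units as fixed effects (the classical connectedness
    setting: a disconnected design confounds the unit contrast with the
    unit effect and scores low), so BLUP / PEV are recomputed per scenario.
    Fold REML fits are warm-started from the full-data estimates.
    """
    spec_full = ModelSpec(y=phen.y, kernels=ks)
    vc_full = reml_estimate(spec_full, max_iter=config.reml_max_iter,
                            tol=config.reml_tol)
    start = [*vc_full.sigma2_u, vc_full.sigma2_e]
    K_avg, s2u = _collapse(ks, vc_full.sigma2_u)
    ids = ks[0].ids
    rows = []
    for s_label, asn in scen.items():
        if config.cd_unit_fixed_effect:
            order = pd.Index(asn.ids).get_indexer(ids)
            mu2 = (asn.units[order] == 2).astype(float)
            X_cd = np.column_stack([np.ones(len(mu2)), mu2])
        else:
            X_cd = None
        spec_cd = ModelSpec(y=phen.y, kernels=ks, X=X_cd)
        fit = fit_blup(spec_cd, vc_full)
        PEV = prediction_error_variance(fit)
        cd = cd_of_contrast(contrasts[s_label], K_avg, PEV, s2u,
                            scenario=s_label)
        cv = twofold_cv(phen.y, ks, asn, g_true=phen.g_true,
                        reml_start=start if len(ks) > 1 else None,
                        reml_kwargs={"max_iter": config.reml_max_iter,
                                     "tol": config.reml_tol})
        rows.append({
            "gene_action": ga, "H2": h2, "scenario": s_label,
            "kernel": label, "replicate": rep,
            "pa": cv["pa_mean"], "pa_fold1": cv["pa_fold"][0],
            "pa_fold2": cv["pa_fold"][1],
            "cd": cd.cd, "pevd": cd.pevd,
            "sigma2_u": float(np.sum(vc_full.sigma2_u)),
            "sigma2_e": vc_full.sigma2_e,
            "reml_converged": vc_full.converged,
        })
    return rows


def summarize_replicates(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard error of PA and CD per grid cell."""
    if table.empty:
        raise ValueError("no results to summarize")
    g = table.groupby(["gene_action", "H2", "scenario", "kernel"],
                      sort=True)
    out = g.agg(pa_mean=("pa", "mean"), pa_se=("pa", "sem"),
                cd_mean=("cd", "mean"), cd_se=("cd", "sem"),
                n_replicates=("replicate", "count")).reset_index()
    return out


def grid_extremes(summary: pd.DataFrame, gene_action: str,
                  value: str = "pa_mean") -> dict:
    """Grid-wide extreme cells (over H2, scenario and kernel config)."""
    sub = summary[summary["gene_action"] == gene_action]
    if sub.empty:
        raise ValueError(f"no rows for gene action '{gene_action}'")
    imin = sub[value].idxmin()
    imax = sub[value].idxmax()
    cols = ["H2", "scenario", "kernel", value]
    return {"min": sub.loc[imin, cols].to_dict(),
            "max": sub.loc[imax, cols].to_dict()}


def plot_scenario_results(summary: pd.DataFrame, gene_action: str, h2: float,
                          path=None):
    """PA (left) and CD (right) against the exchange scenarios."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = summary[(summary["gene_action"] == gene_action)
                  & (summary["H2"] == h2)]
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharex=True)
    for kernel, grp in sub.groupby("kernel"):
        grp = grp.sort_values("scenario")
        axes[0].errorbar(grp["scenario"], grp["pa_mean"], yerr=grp["pa_se"],
                         marker="o", label=kernel)
        axes[1].errorbar(grp["scenario"], grp["cd_mean"], yerr=grp["cd_se"],
                         marker="o", label=kernel)
    axes[0].set_ylabel("prediction accuracy")
    axes[1].set_ylabel("CD of contrast")
    for ax in axes:
        ax.set_xlabel("scenario")
    axes[0].legend(fontsize=8)
    fig.suptitle(f"{gene_action}, H2={h2}")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
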