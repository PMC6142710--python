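# Methods

This note documents the models, the synthetic-data generator, the
numerical choices and the known limitations of `genoconnect`, in the
package's own terms.

## Mixed model and estimation

All analyses use the kernel-BLUP model `y = Xb + Zu + e` with
`var(u) = Σ_k K_k σ²_k` over one or more positive-semidefinite
relationship kernels and `var(e) = I σ²_e`. `Z` is a record-to-individual
selection matrix; individuals without phenotypes are predicted through
the kernel's train–test block, which is algebraically identical to
solving Henderson's mixed-model equations with those phenotypes missing
(asserted in the tests to 1e-8).

**REML.** Single-kernel fits are exact: the model is projected onto an
orthonormal basis of error contrasts, the projected kernel is
eigendecomposed once, and the restricted likelihood becomes a smooth
1-D function of the variance ratio λ = σ²_u/σ²_e, maximized by bounded
scalar search with σ²_e profiled in closed form. Multi-kernel fits use
average-information (AI) REML: the AI step is damped so no component
falls below half its value when the proposal would leave the parameter
space; a component parked at the variance floor (1e-8 × var(y)) whose
gradient points further down is frozen (active set); a rejected step
falls back to step-halving and then to the monotone EM-style update
σ² ← σ² + σ⁴ (y′PV_kPy − tr(PV_k))/n. A tiny component the gradient
keeps pushing down is additionally tested directly at the floor and
moved there only if the restricted likelihood does not drop. The
residual is treated like any other component, because a
diagonal-dominant kernel (notably G#D) can absorb it; such
weakly-identified fits are flagged `converged=False` when the
parameters are still drifting after 200 iterations. Convergence is
declared when the maximum parameter change falls below 1e-6 of the
total variance or the restricted log-likelihood changes by < 1e-9.

**Multi-kernel collapse.** For BLUP, PEV and CD, the fitted components
are collapsed onto the variance-weighted averaged kernel
`K = Σ_k (σ²_k/Σσ²) K_k` with `σ²_u = Σ_k σ²_k` (kernel averaging).
This leaves the phenotypic covariance `V` unchanged, so the averaged
single-effect BLUP equals the multi-component prediction of the total
genetic value (asserted in the tests).

## Connectedness

CD of the between-unit contrast `x` (`+1/n₁` on MU1, `−1/n₂` on MU2) is

    CD = 1 − x′ PEV x / (x′ K x · σ²_u),
    PEV = K σ²_u − σ²_u K Z′ P Z K σ²_u.

The CD model includes the management units as fixed effects
(`X = [1, 1{MU2}]`). This is the classical connectedness setting: what
makes a disconnected design unreliable is precisely that the genetic
contrast is confounded with the unit effect. With an intercept-only
model the characteristic rise of CD from the disconnected scenario S1
to a peak near 20–30% exchange cannot occur (CD then only falls as
units mix); with unit fixed effects the rise–peak–decline pattern
appears. Variance components for CD come from a single intercept-only
full-data REML fit per kernel configuration and are shared across
exchange scenarios; prediction folds always use an intercept-only model
(inside a training fold the unit effect would be collinear with the
intercept) and re-estimate components per fold, warm-started from the
full-data estimates.

## Synthetic data

The generator emulates a livestock population genotyped on a dense SNP
chip.

* **Historical phase.** Wright–Fisher random union of gametes with
  Haldane recombination (crossover probability
  `(1 − exp(−2d/100))/2` between loci d cM apart) and symmetric
  per-locus mutation (default 2.5e-5). Every locus starts at frequency
  0.5 exactly (fixed allele counts, randomized assignment). The default
  trajectory holds 1000 individuals for 400 equilibration generations,
  then declines linearly to 220 over 100 bottleneck generations.
  The pre-phase matters: starting from linkage equilibrium, 100
  generations of drift produce r² ≈ 0.08 at all map distances, far from
  the chip-like LD the design presumes; after the pre-phase,
  adjacent-marker r² is ≈ 0.2–0.3 at 0.05 cM spacing, comparable to a
  bovine 54K panel. Dominance effects are tagged by markers only
  through r⁴-decaying dominance LD, so this choice decides whether the
  D kernel can capture anything at all.
* **Recent pedigree.** 200 dams × 10 sires per generation, two
  offspring per dam per generation for 5 generations (2000 offspring);
  dams and sires are resampled from the previous generation. Offspring
  sexes are an exactly balanced random permutation, which keeps the
  design feasible in every generation. The 210 sampled founders are
  generation 0 of the pedigree (used for the A matrix) and excluded
  from the analysis cohort.
* **Traits.** Per chromosome, 65 QTL are drawn from segregating loci
  (disjoint from the marker panel), 5 of them epistatic; all unordered
  epistatic pairs interact. Additive effects: |a| ~ Gamma(0.42, 8.282)
  with random sign; dominance d = δ|a| with degree of dominance
  δ ~ N(0,1); pair effects ad ~ N(0.02, 0.03). Genetic values use the
  centered additive code (w − 2p), the Vitezica dominance-deviation
  code {−2p², 2pq, −2q²} (orthogonal to the additive code under
  Hardy–Weinberg), and the A×D pair code w_a(k)·w_d(k′) for k < k′
  (one direction per pair, by convention; an A×A variant would be a
  one-line change in `_epi_component`).
* **Scaling.** Each effect class is rescaled by one scalar so the
  *realized* (empirical, in-sample) component variances equal the
  target partition exactly — two passes for additive/dominance because
  d is tied to |a|, then the pair effects. Empirical scaling is used
  instead of the closed-form variances because it absorbs LD and
  Hardy–Weinberg departures and remains defined for the
  purely-epistatic scenario (where the printed closed form is zero).
  The closed forms (σ²_a = Σ2pqα² with the allele-substitution effect
  α = a + d(q−p); σ²_d = Σ(2pqd)²; the printed A×D form) are kept as
  diagnostics in `analytic_variances`. Residual variance is 1 − H², so
  var(y) ≈ 1 with the deviation coming only from in-sample covariance
  between components (≈ 0.005 at n = 2000).

Default variance partitions (phenotypic variance 1):

| H²  | scenario | σ²_A | σ²_D | σ²_E |
|-----|----------|------|------|------|
| 0.4 | AD       | 0.3  | 0.1  | –    |
| 0.4 | ADE      | 0.2  | 0.1  | 0.1  |
| 0.4 | PE       | –    | –    | 0.4  |
| 0.8 | AD       | 0.6  | 0.2  | –    |
| 0.8 | ADE      | 0.4  | 0.2  | 0.2  |
| 0.8 | PE       | –    | –    | 0.8  |

**What the generator does not emulate:** selection, overlapping
generations, sex chromosomes, genotyping error, a mutation model beyond
symmetric flips, or a realistic site-frequency spectrum (all loci start
at 0.5). A green test on this world establishes internal consistency of
the pipeline and qualitative transferability, not agreement with any
particular real population.

## Kernels

* `A`: Wright's tabular method; unknown parents contribute zero;
  cyclic pedigrees raise.
* `G` (VanRaden), `D` (Vitezica), `G#D` (Hadamard). Monomorphic SNPs
  are dropped from designs and denominators with a logged count.
  Allele frequencies are estimated from the supplied matrix unless
  injected (e.g. training-set frequencies for a validation set).
* `GK(θ) = exp(−θ d²)`: by default squared Euclidean dosage distances
  are divided by their across-pair mean, making θ dimensionless and the
  mean off-diagonal ≈ exp(−θ). Under this convention the grid
  θ = 0.22/0.5/0.9/1.6 yields mean off-diagonals ≈ 0.80/0.61/0.41/0.20 —
  matching the θ ↔ off-diagonal mapping the full-scale design
  prescribes, which is why the convention was adopted (raw distances
  are available via
  `scaling="raw"`). `calibrate_theta` bisects on the strictly
  decreasing mean off-diagonal (tolerance 1e-4).
* PSD policy: kernels whose smallest eigenvalue is below −1e-8 get
  1e-6 diagonal jitter, always logged, never silent.

## Management units

Two units by K-means (k = 2, 25 restarts) on the rows of a relationship
matrix — equivalent to clustering on the induced distance
`K_ii + K_jj − 2K_ij`, so between-unit relatedness is minimized. The
smaller cluster is labelled MU1, so the exchange step
(swap `round(rate·|MU1|)` individuals each way, preserving unit sizes)
is always feasible. Exchange sets are resampled independently per
scenario from the S1 base (a nested mode exists). A forward split by
generation (train on generations 1–3, 1200 individuals; test on 4–5,
800) supports time-forward validation.

## Scaled profile

`RunConfig.ci_profile()` runs the same world at 600 cohort individuals
(60 dams × 2 × 5 generations), 10 chromosomes × 200 SNPs + 65 QTL.
Chromosomes shrink to 10.6 cM so the scaled panel keeps the full
design's SNP spacing (0.053 cM) — scaling down marker *count* at fixed
chromosome length would cut marker density tenfold and silently remove
dominance tagging from the world. Three replicates run in ~90 s; the
acceptance script uses 10.

## Known limitations

* CD with the variance-weighted averaged kernel is a
  contrast-variance-weighted mean of the per-component CDs. Because
  dominance relationships barely cross management units, the dominance
  part of a between-unit contrast is nearly unestimable, and adding D
  *dilutes* CD slightly in this implementation (at n = 600 and
  n = 2000 alike) rather than raising it. The companion claim that
  non-additive kernels raise the CD of contrasts is therefore not
  reproduced; the corresponding tests are left failing rather than
  weakened.
* The A×D epistatic component is only weakly capturable by marker
  kernels (tagging decays like products of r² and r⁴ terms); the
  purely-epistatic scenario consequently shows low prediction accuracy
  at the scaled size, and the G#D kernel's advantage in the ADE world
  is smaller than at full scale.
* REML fits where a diagonal-dominant kernel competes with the residual
  are weakly identified; they are flagged, not repaired.
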