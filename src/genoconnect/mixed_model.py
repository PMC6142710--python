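"""REML variance components, BLUP and prediction error variance.

Model: y = Xb + Zu + e with var(u) = sum_k K_k sigma2_k over one or more
relationship kernels and var(e) = I sigma2_e.  Records are mapped to kernel
individuals by a selection matrix Z (individuals without phenotypes are
still predicted through the kernel's train-test block).

Single-kernel fits use an exact eigendecomposition of the kernel projected
onto an orthonormal error-contrast basis, profiling out the residual
variance (fast; used heavily inside cross-validation folds).  Multi-kernel
fits use average-information REML with EM fallback steps.  For multi-kernel
models, BLUP / PEV / CD collapse the components onto the variance-weighted
averaged kernel, which leaves the phenotypic covariance V unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy.optimize import minimize_scalar

from .kernels import KernelMatrix, average_kernels

logger = logging.getLogger(__name__)


@dataclass
class ModelSpec:
    """Phenotypes, fixed-effect design, record-to-individual map, kernels."""

    y: np.ndarray
    kernels: Sequence[KernelMatrix]
    X: Optional[np.ndarray] = None
    obs_ids: Optional[np.ndarray] = None

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        n = len(self.y)
        if self.X is None:
            self.X = np.ones((n, 1))
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape[0] != n:
            raise ValueError("X rows must match y")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("X must have full column rank")
        base = self.kernels[0]
        for k in self.kernels[1:]:
            if not np.array_equal(k.ids, base.ids):
                raise ValueError("kernels must share identifiers")
        if self.obs_ids is None:
            if n != base.n:
                raise ValueError("obs_ids required when records != individuals")
            self.obs_ids = base.ids.copy()
        pos = pd.Index(base.ids).get_indexer(np.asarray(self.obs_ids))
        if (pos < 0).any():
            raise KeyError("record ids missing from the kernels")
        self.obs_idx = pos

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def n_individuals(self) -> int:
        return self.kernels[0].n


@dataclass
class VarianceComponents:
    sigma2_u: np.ndarray           # one variance per kernel
    sigma2_e: float
    loglik: float
    converged: bool
    n_iter: int = 0
    loglik_path: Optional[list] = None

    @property
    def h2(self) -> float:
        """Proportion of phenotypic variance marked by the kernels."""
        tot = float(np.sum(self.sigma2_u))
        return tot / (tot + self.sigma2_e)


@dataclass
class BLUPFit:
    """GLS fixed effects, predicted genetic values and PEV machinery."""

    b_hat: np.ndarray
    u_hat: np.ndarray              # aligned with kernel ids (train + test)
    ids: np.ndarray
    sigma2_u: float                # total genetic variance on the fitted kernel
    sigma2_e: float
    kernel: KernelMatrix           # the (possibly averaged) fitted kernel
    _P: np.ndarray = field(repr=False, default=None)
    _obs_idx: np.ndarray = field(repr=False, default=None)
    _pev: Optional[np.ndarray] = field(repr=False, default=None)

    @property
    def pev(self) -> np.ndarray:
        if self._pev is None:
            self._pev = prediction_error_variance(self)
        return self._pev


# ---------------------------------------------------------------------------
# Restricted likelihood helpers
# ---------------------------------------------------------------------------


def _build_V(spec: ModelSpec, sigma2_u, sigma2_e) -> np.ndarray:
    idx = spec.obs_idx
    V = np.eye(spec.n) * sigma2_e
    for s2, K in zip(np.atleast_1d(sigma2_u), spec.kernels):
        V += s2 * K.values[np.ix_(idx, idx)]
    return V


def restricted_loglik(y: np.ndarray, X: np.ndarray, V: np.ndarray) -> float:
    """REML log-likelihood -0.5[(n-p)log 2pi + log|V| + log|X'V^-1 X| + y'Py]."""
    n, p = X.shape
    cho = sla.cho_factor(V, lower=True)
    logdetV = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    VinvX = sla.cho_solve(cho, X)
    Vinvy = sla.cho_solve(cho, y)
    XtVinvX = X.T @ VinvX
    sign, logdetX = np.linalg.slogdet(XtVinvX)
    beta = np.linalg.solve(XtVinvX, VinvX.T @ y)
    yPy = float(y @ Vinvy - (X.T @ Vinvy) @ beta)
    return -0.5 * ((n - p) * np.log(2 * np.pi) + logdetV + logdetX + yPy)


def _error_contrasts(X: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the null space of X' (error contrasts)."""
    return sla.null_space(X.T)


def _reml_one_kernel(spec: ModelSpec, tol: float) -> VarianceComponents:
    """Exact single-kernel REML via eigendecomposition and profiling.

    On the error-contrast basis B, B'VB = sigma2_e (lambda M + I) with
    M = B'(ZKZ')B; after rotating by M's eigenvectors the restricted
    likelihood is a smooth 1-D function of the ratio
    lambda = sigma2_u / sigma2_e, and sigma2_e has a closed form.
    """
    idx = spec.obs_idx
    K = spec.kernels[0].values[np.ix_(idx, idx)]
    B = _error_contrasts(spec.X)
    Mt = B.T @ K @ B
    yt = B.T @ spec.y
    w, U = np.linalg.eigh(Mt)
    w = np.maximum(w, 0.0)
    z = U.T @ yt
    m = len(yt)

    def negll(t):
        lam = np.exp(t)
        denom = lam * w + 1.0
        s2e = float(np.mean(z ** 2 / denom))
        return 0.5 * (np.sum(np.log(denom)) + m * np.log(max(s2e, 1e-300)))

    res = minimize_scalar(negll, bounds=(-25.0, 25.0), method="bounded",
                          options={"xatol": 1e-10})
    lam = float(np.exp(res.x))
    denom = lam * w + 1.0
    s2e = float(np.mean(z ** 2 / denom))
    s2u = lam * s2e
    ll = restricted_loglik(spec.y, spec.X, _build_V(spec, [s2u], s2e))
    return VarianceComponents(np.array([s2u]), s2e, ll, True, 1)


def _reml_ai(spec: ModelSpec, max_iter: int, tol: float,
             method: str, start=None) -> VarianceComponents:
    """AI-REML over (sigma2_1..sigma2_K, sigma2_e) with EM fallback.

    AI updates use the average-information matrix; when a proposal leaves
    the parameter space or decreases the restricted likelihood, the
    iteration falls back to the (monotone) EM-style gradient step
    sigma2_new = sigma2 + sigma2^2 (y'P V_k P y - tr(P V_k)) / n.
    """
    y, X = spec.y, spec.X
    n = spec.n
    idx = spec.obs_idx
    Vks = [K.values[np.ix_(idx, idx)] for K in spec.kernels]
    nk = len(Vks)
    vary = float(np.var(y))
    floor = 1e-8 * max(vary, 1e-12)
    if start is not None:
        theta = np.maximum(np.asarray(start, dtype=float), floor)
        if len(theta) != nk + 1:
            raise ValueError("start must hold one variance per kernel "
                             "plus the residual")
    else:
        theta = np.full(nk + 1, vary / (nk + 1))

    def components(theta):
        V = np.eye(n) * theta[-1]
        for s2, Vk in zip(theta[:-1], Vks):
            V += s2 * Vk
        cho = sla.cho_factor(V, lower=True)
        Vinv = sla.cho_solve(cho, np.eye(n))
        VinvX = Vinv @ X
        XtVinvX = X.T @ VinvX
        P = Vinv - VinvX @ np.linalg.solve(XtVinvX, VinvX.T)
        logdetV = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
        _, logdetX = np.linalg.slogdet(XtVinvX)
        Py = P @ y
        ll = -0.5 * ((n - X.shape[1]) * np.log(2 * np.pi)
                     + logdetV + logdetX + float(y @ Py))
        return P, Py, ll

    def em_step(theta, P, Py):
        new = theta.copy()
        for k in range(nk):
            VkPy = Vks[k] @ Py
            grad = float(Py @ VkPy) - float(np.sum(P * Vks[k]))
            new[k] = theta[k] + theta[k] ** 2 * grad / n
        grad_e = float(Py @ Py) - float(np.trace(P))
        new[-1] = theta[-1] + theta[-1] ** 2 * grad_e / n
        return np.maximum(new, floor)

    P, Py, ll = components(theta)
    path = [ll]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if method == "em":
            proposal = em_step(theta, P, Py)
            P_new, Py_new, ll_new = components(proposal)
        else:
            mats = [Vk @ Py for Vk in Vks] + [Py]
            score = np.empty(nk + 1)
            for k in range(nk):
                score[k] = -0.5 * (float(np.sum(P * Vks[k]))
                                   - float(Py @ mats[k]))
            score[-1] = -0.5 * (float(np.trace(P)) - float(Py @ Py))
            # active-set step: a component parked at the floor whose
            # gradient points further down stays frozen this iteration
            # (the residual included: a diag-dominant kernel can absorb it)
            active = (theta > 10 * floor) | (score > 0)
            if not active.any():
                converged = True
                break
            idx_a = np.where(active)[0]
            Pm = [P @ mats[i] for i in idx_a]
            AI = 0.5 * np.array([[float(mats[i] @ Pm[jj])
                                  for jj in range(len(idx_a))]
                                 for i in idx_a])
            try:
                delta_a = np.linalg.solve(AI, score[idx_a])
                # damp the step so no component falls below half its
                # current value (keeps the AI direction near a bound)
                with np.errstate(divide="ignore", invalid="ignore"):
                    limits = np.where(theta[idx_a] + delta_a < floor,
                                      -0.5 * theta[idx_a] / delta_a, 1.0)
                t = float(np.clip(np.min(limits), 0.0, 1.0))
                if t < 1e-3:
                    proposal = em_step(theta, P, Py)
                else:
                    proposal = np.full(nk + 1, floor)
                    proposal[idx_a] = np.maximum(theta[idx_a] + t * delta_a,
                                                 floor)
            except np.linalg.LinAlgError:
                proposal = em_step(theta, P, Py)
            P_new, Py_new, ll_new = components(proposal)
            if ll_new < ll - 1e-10:
                for _ in range(8):
                    proposal = np.maximum(theta + 0.5 * (proposal - theta),
                                          floor)
                    P_new, Py_new, ll_new = components(proposal)
                    if ll_new >= ll - 1e-10:
                        break
                else:
                    proposal = em_step(theta, P, Py)
                    P_new, Py_new, ll_new = components(proposal)
            # boundary acceleration: a tiny component the gradient keeps
            # pushing down is tested directly at the floor, accepted only
            # if the restricted likelihood does not drop
            small = (proposal < 1e-3 * vary) & (score < 0) & \
                    (proposal > floor)
            if small.any():
                cand = proposal.copy()
                cand[small] = floor
                P_c, Py_c, ll_c = components(cand)
                if ll_c >= ll_new - 1e-10:
                    proposal, P_new, Py_new, ll_new = cand, P_c, Py_c, ll_c
        # change measured against the total variance, so components parked
        # at the floor cannot stall convergence
        rel = float(np.max(np.abs(proposal - theta)) / max(theta.sum(), floor))
        theta, P, Py = proposal, P_new, Py_new
        path.append(ll_new)
        if rel < tol or abs(ll_new - ll) < 1e-9:
            ll = ll_new
            converged = True
            break
        ll = ll_new
    if not converged:
        logger.warning("REML did not converge in %d iterations", max_iter)
    return VarianceComponents(theta[:-1].copy(), float(theta[-1]), ll,
                              converged, it, path)


def reml_estimate(spec: ModelSpec, max_iter: int = 200, tol: float = 1e-6,
                  method: str = "auto", start=None) -> VarianceComponents:
    """Estimate variance components by REML.

    ``method``: 'auto' (eigendecomposition path for one kernel, AI-REML
    otherwise), 'ai', or 'em' (monotone EM-style steps only).  ``start``
    warm-starts the iterative path with (sigma2_1..sigma2_K, sigma2_e),
    e.g. full-data estimates when refitting inside a cross-validation fold.
    """
    if method == "auto" and len(spec.kernels) == 1:
        return _reml_one_kernel(spec, tol)
    ai_method = "em" if method == "em" else "ai"
    return _reml_ai(spec, max_iter, tol, ai_method, start=start)


# ---------------------------------------------------------------------------
# BLUP and PEV
# ---------------------------------------------------------------------------


def _collapse(kernels, sigma2_u) -> tuple:
    """Averaged kernel and the summed genetic variance it carries."""
    s2 = np.atleast_1d(np.asarray(sigma2_u, dtype=float))
    total = float(s2.sum())
    if len(kernels) == 1:
        return kernels[0], total
    return average_kernels(kernels, s2), total


def fit_blup(spec: ModelSpec, vc: VarianceComponents) -> BLUPFit:
    """GLS fixed effects and BLUP of genetic values.

    u_hat = sigma2_u K Z' V^-1 (y - X b_hat), evaluated for *all* kernel
    individuals, so unphenotyped individuals are predicted through the
    train-test kernel block.  Multi-kernel components are collapsed onto
    the variance-weighted averaged kernel (identical V).
    """
    K_fit, s2u = _collapse(spec.kernels, vc.sigma2_u)
    s2e = vc.sigma2_e
    idx = spec.obs_idx
    Koo = K_fit.values[np.ix_(idx, idx)]
    n = spec.n
    V = s2u * Koo + s2e * np.eye(n)
    cho = sla.cho_factor(V, lower=True)
    Vinv = sla.cho_solve(cho, np.eye(n))
    X = spec.X
    VinvX = Vinv @ X
    XtVinvX = X.T @ VinvX
    if np.linalg.cond(XtVinvX) > 1e12:
        logger.warning("rank-deficient fixed effects; using pseudo-inverse")
        b = np.linalg.pinv(XtVinvX) @ (VinvX.T @ spec.y)
    else:
        b = np.linalg.solve(XtVinvX, VinvX.T @ spec.y)
    resid = spec.y - X @ b
    alpha = Vinv @ resid
    u = s2u * (K_fit.values[:, idx] @ alpha)
    P = Vinv - VinvX @ np.linalg.solve(XtVinvX, VinvX.T)
    return BLUPFit(b, u, K_fit.ids.copy(), s2u, s2e, K_fit, P, idx)


def prediction_error_variance(fit: BLUPFit, spec: ModelSpec = None,
                              vc: VarianceComponents = None) -> np.ndarray:
    """PEV = var(u_hat - u) = K sigma2_u - sigma2_u K Z' P Z K sigma2_u.

    Equals sigma2_e times the random-effect block of the inverted mixed
    model equations (cross-checked in the test-suite via solve_mme).
    """
    K = fit.kernel.values
    idx = fit._obs_idx
    KZt = K[:, idx]
    return fit.sigma2_u * K - (fit.sigma2_u ** 2) * (KZt @ fit._P @ KZt.T)


def solve_mme(y, X, K, obs_idx, sigma2_u, sigma2_e):
    """Henderson's mixed-model equations (dense, for cross-checks).

    Returns (b_hat, u_hat, PEV) with PEV = sigma2_e * C^uu, the
    random-effect block of the inverse coefficient matrix.
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    K = np.asarray(K, float)
    n, p = X.shape
    q = K.shape[0]
    Z = np.zeros((n, q))
    Z[np.arange(n), obs_idx] = 1.0
    Kinv = np.linalg.inv(K)
    lam = sigma2_e / sigma2_u
    C = np.block([[X.T @ X, X.T @ Z],
                  [Z.T @ X, Z.T @ Z + Kinv * lam]])
    rhs = np.concatenate([X.T @ y, Z.T @ y])
    sol = np.linalg.solve(C, rhs)
    Cinv = np.linalg.inv(C)
    pev = sigma2_e * Cinv[p:, p:]
    return sol[:p], sol[p:], pev
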