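"""Pedigree and genomic relationship kernel matrices.

Implements the numerator relationship matrix A (Wright's tabular method),
the VanRaden additive genomic matrix G, the Vitezica dominance matrix D,
the Hadamard epistatic product G#D, a Gaussian kernel GK over marker
distances (with a calibration routine for its smoothing parameter), and
variance-weighted kernel averaging.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from .simulate import GenotypeMatrix, Pedigree

logger = logging.getLogger(__name__)

#: eigenvalue floor below which a kernel is considered numerically indefinite
PSD_TOL = -1e-8
#: diagonal jitter added (and logged) when a kernel violates the floor
PSD_JITTER = 1e-6


@dataclass
class KernelMatrix:
    """Symmetric positive semidefinite relationship matrix with identifiers.

    ``kind`` tags the construction: A, G, D, GxD, GK or averaged.
    """

    values: np.ndarray
    ids: np.ndarray
    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("kernel must be square")
        if len(self.ids) != v.shape[0]:
            raise ValueError("ids do not match kernel dimension")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])

    def ensure_psd(self, tol: float = PSD_TOL,
                   jitter: float = PSD_JITTER) -> "KernelMatrix":
        """Add diagonal jitter (logged, never silent) if indefinite."""
        lam = self.min_eigenvalue()
        if lam < tol:
            logger.warning("kernel %s has min eigenvalue %.3e; adding "
                           "jitter %.1e to the diagonal", self.kind, lam, jitter)
            vals = self.values + jitter * np.eye(self.n)
            return KernelMatrix(vals, self.ids.copy(), self.kind,
                                {**self.params, "jitter": jitter})
        return self

    def subset(self, ids) -> "KernelMatrix":
        pos = pd.Index(self.ids).get_indexer(np.asarray(ids))
        if (pos < 0).any():
            raise KeyError("unknown ids requested from kernel")
        return KernelMatrix(self.values[np.ix_(pos, pos)],
                            np.asarray(ids).copy(), self.kind, dict(self.params))

    # -- serialization ------------------------------------------------------

    def write_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.ids,
                     columns=self.ids).to_csv(path, sep="\t",
                                              index_label=self.kind)

    @classmethod
    def read_tsv(cls, path) -> "KernelMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        kind = df.index.name or "K"
        ids = np.array([_maybe_int(i) for i in df.index])
        return cls(df.to_numpy(dtype=float), ids, kind)

    def write_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("values", data=self.values)
            f.create_dataset("ids", data=np.asarray(self.ids, dtype="S"))
            f.attrs["kind"] = self.kind
            f.attrs["params"] = json.dumps(self.params, default=float)

    @classmethod
    def read_hdf5(cls, path) -> "KernelMatrix":
        import h5py

        with h5py.File(path, "r") as f:
            vals = f["values"][...]
            ids = np.array([_maybe_int(i.decode()) for i in f["ids"][...]])
            kind = f.attrs["kind"]
            params = json.loads(f.attrs["params"])
        return cls(vals, ids, kind, params)


def _maybe_int(x):
    try:
        return int(x)
    except (TypeError, ValueError):
        return x


# ---------------------------------------------------------------------------
# Pedigree relationship
# ---------------------------------------------------------------------------


def numerator_relationship(pedigree: Pedigree) -> KernelMatrix:
    """Wright's numerator relationship matrix A via the tabular method.

    A_ii = 1 + A(sire, dam)/2; A_ij = (A(j, sire_i) + A(j, dam_i))/2 for j
    preceding i; unknown parents contribute zero.  The pedigree is sorted
    parents-before-offspring internally (cycles raise).
    """
    ped = pedigree.topo_sort()
    tab = ped.table
    ids = tab["id"].to_numpy()
    pos = {iid: i for i, iid in enumerate(ids)}
    sire = np.array([pos.get(s, -1) for s in tab["sire"]])
    dam = np.array([pos.get(d, -1) for d in tab["dam"]])
    n = len(ids)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
        if i == 0:
            continue
        row = np.zeros(i)
        if s >= 0:
            row += A[s, :i]
        if d >= 0:
            row += A[d, :i]
        A[i, :i] = 0.5 * row
        A[:i, i] = A[i, :i]
    return KernelMatrix(A, ids, "A")


# ---------------------------------------------------------------------------
# Genomic kernels
# ---------------------------------------------------------------------------


def _polymorphic(genotypes: GenotypeMatrix, freqs):
    p = genotypes.allele_freqs if freqs is None else np.asarray(freqs, float)
    keep = (p > 0.0) & (p < 1.0)
    if not keep.any():
        raise ValueError("all SNPs are monomorphic")
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropping %d monomorphic SNPs", dropped)
    return genotypes.dosages[:, keep].astype(float), p[keep]


def additive_kernel(genotypes: GenotypeMatrix, freqs=None) -> KernelMatrix:
    """VanRaden additive genomic relationship matrix.

    G = Wa Wa' / (2 sum p_k q_k) with Wa the dosage matrix column-centered
    by twice the allele frequency.
    """
    W, p = _polymorphic(genotypes, freqs)
    q = 1.0 - p
    Wa = W - 2.0 * p
    den = 2.0 * float(np.sum(p * q))
    G = (Wa @ Wa.T) / den
    return KernelMatrix(G, genotypes.ids.copy(), "G", {"m": W.shape[1]})


def dominance_kernel(genotypes: GenotypeMatrix, freqs=None) -> KernelMatrix:
    """Vitezica dominance relationship matrix.

    Codes {-2p^2, 2pq, -2q^2} for dosages {0, 1, 2};
    D = Wd Wd' / sum (2 p_k q_k)^2.
    """
    W, p = _polymorphic(genotypes, freqs)
    q = 1.0 - p
    Wd = np.where(W == 0, -2.0 * p ** 2,
                  np.where(W == 1, 2.0 * p * q, -2.0 * q ** 2))
    den = float(np.sum((2.0 * p * q) ** 2))
    D = (Wd @ Wd.T) / den
    return KernelMatrix(D, genotypes.ids.copy(), "D", {"m": W.shape[1]})


def hadamard_kernel(G: KernelMatrix, D: KernelMatrix) -> KernelMatrix:
    """Element-wise (Hadamard) product kernel, e.g. additive-by-dominance."""
    if G.n != D.n or not np.array_equal(G.ids, D.ids):
        raise ValueError("kernels must share identifiers in the same order")
    return KernelMatrix(G.values * D.values, G.ids.copy(), "GxD",
                        {"components": [G.kind, D.kind]})


def _sq_distances(genotypes: GenotypeMatrix, scaling: str) -> np.ndarray:
    """Pairwise squared Euclidean marker distances, optionally normalized by
    their across-pair mean (making the smoothing parameter dimensionless)."""
    X = genotypes.dosages.astype(float)
    d2 = squareform(pdist(X, "sqeuclidean"))
    if scaling == "mean":
        off = d2[np.triu_indices_from(d2, k=1)]
        m = float(off.mean())
        if m > 0:
            d2 = d2 / m
    elif scaling != "raw":
        raise ValueError("scaling must be 'mean' or 'raw'")
    return d2


def gaussian_kernel(genotypes: GenotypeMatrix, theta: float,
                    scaling: str = "mean") -> KernelMatrix:
    """Gaussian kernel GK(i, j) = exp(-theta * d_ij^2) over marker dosages.

    Small theta gives a global kernel (entries near 1); large theta a local
    one (off-diagonals near 0).  With the default mean scaling the mean
    off-diagonal entry is approximately exp(-theta).
    """
    if theta <= 0:
        raise ValueError("theta must be > 0")
    d2 = _sq_distances(genotypes, scaling)
    K = np.exp(-theta * d2)
    np.fill_diagonal(K, 1.0)
    return KernelMatrix(K, genotypes.ids.copy(), "GK",
                        {"theta": float(theta), "scaling": scaling})


def calibrate_theta(genotypes: GenotypeMatrix, target_mean_offdiag: float,
                    scaling: str = "mean", tol: float = 1e-4,
                    max_iter: int = 200) -> float:
    """Bisection for the theta whose mean off-diagonal GK entry hits the
    target; the mean is strictly decreasing in theta, so the root is unique."""
    if not (0.0 < target_mean_offdiag < 1.0):
        raise ValueError("target must be in (0, 1)")
    if genotypes.n_individuals < 2:
        raise ValueError("need at least two individuals")
    d2 = _sq_distances(genotypes, scaling)
    off = d2[np.triu_indices_from(d2, k=1)]

    def mean_off(theta):
        return float(np.exp(-theta * off).mean())

    lo, hi = 0.0, 1.0
    while mean_off(hi) > target_mean_offdiag:
        hi *= 2.0
        if hi > 1e12:
            raise RuntimeError("failed to bracket theta")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        m = mean_off(mid)
        if abs(m - target_mean_offdiag) < tol:
            return mid
        if m > target_mean_offdiag:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def average_kernels(kernels: Sequence[KernelMatrix],
                    variances: Sequence[float]) -> KernelMatrix:
    """Variance-weighted kernel average (multiple kernel learning).

    K = sum_k (sigma2_k / sum sigma2) K_k; the weights are each component's
    share of the marked total genetic variance.
    """
    if len(kernels) != len(variances):
        raise ValueError("one variance per kernel required")
    v = np.asarray(variances, dtype=float)
    if (v < 0).any():
        raise ValueError("variances must be non-negative")
    total = v.sum()
    if total <= 0:
        raise ValueError("variances must not all be zero")
    ids = kernels[0].ids
    for k in kernels[1:]:
        if k.n != kernels[0].n or not np.array_equal(k.ids, ids):
            raise ValueError("kernels must share identifiers in the same order")
    if len(kernels) == 1:
        return kernels[0]
    w = v / total
    K = np.zeros_like(kernels[0].values)
    for wk, k in zip(w, kernels):
        K += wk * k.values
    return KernelMatrix(K, ids.copy(), "averaged",
                        {"weights": w.tolist(),
                         "components": [k.kind for k in kernels]})
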