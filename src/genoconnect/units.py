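"""Management-unit construction: clustering, exchange scenarios, contrasts.

Two management units are formed by K-means clustering of a relationship
matrix (pedigree A by default; G or G+D also accepted), then progressively
connected by symmetrically swapping a fraction of individuals between the
units (scenarios S1 = no exchange up to S6 = 50% exchange).  A forward
split by generation supports time-forward validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from numpy.random import SeedSequence, default_rng

from .kernels import KernelMatrix
from .simulate import Pedigree, _rng

logger = logging.getLogger(__name__)

DEFAULT_RATES = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)


@dataclass
class UnitAssignment:
    """Partition of individuals into management units MU1 / MU2."""

    ids: np.ndarray
    units: np.ndarray              # int8 array of 1 / 2
    exchange_rate: float = 0.0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.ids) != len(self.units):
            raise ValueError("ids and units differ in length")
        present = set(np.unique(self.units))
        if not present <= {1, 2}:
            raise ValueError("units must be labelled 1 or 2")
        if present != {1, 2}:
            raise ValueError("both units must be non-empty")

    @property
    def mu1(self) -> np.ndarray:
        return self.ids[self.units == 1]

    @property
    def mu2(self) -> np.ndarray:
        return self.ids[self.units == 2]

    def write_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"id": self.ids, "unit": self.units}).to_csv(
            path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "UnitAssignment":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        return cls(df["id"].to_numpy(), df["unit"].to_numpy(np.int8))


@dataclass
class ContrastVector:
    """Between-unit contrast: +1/n1 on MU1, -1/n2 on MU2, 0 elsewhere."""

    x: np.ndarray
    ids: np.ndarray

    def __post_init__(self):
        if abs(self.x.sum()) > 1e-10:
            raise ValueError("contrast coefficients must sum to zero")


def _seed_int(seed) -> Optional[int]:
    """Deterministic 31-bit int for APIs wanting an integer random_state."""
    if seed is None:
        return None
    if isinstance(seed, SeedSequence):
        return int(seed.generate_state(1)[0] >> 1)
    return int(seed) % (2 ** 31)


def cluster_units(relationship: KernelMatrix, k: int = 2, seed=None,
                  n_restarts: int = 25) -> UnitAssignment:
    """K-means (k=2) on the rows of a relationship matrix.

    Using rows of K as feature vectors is equivalent to clustering on the
    induced distance d^2_ij = K_ii + K_jj - 2 K_ij, so between-unit
    relatedness is minimized.  Unit 1 is the cluster containing the first
    individual (canonical labelling, making results seed-reproducible).
    """
    from sklearn.cluster import KMeans

    n = relationship.n
    if n < 2 * k:
        raise ValueError("need at least 2k individuals")
    X = relationship.values
    if np.allclose(X, X[0]):
        raise ValueError("degenerate relationship matrix: all rows equal")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=_seed_int(seed))
    labels = km.fit_predict(X)
    if len(np.unique(labels)) < k:
        raise ValueError("clustering produced an empty unit")
    # MU1 is the smaller cluster (ties: the first individual's cluster), so
    # a swap of round(rate * |MU1|) individuals always fits inside MU2
    n_first = int(np.sum(labels == labels[0]))
    small_first = n_first < len(labels) - n_first or (
        2 * n_first == len(labels))
    units = np.where((labels == labels[0]) == small_first, 1, 2).astype(np.int8)
    return UnitAssignment(relationship.ids.copy(), units, 0.0,
                          {"kernel": relationship.kind,
                           "inertia": float(km.inertia_)})


def apply_exchange(assignment: UnitAssignment, rate: float, seed=None,
                   mode: str = "swap") -> UnitAssignment:
    """Exchange a fraction of individuals between MU1 and MU2.

    ``swap`` (default) moves round(rate * |MU1|) uniformly chosen MU1
    individuals to MU2 and equally many the other way, preserving unit
    sizes; ``move`` only transfers from MU1 to MU2.
    """
    if not (0.0 <= rate <= 0.5):
        raise ValueError("exchange rate must be in [0, 0.5]")
    if rate == 0.0:
        return replace(assignment, exchange_rate=0.0)
    rng = _rng(seed)
    units = assignment.units.copy()
    i1 = np.where(units == 1)[0]
    i2 = np.where(units == 2)[0]
    n_swap = int(round(rate * len(i1)))
    if n_swap > len(i2) and mode == "swap":
        raise ValueError("MU2 too small for the requested exchange")
    out1 = rng.choice(i1, n_swap, replace=False)
    units[out1] = 2
    if mode == "swap":
        out2 = rng.choice(i2, n_swap, replace=False)
        units[out2] = 1
    elif mode != "move":
        raise ValueError("mode must be 'swap' or 'move'")
    return UnitAssignment(assignment.ids.copy(), units, rate,
                          {**assignment.provenance, "mode": mode})


def scenario_grid(base: UnitAssignment, rates=DEFAULT_RATES, seed=None,
                  nested: bool = False, mode: str = "swap") -> dict:
    """S1..Sk assignments from one base clustering.

    By default the exchanged sets are resampled independently per scenario
    from the S1 base; ``nested=True`` grows each scenario's swap set from
    the previous one.
    """
    ss = SeedSequence(seed) if not isinstance(seed, SeedSequence) else seed
    children = ss.spawn(len(rates))
    out = {}
    prev = base
    prev_rate = 0.0
    for i, (rate, child) in enumerate(zip(rates, children), start=1):
        if nested and rate > 0:
            # incremental swap on top of the previous scenario
            n1 = len(prev.mu1)
            extra = (rate - prev_rate)
            prev = apply_exchange(prev, extra * len(base.mu1) / max(n1, 1),
                                  seed=child, mode=mode)
            out[f"S{i}"] = replace(prev, exchange_rate=rate)
            prev_rate = rate
        else:
            out[f"S{i}"] = apply_exchange(base, rate, seed=child, mode=mode)
    return out


def contrast_vector(assignment: UnitAssignment) -> ContrastVector:
    """Contrast of unit means: sums to zero by construction."""
    n1 = int((assignment.units == 1).sum())
    n2 = int((assignment.units == 2).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("both units must be non-empty")
    x = np.where(assignment.units == 1, 1.0 / n1, -1.0 / n2)
    return ContrastVector(x, assignment.ids.copy())


def forward_split(pedigree: Pedigree, train_generations,
                  ids=None) -> UnitAssignment:
    """MU1 = individuals in the training generations, MU2 = the rest.

    ``ids`` restricts the split to a subset (e.g. the analysis cohort).
    """
    tab = pedigree.table
    if ids is not None:
        tab = tab[tab["id"].isin(np.asarray(ids))]
    gens = set(int(g) for g in np.atleast_1d(list(train_generations)))
    units = np.where(tab["generation"].isin(gens), 1, 2).astype(np.int8)
    if (units == 1).sum() == 0 or (units == 2).sum() == 0:
        raise ValueError("forward split leaves one side empty")
    return UnitAssignment(tab["id"].to_numpy(), units, 0.0,
                          {"kind": "forward", "train_generations": sorted(gens)})
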