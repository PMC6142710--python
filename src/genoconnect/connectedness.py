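"""Connectedness statistics: CD of contrasts and PEVD.

The coefficient of determination (CD) of a between-unit contrast x is

    CD = 1 - x' PEV x / (x' K x * sigma2_u),

the squared correlation between the predicted and the true difference in
genetic values.  Large CD means across-unit comparisons of predicted
genetic values are reliable; the denominator penalizes designs whose units
have little genetic variability between them.  PEVD = x' PEV x is the
prediction error variance of the difference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .kernels import KernelMatrix
from .units import ContrastVector


@dataclass
class ConnectednessResult:
    cd: float
    pevd: float
    numerator: float               # x' PEV x
    denominator: float             # x' K x * sigma2_u
    contrast: np.ndarray
    kernel_kind: str = ""
    scenario: str = ""


def _as_vector(x) -> np.ndarray:
    if isinstance(x, ContrastVector):
        return x.x
    return np.asarray(x, dtype=float)


def pevd_of_contrast(x, PEV: np.ndarray) -> float:
    """Prediction error variance of the contrast difference, x' PEV x."""
    v = _as_vector(x)
    return float(v @ PEV @ v)


def cd_of_contrast(x, K: Union[KernelMatrix, np.ndarray], PEV: np.ndarray,
                   sigma2_u: float, scenario: str = "") -> ConnectednessResult:
    """CD of a unit contrast from a kernel, its variance, and the PEV matrix.

    CD = 1 when the contrast is perfectly estimated (PEV = 0) and 0 when
    the data are uninformative (PEV = K sigma2_u).  Invariant to flipping
    the contrast's sign.
    """
    v = _as_vector(x)
    kind = K.kind if isinstance(K, KernelMatrix) else "K"
    Kv = K.values if isinstance(K, KernelMatrix) else np.asarray(K, float)
    den = float(v @ Kv @ v) * float(sigma2_u)
    if den <= 0:
        raise ValueError("contrast carries no genetic variance (x'Kx <= 0)")
    num = pevd_of_contrast(v, PEV)
    return ConnectednessResult(cd=1.0 - num / den, pevd=num, numerator=num,
                               denominator=den, contrast=v,
                               kernel_kind=kind, scenario=scenario)
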