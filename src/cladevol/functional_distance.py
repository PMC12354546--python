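"""Functional distances and their per-cluster decomposition.

A pairwise Type-I coefficient θ maps to a functional distance
d_F = −ln(1 − θ), which is additive over clusters:
d_F(A,B) = b_F(A) + b_F(B), where b_F(x) is the functional branch length of
cluster x — how much site-specific rate change accumulated on x's side of
the split.  For exactly three clusters the decomposition is closed-form,

    b_F(A) = (d_F(A,B) + d_F(A,C) − d_F(B,C)) / 2   (and cyclically),

and for n ≥ 3 clusters a least-squares fit of the additive model minimizes
Σ_{i<j} (d_ij − b_i − b_j)²; at n = 3 the two coincide with zero residual.
Negative b_F (distances violating star additivity) are reported as computed
with a warning, never truncated.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ThetaMatrix",
    "FunctionalDistanceResult",
    "functional_distance",
    "distance_matrix",
    "bf_three_clusters",
    "bf_least_squares",
    "decompose",
]


@dataclass
class ThetaMatrix:
    """Symmetric matrix of pairwise Type-I θ estimates for ≥3 clusters."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("theta matrix shape mismatch")
        if n < 3:
            raise ValueError("need at least 3 clusters")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("theta matrix must be symmetric")
        off = self.values[~np.eye(n, dtype=bool)]
        if np.any(off >= 1):
            raise ValueError("theta must be < 1 for finite distances")


@dataclass
class FunctionalDistanceResult:
    labels: list[str]
    d_f: np.ndarray
    b_f: np.ndarray
    method: str
    residual: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cluster": self.labels, "b_F": self.b_f}
        )


def functional_distance(theta: float, clamp_negative: bool = False) -> float:
    """d_F = −ln(1 − θ).  θ ≥ 1 is an infinite distance (error)."""
    if theta >= 1:
        raise ValueError(f"theta = {theta} >= 1: infinite functional distance")
    if theta < 0:
        if not clamp_negative:
            raise ValueError(f"negative theta {theta}; pass clamp_negative=True "
                             "to treat as 0")
        theta = 0.0
    # log1p keeps d_F strictly increasing down to subnormal theta
    return -math.log1p(-theta)


def distance_matrix(thetas: ThetaMatrix, clamp_negative: bool = False) -> np.ndarray:
    n = len(thetas.labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = functional_distance(
                thetas.values[i, j], clamp_negative=clamp_negative
            )
    return d


def bf_three_clusters(
    d_ab: float, d_ac: float, d_bc: float
) -> tuple[float, float, float]:
    """Closed-form three-cluster decomposition of pairwise d_F."""
    for d in (d_ab, d_ac, d_bc):
        if not np.isfinite(d):
            raise ValueError("non-finite functional distance")
    b_a = (d_ab + d_ac - d_bc) / 2.0
    b_b = (d_ab + d_bc - d_ac) / 2.0
    b_c = (d_ac + d_bc - d_ab) / 2.0
    if min(b_a, b_b, b_c) < 0:
        warnings.warn("negative functional branch length: distances violate "
                      "star additivity")
    return b_a, b_b, b_c


def bf_least_squares(d: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares b_F for n ≥ 3 clusters under the additive model.

    Minimizes Σ_{i<j} (d_ij − b_i − b_j)²; returns (b, residual sum of
    squares).  For n = 3 this equals the closed form exactly with zero
    residual.
    """
    d = np.asarray(d, float)
    n = d.shape[0]
    if d.shape != (n, n) or n < 3:
        raise ValueError("need a square distance matrix over >= 3 clusters")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite distances")
    rows, targets = [], []
    for i in range(n):
        for j in range(i + 1, n):
            row = np.zeros(n)
            row[i] = row[j] = 1.0
            rows.append(row)
            targets.append(d[i, j])
    A = np.array(rows)
    y = np.array(targets)
    b, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = float(np.sum((A @ b - y) ** 2))
    if np.any(b < 0):
        warnings.warn("negative functional branch length in least-squares fit")
    return b, resid


def decompose(
    thetas: ThetaMatrix,
    method: str = "closed-form",
    clamp_negative_theta: bool = False,
) -> FunctionalDistanceResult:
    """θ matrix → d_F matrix → per-cluster b_F.

    ``method="closed-form"`` requires exactly 3 clusters;
    ``method="least-squares"`` works for any n ≥ 3.
    """
    d = distance_matrix(thetas, clamp_negative=clamp_negative_theta)
    n = len(thetas.labels)
    if method == "closed-form":
        if n != 3:
            raise ValueError("closed form is defined for exactly 3 clusters")
        b = np.array(bf_three_clusters(d[0, 1], d[0, 2], d[1, 2]))
        resid = 0.0
    elif method == "least-squares":
        b, resid = bf_least_squares(d)
    else:
        raise ValueError(f"unknown method {method!r}")
    return FunctionalDistanceResult(
        labels=list(thetas.labels), d_f=d, b_f=np.asarray(b), method=method,
        residual=resid,
    )
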