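"""Decomposition of a multi-objective problem into scalar subproblems.

A simplex-lattice design generates N = C(H+M-1, M-1) weight vectors on the
unit simplex; each defines one subproblem via the penalty-based boundary
intersection (PBI) scalarization

    g(F | lambda, z*) = d1 + theta * d2,

where d1 is the distance travelled along the ray z* + t*lambda (convergence
term) and d2 the perpendicular deviation of F from that ray (direction
error / diversity term). Subproblems exchange information through a
neighborhood B(i): the T weight vectors closest to lambda_i in Euclidean
distance, i itself included.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
from scipy.spatial.distance import cdist

from .errors import InvalidArgumentError

__all__ = [
    "PBIResult",
    "simplex_lattice",
    "build_neighborhoods",
    "pbi_aggregate",
    "penalty_schedule",
    "update_ideal",
]


@dataclass(frozen=True)
class PBIResult:
    """Components of the PBI scalarization: g = d1 + theta * d2."""

    d1: float
    d2: float
    g: float


def simplex_lattice(H: int, M: int = 3) -> np.ndarray:
    """Weight vectors of the simplex-lattice design with H divisions.

    Returns an (N, M) array with N = C(H+M-1, M-1); every component is a
    multiple of 1/H and each row sums to 1. Rows are in lexicographic order
    of the underlying integer compositions, so subproblem indices are
    reproducible.
    """
    if H < 1:
        raise InvalidArgumentError("H must be >= 1")
    if M < 2:
        raise InvalidArgumentError("M must be >= 2")

    def compositions(total: int, parts: int):
        if parts == 1:
            yield (total,)
            return
        for first in range(total + 1):
            for rest in compositions(total - first, parts - 1):
                yield (first,) + rest

    grid = np.array(list(compositions(H, M)), dtype=float)
    weights = grid / H
    assert weights.shape[0] == comb(H + M - 1, M - 1)
    return weights


def build_neighborhoods(weights: np.ndarray, T: int) -> np.ndarray:
    """Indices of the T closest weight vectors to each row (self included).

    Ties in distance are broken by lower index (stable sort). Returns an
    (N, T) integer array B with B[i, 0] == i because the self-distance is 0.
    """
    weights = np.asarray(weights, dtype=float)
    N = weights.shape[0]
    if not (1 <= T <= N):
        raise InvalidArgumentError(f"T={T} must be in [1, N={N}]")
    dist = cdist(weights, weights)
    order = np.argsort(dist, axis=1, kind="stable")
    return order[:, :T]


def pbi_aggregate(F, lam, z, theta: float, nadir=None) -> PBIResult:
    """PBI scalar value of objective vector F for subproblem weight lam.

    d1 = |(F - z*) . lambda| / ||lambda||            (projection distance)
    d2 = ||F - (z* + d1 * lambda/||lambda||)||        (perpendicular distance)
    g  = d1 + theta * d2

    When ``nadir`` is given, each objective is first min-max normalized to
    (F - z*) / (nadir - z*), so the distances are measured in a space where
    every objective spans [0, 1] between the running ideal and nadir
    estimates. With raw energies of very different magnitudes the largest-
    scale objective otherwise dominates both distances and all subproblems
    collapse onto it; normalization keeps the weight rays spread over the
    front. Off by default: the plain definition uses raw objective values.
    """
    F = np.asarray(F, dtype=float)
    lam = np.asarray(lam, dtype=float)
    z = np.asarray(z, dtype=float)
    if not (F.shape == lam.shape == z.shape):
        raise InvalidArgumentError("F, lambda and z* must share one dimension")
    if theta < 0:
        raise InvalidArgumentError("theta must be >= 0")
    norm = np.linalg.norm(lam)
    if norm < 1e-300:
        raise InvalidArgumentError("weight vector must have non-zero norm")
    if nadir is not None:
        span = np.maximum(np.asarray(nadir, dtype=float) - z, 1e-12)
        diff = (F - z) / span
    else:
        diff = F - z
    d1 = abs(float(np.dot(diff, lam))) / norm
    d2 = float(np.linalg.norm(diff - d1 * lam / norm))
    return PBIResult(d1=d1, d2=d2, g=d1 + theta * d2)


def pbi_g(F, lam, z, theta: float) -> float:
    """Shorthand for ``pbi_aggregate(...).g`` on the optimizer's hot path."""
    return pbi_aggregate(F, lam, z, theta).g


def penalty_schedule(t: int, max_iter: int, theta_min: float = 5.0,
                     theta_max: float = 20.0) -> float:
    """Adaptive penalty: theta rises linearly from theta_min at generation 0
    to theta_max at generation max_iter."""
    if max_iter < 1:
        raise InvalidArgumentError("max_iter must be >= 1")
    if not (0 <= t <= max_iter):
        raise InvalidArgumentError(f"generation t={t} outside [0, {max_iter}]")
    return theta_min + (theta_max - theta_min) * (t / max_iter)


def update_ideal(z, F) -> np.ndarray:
    """Component-wise minimum of the running ideal point and a new F."""
    z = np.asarray(z, dtype=float)
    F = np.asarray(F, dtype=float)
    if z.shape != F.shape:
        raise InvalidArgumentError("dimension mismatch in ideal-point update")
    return np.minimum(z, F)
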