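"""Knee-oriented model selection by expected utility.

Archived Pareto solutions are scored by the Monte-Carlo expectation of the
linear utility U(C, w) = w . F(C) over weights w drawn uniformly from the
simplex (flat Dirichlet). Solutions near a knee of the front — where every
objective is relatively good — achieve low utility for most weight draws,
so ranking ascending by expected utility surfaces balanced models first.

All archive members are scored with the *same* weight sample (common
random numbers): ranking noise then cancels between solutions, and a
dominated solution can never outrank one that dominates it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .archive import ArchiveEntry, ParetoArchive
from .errors import EmptyArchiveError, InvalidArgumentError

__all__ = ["UtilityConfig", "utility", "expected_utility",
           "sample_simplex_weights", "rank_select"]


@dataclass(frozen=True)
class UtilityConfig:
    """Monte-Carlo sample size S, seed, and number of models to output."""

    n_samples: int = 20_000
    rng_seed: int = 0
    top_k: int = 5

    def __post_init__(self):
        if self.n_samples < 1:
            raise InvalidArgumentError("n_samples must be >= 1")
        if self.top_k < 1:
            raise InvalidArgumentError("top_k must be >= 1")


def utility(F, w) -> float:
    """Linear utility w . F for one weight vector on the simplex."""
    F = np.asarray(F, dtype=float)
    w = np.asarray(w, dtype=float)
    if F.shape != w.shape:
        raise InvalidArgumentError("F and w must share one dimension")
    return float(np.dot(w, F))


def sample_simplex_weights(S: int, M: int,
                           rng_seed: int = 0) -> np.ndarray:
    """S weight vectors drawn uniformly on the (M-1)-simplex."""
    rng = np.random.default_rng(rng_seed)
    return rng.dirichlet(np.ones(M), size=S)


def expected_utility(F, config: UtilityConfig,
                     weight_samples: np.ndarray | None = None) -> float:
    """Monte-Carlo mean of the utility over S uniform-simplex draws.

    ``weight_samples`` lets callers reuse one sample across many solutions
    (common random numbers); when omitted, samples are drawn from
    ``config.rng_seed``, so the value is deterministic per config.
    """
    F = np.asarray(F, dtype=float)
    if weight_samples is None:
        weight_samples = sample_simplex_weights(config.n_samples, F.shape[0],
                                                config.rng_seed)
    if weight_samples.shape[1] != F.shape[0]:
        raise InvalidArgumentError("weight sample dimension mismatch")
    return float(np.mean(weight_samples @ F))


def rank_select(archive: ParetoArchive, config: UtilityConfig,
                rescale: bool = False) -> list[ArchiveEntry]:
    """Top-k archive entries, ascending expected utility (best first).

    Ties break by earlier ``generation_found``, then by archive position.
    With ``rescale``, each objective is min-max normalized over the archive
    before the utility is computed, preventing one raw energy scale from
    dominating the ranking (off by default: raw energies are ranked as-is).
    """
    if len(archive) == 0:
        raise EmptyArchiveError("cannot rank an empty archive")
    F = archive.objective_matrix()
    if rescale:
        lo = F.min(axis=0)
        span = F.max(axis=0) - lo
        span[span == 0] = 1.0
        F = (F - lo) / span
    W = sample_simplex_weights(config.n_samples, F.shape[1], config.rng_seed)
    eu = (W @ F.T).mean(axis=0)
    order = sorted(
        range(len(archive)),
        key=lambda i: (eu[i], archive.entries[i].generation_found, i),
    )
    k = min(config.top_k, len(archive))
    return [archive.entries[i] for i in order[:k]]
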