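"""Multi-objective energy interface and surrogate energy functions.

The refinement engine minimizes a vector of M >= 2 energies F(C) evaluated
on a conformation C. Production force fields (Rosetta-like, statistical
potentials, molecular-mechanics terms) are external programs; the engine
only requires the :class:`EnergyModel` contract — a named, deterministic,
lower-is-better scalar function. This module provides:

* three surrogate backbone energies (steric clash, compactness, torsion
  basin preference) that genuinely conflict, so the Pareto front of the
  surrogate problem is non-degenerate;
* benchmark landscapes over real vectors ("dtlz2", "convex-plane") with
  closed-form Pareto fronts, used to validate the optimizer;
* an adapter sketch for shelling out to an external scorer.

Surrogate defaults live in :data:`SURROGATE_DEFAULTS`.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .conformation import (
    GeometryParams,
    TorsionChain,
    angular_difference,
    torsions_to_cartesian,
    write_pdb,
)
from .errors import InvalidArgumentError, ObjectiveEvaluationError

__all__ = [
    "ObjectiveVector",
    "EnergyModel",
    "evaluate_all",
    "clash_energy",
    "compactness_energy",
    "torsion_preference_energy",
    "ClashEnergy",
    "CompactnessEnergy",
    "TorsionPreferenceEnergy",
    "surrogate_energies",
    "benchmark_problem",
    "SURROGATE_DEFAULTS",
]

#: Single table of surrogate parameters (units: Angstrom / degrees).
SURROGATE_DEFAULTS = {
    "clash_r_min": 2.5,        # soft-sphere contact radius
    "clash_exclusion": 3,      # skip pairs within 3 bonds along the backbone
    "basin_phi": -57.0,        # alpha-helical torsion basin
    "basin_psi": -47.0,
    "basin_width": 30.0,       # Gaussian basin width (deg)
}


@dataclass(frozen=True)
class ObjectiveVector:
    """Ordered energy values with their objective labels."""

    values: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.shape[0] < 2:
            raise InvalidArgumentError("an objective vector needs M >= 2 values")
        if len(self.labels) != values.shape[0]:
            raise InvalidArgumentError("labels/values length mismatch")
        if not np.isfinite(values).all():
            raise InvalidArgumentError("objective values must be finite")

    def __len__(self) -> int:
        return self.values.shape[0]


class EnergyModel:
    """Contract for one energy term: deterministic, scalar, lower is better.

    Subclasses set :attr:`name` and implement :meth:`evaluate`, which maps a
    conformation (a :class:`TorsionChain` for the protein surrogates, a flat
    real vector for benchmark landscapes) to one float.
    """

    name: str = "energy"

    def evaluate(self, conformation) -> float:  # pragma: no cover - interface
        raise NotImplementedError

    def __repr__(self) -> str:
        return f"<{type(self).__name__} {self.name!r}>"


def evaluate_all(models, conformation) -> ObjectiveVector:
    """Evaluate every model on one conformation, preserving order.

    Raises :class:`ObjectiveEvaluationError` naming the offending model if
    any value comes back non-finite.
    """
    if len(models) < 2:
        raise InvalidArgumentError("need at least 2 energy models")
    values = []
    for model in models:
        v = float(model.evaluate(conformation))
        if not np.isfinite(v):
            raise ObjectiveEvaluationError(model.name, v)
        values.append(v)
    return ObjectiveVector(np.array(values), tuple(m.name for m in models))


# --- surrogate backbone energies ------------------------------------------

def clash_energy(chain: TorsionChain,
                 r_min: float = SURROGATE_DEFAULTS["clash_r_min"],
                 exclusion: int = SURROGATE_DEFAULTS["clash_exclusion"],
                 geom: GeometryParams | None = None) -> float:
    """Soft-sphere steric repulsion over non-bonded backbone atom pairs.

    sum over pairs (i, j) with |i - j| > exclusion (indices along the flat
    N, CA, C, N, ... atom sequence) of max(0, r_min - d_ij)^2. Pairs closer
    than ``exclusion`` positions are covalently coupled (their separation is
    set by bond geometry or a single torsion), so they are excluded; a chain
    with no pair beyond the exclusion scores exactly 0.
    """
    coords = torsions_to_cartesian(chain, geom).atoms_flat()
    i, j = _nonbonded_pairs(coords.shape[0], exclusion)
    diff = coords[i] - coords[j]
    d2 = np.einsum("ij,ij->i", diff, diff)
    close = d2 < r_min * r_min  # sqrt only where an overlap can exist
    if not close.any():
        return 0.0
    overlap = r_min - np.sqrt(d2[close])
    return float(np.sum(overlap**2))


@lru_cache(maxsize=32)
def _nonbonded_pairs(n_atoms: int, exclusion: int):
    return np.triu_indices(n_atoms, k=exclusion + 1)


def compactness_energy(chain: TorsionChain,
                       geom: GeometryParams | None = None) -> float:
    """Squared radius of gyration of the CA trace (A^2); favors collapse."""
    ca = torsions_to_cartesian(chain, geom).ca
    centered = ca - ca.mean(axis=0)
    return float(np.mean(np.sum(centered**2, axis=1)))


def torsion_preference_energy(
    chain: TorsionChain,
    basin_phi: float = SURROGATE_DEFAULTS["basin_phi"],
    basin_psi: float = SURROGATE_DEFAULTS["basin_psi"],
    width: float = SURROGATE_DEFAULTS["basin_width"],
) -> float:
    """Smooth penalty for torsions away from a (phi*, psi*) basin.

    Each residue with both phi and psi defined contributes a harmonic
    restraint d^2 / (2 width^2), where d is the Euclidean circular distance
    of (phi, psi) from the basin center: zero exactly at the basin and
    monotone in the deviation of every angle. The quadratic (rather than a
    saturating) form mirrors the torsion restraints used in structure
    refinement and keeps the energy ordering consistent with overall
    closeness to the target basin — a bounded penalty would score a chain
    with a few wildly wrong angles better than one with many slightly
    displaced angles.
    """
    dphi = angular_difference(chain.phi[1:-1], basin_phi)
    dpsi = angular_difference(chain.psi[1:-1], basin_psi)
    d2 = dphi**2 + dpsi**2
    return float(np.sum(d2 / (2.0 * width**2)))


class ClashEnergy(EnergyModel):
    name = "clash"

    def __init__(self, r_min: float = SURROGATE_DEFAULTS["clash_r_min"],
                 exclusion: int = SURROGATE_DEFAULTS["clash_exclusion"]):
        self.r_min = r_min
        self.exclusion = exclusion

    def evaluate(self, chain: TorsionChain) -> float:
        return clash_energy(chain, self.r_min, self.exclusion)


class CompactnessEnergy(EnergyModel):
    name = "compactness"

    def evaluate(self, chain: TorsionChain) -> float:
        return compactness_energy(chain)


class TorsionPreferenceEnergy(EnergyModel):
    name = "torsion_preference"

    def __init__(self, basin_phi: float = SURROGATE_DEFAULTS["basin_phi"],
                 basin_psi: float = SURROGATE_DEFAULTS["basin_psi"],
                 width: float = SURROGATE_DEFAULTS["basin_width"]):
        self.basin_phi = basin_phi
        self.basin_psi = basin_psi
        self.width = width

    def evaluate(self, chain: TorsionChain) -> float:
        return torsion_preference_energy(chain, self.basin_phi, self.basin_psi,
                                         self.width)


def surrogate_energies() -> list[EnergyModel]:
    """The default conflicting surrogate triple (clash, compactness,
    torsion preference)."""
    return [ClashEnergy(), CompactnessEnergy(), TorsionPreferenceEnergy()]


class CallableEnergy(EnergyModel):
    """Wrap a plain function as an energy model (used for mocks/adapters)."""

    def __init__(self, name: str, fn):
        self.name = name
        self._fn = fn

    def evaluate(self, conformation) -> float:
        return float(self._fn(conformation))


class ExternalScorerAdapter(EnergyModel):
    """Adapter contract for an external scoring program.

    ``scorer`` is any callable taking the path of a written PDB file and
    returning one float (in production this shells out to the force-field
    binary and parses its output; tests pass a mock). The adapter converts
    the torsion chain to Cartesian coordinates, writes a temporary PDB and
    delegates.
    """

    def __init__(self, name: str, scorer, geom: GeometryParams | None = None):
        self.name = name
        self._scorer = scorer
        self._geom = geom

    def evaluate(self, chain: TorsionChain) -> float:
        import tempfile
        from pathlib import Path

        structure = torsions_to_cartesian(chain, self._geom)
        with tempfile.TemporaryDirectory() as tmp:
            path = Path(tmp) / "model.pdb"
            write_pdb(structure, path)
            return float(self._scorer(path))


# --- benchmark landscapes over real vectors --------------------------------

class _Dtlz2Objective(EnergyModel):
    def __init__(self, k: int, dim: int):
        self.name = f"dtlz2_f{k + 1}"
        self._k = k
        self._dim = dim

    def evaluate(self, x) -> float:
        x = np.asarray(x, dtype=float)
        if x.shape != (self._dim,):
            raise InvalidArgumentError(f"expected vector of length {self._dim}")
        g = float(np.sum((x[2:] - 0.5) ** 2))
        a = x[0] * np.pi / 2.0
        b = x[1] * np.pi / 2.0
        if self._k == 0:
            return (1 + g) * np.cos(a) * np.cos(b)
        if self._k == 1:
            return (1 + g) * np.cos(a) * np.sin(b)
        return (1 + g) * np.sin(a)


class _ConvexPlaneObjective(EnergyModel):
    """Unimodal 3-objective landscape whose Pareto front is the plane
    f1 + f2 + f3 = 1 (f_k >= 0).

    x[0], x[1] in [0, 1] parameterize a point of the simplex,
    p = (x0*x1, x0*(1-x1), 1-x0); the remaining coordinates add a distance
    term g = sum (x_i - 0.5)^2, and f = (1 + g) * p. On the optimum
    manifold g = 0 and sum(f) = 1.
    """

    def __init__(self, k: int, dim: int):
        self.name = f"plane_f{k + 1}"
        self._k = k
        self._dim = dim

    def evaluate(self, x) -> float:
        x = np.asarray(x, dtype=float)
        if x.shape != (self._dim,):
            raise InvalidArgumentError(f"expected vector of length {self._dim}")
        g = float(np.sum((x[2:] - 0.5) ** 2))
        p = (x[0] * x[1], x[0] * (1.0 - x[1]), 1.0 - x[0])
        return (1 + g) * p[self._k]


def benchmark_problem(name: str, dim: int = 7) -> list[EnergyModel]:
    """Three-objective benchmark with a closed-form Pareto front.

    ``dtlz2``: PF is the unit-sphere octant, ||F|| = 1.
    ``convex-plane``: PF is the plane f1 + f2 + f3 = 1.
    ``dim`` >= 3 decision variables in [0, 1]; the first two position the
    solution on the front, the rest form the distance term.
    """
    if dim < 3:
        raise InvalidArgumentError("benchmark needs dim >= 3")
    if name == "dtlz2":
        return [_Dtlz2Objective(k, dim) for k in range(3)]
    if name == "convex-plane":
        return [_ConvexPlaneObjective(k, dim) for k in range(3)]
    raise InvalidArgumentError(f"unknown benchmark {name!r}")
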