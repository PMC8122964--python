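"""Backbone conformations in torsion and Cartesian coordinates.

A protein backbone is parameterized either by per-residue torsion angles
(phi, psi, omega) — the representation the optimizer moves in — or by the
Cartesian coordinates of the N, CA, C (and optionally O) atoms. Conversion
from torsions to Cartesians places atoms sequentially: each new atom is
positioned in the frame of the previous three using a fixed bond length, a
fixed bond angle and the free torsion (the natural-extension / DH-style
construction). The inverse direction measures standard dihedrals.

Angle convention: degrees, wrapped to the half-open interval (-180, 180].
By convention residue 1 has no phi and the last residue has no psi/omega;
these slots are stored as NaN, never as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import gemmi
import numpy as np

from .errors import (
    DegenerateGeometryError,
    InvalidArgumentError,
    MissingAtomError,
    PDBParseError,
)

__all__ = [
    "TorsionChain",
    "BackboneStructure",
    "GeometryParams",
    "wrap_angle",
    "dihedral",
    "torsions_to_cartesian",
    "cartesian_to_torsions",
    "perturb",
    "read_pdb",
    "write_pdb",
]

_BACKBONE_ATOMS = ("N", "CA", "C")


def wrap_angle(theta):
    """Wrap an angle (degrees) into the half-open interval (-180, 180].

    Accepts scalars or arrays; NaN is passed through (it marks undefined
    torsion slots). Non-finite values other than NaN raise
    :class:`InvalidArgumentError`.
    """
    arr = np.asarray(theta, dtype=float)
    if np.isinf(arr).any():
        raise InvalidArgumentError("angle must be finite")
    reduced = np.mod(arr, 360.0)
    reduced = np.where(reduced > 180.0, reduced - 360.0, reduced)
    # values already in range pass through bit-exactly (mod would otherwise
    # introduce rounding noise)
    in_range = (arr > -180.0) & (arr <= 180.0)
    wrapped = np.where(in_range, arr, reduced)
    if np.isscalar(theta) or arr.ndim == 0:
        return float(wrapped)
    return wrapped


def angular_difference(a, b):
    """Shortest signed angular difference a - b, wrapped to (-180, 180]."""
    return wrap_angle(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


@dataclass(frozen=True)
class GeometryParams:
    """Fixed covalent backbone geometry used by the torsion->Cartesian build.

    Defaults are standard Engh–Huber-style values (lengths in Angstrom,
    angles in degrees).
    """

    n_ca: float = 1.458
    ca_c: float = 1.525
    c_n: float = 1.329
    n_ca_c: float = 111.2
    ca_c_n: float = 116.2
    c_n_ca: float = 121.7

    def __post_init__(self):
        for name in ("n_ca", "ca_c", "c_n"):
            v = getattr(self, name)
            if not (0.5 < v < 3.0):
                raise InvalidArgumentError(
                    f"bond length {name}={v} outside (0.5, 3.0) A"
                )
        for name in ("n_ca_c", "ca_c_n", "c_n_ca"):
            v = getattr(self, name)
            if not (60.0 < v < 180.0):
                raise InvalidArgumentError(
                    f"bond angle {name}={v} outside (60, 180) deg"
                )


@dataclass(frozen=True)
class TorsionChain:
    """Per-residue backbone torsions (phi, psi, omega) in degrees.

    ``phi``, ``psi`` and ``omega`` are float arrays of length L. ``phi[0]``
    and ``psi[-1]`` / ``omega[-1]`` are NaN (undefined by convention); all
    defined entries lie in (-180, 180].
    """

    phi: np.ndarray
    psi: np.ndarray
    omega: np.ndarray
    residue_names: tuple[str, ...] = ()

    def __post_init__(self):
        phi = np.asarray(self.phi, dtype=float)
        psi = np.asarray(self.psi, dtype=float)
        omega = np.asarray(self.omega, dtype=float)
        object.__setattr__(self, "phi", phi)
        object.__setattr__(self, "psi", psi)
        object.__setattr__(self, "omega", omega)
        L = len(phi)
        if L < 2:
            raise InvalidArgumentError("a torsion chain needs at least 2 residues")
        if len(psi) != L or len(omega) != L:
            raise InvalidArgumentError("phi/psi/omega must have equal length")
        names = self.residue_names or ("ALA",) * L
        if len(names) != L:
            raise InvalidArgumentError("residue_names length mismatch")
        object.__setattr__(self, "residue_names", tuple(names))
        for arr, undef_idx, label in (
            (phi, 0, "phi"),
            (psi, L - 1, "psi"),
            (omega, L - 1, "omega"),
        ):
            if not np.isnan(arr[undef_idx]):
                raise InvalidArgumentError(
                    f"{label}[{undef_idx}] must be NaN (undefined by convention)"
                )
            defined = np.delete(arr, undef_idx)
            if not np.isfinite(defined).all():
                raise InvalidArgumentError(f"{label} contains non-finite values")
            if ((defined <= -180.0) | (defined > 180.0)).any():
                raise InvalidArgumentError(f"{label} outside (-180, 180]")

    def __len__(self) -> int:
        return len(self.phi)

    @classmethod
    def from_angles(cls, phi, psi, omega, residue_names=()) -> "TorsionChain":
        """Build a chain, wrapping all defined angles into (-180, 180]."""
        return cls(wrap_angle(np.asarray(phi, dtype=float)),
                   wrap_angle(np.asarray(psi, dtype=float)),
                   wrap_angle(np.asarray(omega, dtype=float)),
                   residue_names)

    @classmethod
    def uniform(cls, L: int, phi: float, psi: float, omega: float = 180.0,
                residue_names=()) -> "TorsionChain":
        """Chain with identical (phi, psi, omega) at every residue."""
        p = np.full(L, float(phi))
        s = np.full(L, float(psi))
        o = np.full(L, float(omega))
        p[0] = np.nan
        s[-1] = np.nan
        o[-1] = np.nan
        return cls.from_angles(p, s, o, residue_names)

    @classmethod
    def _from_validated(cls, phi, psi, omega, residue_names) -> "TorsionChain":
        """Bypass __post_init__ for internally produced, already-valid
        angles (hot path: the optimizer builds thousands of chains whose
        angles are wrapped by construction)."""
        obj = object.__new__(cls)
        object.__setattr__(obj, "phi", phi)
        object.__setattr__(obj, "psi", psi)
        object.__setattr__(obj, "omega", omega)
        object.__setattr__(obj, "residue_names", residue_names)
        return obj

    # --- flat-vector view used by the optimizer ---------------------------

    def to_vector(self, include_omega: bool = False) -> np.ndarray:
        """Defined torsions as a flat vector: [phi[1:], psi[:-1](, omega[:-1])]."""
        parts = [self.phi[1:], self.psi[:-1]]
        if include_omega:
            parts.append(self.omega[:-1])
        return np.concatenate(parts)

    def with_vector(self, vec: np.ndarray, include_omega: bool = False) -> "TorsionChain":
        """Return a copy with defined torsions replaced from a flat vector."""
        L = len(self)
        vec = np.asarray(vec, dtype=float)
        expect = (3 if include_omega else 2) * (L - 1)
        if vec.shape != (expect,):
            raise InvalidArgumentError(
                f"vector length {vec.shape} != expected ({expect},)"
            )
        phi = self.phi.copy()
        psi = self.psi.copy()
        omega = self.omega.copy()
        phi[1:] = vec[: L - 1]
        psi[:-1] = vec[L - 1 : 2 * (L - 1)]
        if include_omega:
            omega[:-1] = vec[2 * (L - 1) :]
        return TorsionChain._from_validated(wrap_angle(phi), wrap_angle(psi),
                                            wrap_angle(omega),
                                            self.residue_names)


@dataclass(frozen=True)
class BackboneStructure:
    """Cartesian backbone: (L, 3) arrays for N, CA, C and optionally O (A)."""

    n: np.ndarray
    ca: np.ndarray
    c: np.ndarray
    o: np.ndarray | None = None
    residue_names: tuple[str, ...] = ()
    chain_id: str = "A"

    def __post_init__(self):
        n = np.asarray(self.n, dtype=float)
        ca = np.asarray(self.ca, dtype=float)
        c = np.asarray(self.c, dtype=float)
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "ca", ca)
        object.__setattr__(self, "c", c)
        L = n.shape[0]
        if L < 2:
            raise InvalidArgumentError("a backbone needs at least 2 residues")
        for arr, nm in ((n, "N"), (ca, "CA"), (c, "C")):
            if arr.shape != (L, 3):
                raise InvalidArgumentError(f"{nm} coordinates must be (L, 3)")
            if not np.isfinite(arr).all():
                raise InvalidArgumentError(f"{nm} coordinates must be finite")
        if self.o is not None:
            o = np.asarray(self.o, dtype=float)
            if o.shape != (L, 3):
                raise InvalidArgumentError("O coordinates must be (L, 3)")
            object.__setattr__(self, "o", o)
        names = self.residue_names or ("ALA",) * L
        if len(names) != L:
            raise InvalidArgumentError("residue_names length mismatch")
        object.__setattr__(self, "residue_names", tuple(names))
        # bonded distances must be positive
        for a, b, nm in ((n, ca, "N-CA"), (ca, c, "CA-C")):
            d = np.linalg.norm(b - a, axis=1)
            if (d <= 0).any() or not np.isfinite(d).all():
                raise InvalidArgumentError(f"non-positive {nm} bond distance")
        d = np.linalg.norm(self.n[1:] - c[:-1], axis=1)
        if (d <= 0).any():
            raise InvalidArgumentError("non-positive C-N(next) bond distance")

    def __len__(self) -> int:
        return self.n.shape[0]

    def atoms_flat(self) -> np.ndarray:
        """All backbone atoms interleaved [N1, CA1, C1, N2, ...], (3L, 3)."""
        return np.stack([self.n, self.ca, self.c], axis=1).reshape(-1, 3)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray
                    ) -> "BackboneStructure":
        """Apply a rigid motion x -> R x + t to every atom."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        new_o = None if self.o is None else self.o @ R.T + t
        return replace(self, n=self.n @ R.T + t, ca=self.ca @ R.T + t,
                       c=self.c @ R.T + t, o=new_o)


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle (degrees) of the quadruple p0-p1-p2-p3.

    IUPAC sign convention; result in (-180, 180]. Raises
    :class:`DegenerateGeometryError` when any three consecutive points are
    collinear.
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    nb1 = np.linalg.norm(b1)
    if nb1 < 1e-12:
        raise DegenerateGeometryError("central bond has zero length")
    b1 = b1 / nb1
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    if np.linalg.norm(v) < 1e-10 or np.linalg.norm(w) < 1e-10:
        raise DegenerateGeometryError("collinear atoms: dihedral undefined")
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return wrap_angle(np.degrees(np.arctan2(y, x)))


def _place_atom(a, b, c, bond_length: float, bond_angle_deg: float,
                torsion_deg: float):
    """Place atom d so that |cd| = bond_length, angle(b,c,d) = bond_angle and
    dihedral(a,b,c,d) = torsion_deg.

    Scalar math on 3-tuples: this sits on the optimizer's hot path, where
    plain floats are several times faster than small numpy arrays.
    """
    ang = math.radians(bond_angle_deg)
    tor = math.radians(torsion_deg)
    bcx = c[0] - b[0]
    bcy = c[1] - b[1]
    bcz = c[2] - b[2]
    inv = 1.0 / math.sqrt(bcx * bcx + bcy * bcy + bcz * bcz)
    bcx *= inv
    bcy *= inv
    bcz *= inv
    abx = b[0] - a[0]
    aby = b[1] - a[1]
    abz = b[2] - a[2]
    nx = aby * bcz - abz * bcy
    ny = abz * bcx - abx * bcz
    nz = abx * bcy - aby * bcx
    nn = math.sqrt(nx * nx + ny * ny + nz * nz)
    if nn < 1e-12:
        raise DegenerateGeometryError("cannot place atom: frame atoms collinear")
    nx /= nn
    ny /= nn
    nz /= nn
    mx = ny * bcz - nz * bcy
    my = nz * bcx - nx * bcz
    mz = nx * bcy - ny * bcx
    d0 = -bond_length * math.cos(ang)
    sin_ang = math.sin(ang)
    d1 = bond_length * sin_ang * math.cos(tor)
    d2 = bond_length * sin_ang * math.sin(tor)
    return (c[0] + d0 * bcx + d1 * mx + d2 * nx,
            c[1] + d0 * bcy + d1 * my + d2 * ny,
            c[2] + d0 * bcz + d1 * mz + d2 * nz)


def torsions_to_cartesian(chain: TorsionChain,
                          geom: GeometryParams | None = None,
                          include_oxygen: bool = False) -> BackboneStructure:
    """Build Cartesian backbone coordinates from torsions.

    The first three atoms fix the canonical frame: N1 at the origin, CA1 on
    the +x axis, C1 in the xy-plane. Subsequent atoms are placed one at a
    time from the preceding three using ``geom`` and the chain's torsions.

    When ``include_oxygen`` is set, carbonyl O atoms are added in the
    peptide plane (C=O 1.231 A, CA-C-O 120.8 deg); the last residue's O is
    placed trans to N.
    """
    if geom is None and not include_oxygen:
        # memoize the default-geometry conversion: several energy terms need
        # the same Cartesian build of the same (immutable) chain
        cached = chain.__dict__.get("_default_cartesian")
        if cached is not None:
            return cached
        result = torsions_to_cartesian(chain, GeometryParams(), False)
        object.__setattr__(chain, "_default_cartesian", result)
        return result
    geom = geom or GeometryParams()
    L = len(chain)
    phi = chain.phi.tolist()
    psi = chain.psi.tolist()
    omega = chain.omega.tolist()
    # canonical frame
    n = [(0.0, 0.0, 0.0)]
    ca = [(geom.n_ca, 0.0, 0.0)]
    ang = math.radians(geom.n_ca_c)
    c = [(geom.n_ca - geom.ca_c * math.cos(ang),
          geom.ca_c * math.sin(ang), 0.0)]
    for i in range(L - 1):
        n.append(_place_atom(n[i], ca[i], c[i], geom.c_n, geom.ca_c_n,
                             psi[i]))
        ca.append(_place_atom(ca[i], c[i], n[i + 1], geom.n_ca, geom.c_n_ca,
                              omega[i]))
        c.append(_place_atom(c[i], n[i + 1], ca[i + 1], geom.ca_c,
                             geom.n_ca_c, phi[i + 1]))
    o = None
    if include_oxygen:
        o = np.array([
            _place_atom(n[i], ca[i], c[i], 1.231, 120.8,
                        wrap_angle((psi[i] if i < L - 1 else 180.0) + 180.0))
            for i in range(L)
        ])
    return BackboneStructure(n=np.array(n), ca=np.array(ca), c=np.array(c),
                             o=o, residue_names=chain.residue_names)


def cartesian_to_torsions(structure: BackboneStructure) -> TorsionChain:
    """Measure (phi, psi, omega) dihedrals from backbone coordinates."""
    L = len(structure)
    n, ca, c = structure.n, structure.ca, structure.c
    phi = np.full(L, np.nan)
    psi = np.full(L, np.nan)
    omega = np.full(L, np.nan)
    for i in range(L - 1):
        psi[i] = dihedral(n[i], ca[i], c[i], n[i + 1])
        omega[i] = dihedral(ca[i], c[i], n[i + 1], ca[i + 1])
        phi[i + 1] = dihedral(c[i], n[i + 1], ca[i + 1], c[i + 1])
    return TorsionChain(phi, psi, omega, structure.residue_names)


def perturb(chain: TorsionChain, sigma: float, rng_seed,
            perturb_omega: bool = False) -> TorsionChain:
    """Add zero-mean Gaussian noise (std ``sigma`` degrees) to defined
    phi/psi angles, wrapping the results.

    Omega is left untouched by default so peptide bonds stay near trans;
    ``perturb_omega`` enables noise on omega as well. ``rng_seed`` may be an
    integer seed or a ``numpy.random.Generator``.
    """
    if sigma < 0:
        raise InvalidArgumentError("sigma must be non-negative")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    L = len(chain)
    phi = chain.phi.copy()
    psi = chain.psi.copy()
    omega = chain.omega.copy()
    phi[1:] = wrap_angle(phi[1:] + rng.normal(0.0, sigma, L - 1))
    psi[:-1] = wrap_angle(psi[:-1] + rng.normal(0.0, sigma, L - 1))
    if perturb_omega:
        omega[:-1] = wrap_angle(omega[:-1] + rng.normal(0.0, sigma, L - 1))
    return TorsionChain(phi, psi, omega, chain.residue_names)


# --- PDB I/O ---------------------------------------------------------------

def read_pdb(path, chain_id: str | None = None) -> BackboneStructure:
    """Read the backbone of the first model (first chain by default).

    Residues must carry complete N/CA/C atoms; a missing atom raises
    :class:`MissingAtomError` naming the residue and atom. Carbonyl O atoms
    are read when present on every residue.
    """
    path = Path(path)
    if not path.exists():
        raise PDBParseError(f"no such file: {path}")
    try:
        st = gemmi.read_structure(str(path))
    except Exception as exc:  # pragma: no cover - gemmi error text varies
        raise PDBParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise PDBParseError(f"{path} contains no models")
    model = st[0]
    if len(model) == 0:
        raise PDBParseError(f"{path} model 1 contains no chains")
    if chain_id is None:
        chain = model[0]
    else:
        chain = model.find_chain(chain_id)
        if chain is None:
            raise PDBParseError(f"{path} has no chain {chain_id!r}")
    rows_n, rows_ca, rows_c, rows_o, names = [], [], [], [], []
    missing: list[MissingAtomError] = []
    for idx, res in enumerate(chain):
        coords = {}
        for atom in res:
            if atom.name in ("N", "CA", "C", "O") and atom.name not in coords:
                if atom.altloc in ("", "A", "\0"):
                    p = atom.pos
                    coords[atom.name] = (p.x, p.y, p.z)
        for nm in _BACKBONE_ATOMS:
            if nm not in coords:
                missing.append(MissingAtomError(idx + 1, res.name, nm))
        if missing:
            continue
        rows_n.append(coords["N"])
        rows_ca.append(coords["CA"])
        rows_c.append(coords["C"])
        rows_o.append(coords.get("O"))
        names.append(res.name)
    if missing:
        raise PDBParseError(
            f"{path}: incomplete backbone — " + "; ".join(str(m) for m in missing)
        )
    if len(rows_n) < 2:
        raise PDBParseError(f"{path}: fewer than 2 complete residues")
    o = None
    if all(r is not None for r in rows_o):
        o = np.array(rows_o, dtype=float)
    return BackboneStructure(
        n=np.array(rows_n), ca=np.array(rows_ca), c=np.array(rows_c), o=o,
        residue_names=tuple(names), chain_id=chain.name or "A",
    )


def write_pdb(structure: BackboneStructure, path) -> None:
    """Write the backbone as fixed-column ATOM records (single model/chain)."""
    st = gemmi.Structure()
    st.name = "torsionswarm"
    model = gemmi.Model("1")
    ch = gemmi.Chain(structure.chain_id or "A")
    atom_sets = [("N", "N", structure.n), ("CA", "C", structure.ca),
                 ("C", "C", structure.c)]
    if structure.o is not None:
        atom_sets.append(("O", "O", structure.o))
    for i in range(len(structure)):
        res = gemmi.Residue()
        res.name = structure.residue_names[i]
        res.seqid = gemmi.SeqId(i + 1, " ")
        res.het_flag = "A"
        for name, element, arr in atom_sets:
            at = gemmi.Atom()
            at.name = name
            at.element = gemmi.Element(element)
            at.occ = 1.0
            at.b_iso = 0.0
            at.pos = gemmi.Position(*arr[i])
            res.add_atom(at)
        ch.add_residue(res)
    model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))
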