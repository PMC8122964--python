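"""Synthetic refinement problems: a known native plus a perturbed start.

Real refinement inputs are a predicted model at some unknown distance from
a hidden native structure. The generator emulates that setting with full
control: a synthetic native backbone built from canonical secondary-
structure torsions (alpha-helix, extended strand, or mixed blocks) and an
initial model produced by Gaussian torsion perturbation at a chosen
deviation. Both are written as PDB files together with a JSON manifest
recording the initial model's RMSD and GDT-TS against the native.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .conformation import (
    BackboneStructure,
    TorsionChain,
    perturb,
    torsions_to_cartesian,
    write_pdb,
)
from .errors import InvalidArgumentError
from .metrics import gdt_ts, kabsch_rmsd

__all__ = ["make_native", "make_refinement_case", "RefinementCase",
           "MOTIF_TORSIONS"]

#: Canonical (phi, psi) per motif; omega stays trans (180 deg).
MOTIF_TORSIONS = {
    "helix": (-57.0, -47.0),
    "extended": (180.0, 180.0),
}

_MIXED_BLOCK = 8  # residues per alternating helix/extended block


def make_native(L: int, motif: str = "helix",
                seed: int = 0) -> tuple[TorsionChain, BackboneStructure]:
    """Deterministic synthetic native: torsions plus Cartesian backbone.

    ``helix`` uses (phi, psi) = (-57, -47); ``extended`` uses (180, 180);
    ``mixed`` alternates blocks of both. A small seeded jitter (std 2 deg)
    keeps repeated fixtures from being perfectly crystalline while staying
    deterministic per seed.
    """
    if L < 2:
        raise InvalidArgumentError("native needs L >= 2 residues")
    if motif in MOTIF_TORSIONS:
        phi0, psi0 = MOTIF_TORSIONS[motif]
        phi = np.full(L, phi0)
        psi = np.full(L, psi0)
    elif motif == "mixed":
        phi = np.empty(L)
        psi = np.empty(L)
        for i in range(L):
            key = "helix" if (i // _MIXED_BLOCK) % 2 == 0 else "extended"
            phi[i], psi[i] = MOTIF_TORSIONS[key]
    else:
        raise InvalidArgumentError(f"unknown motif {motif!r}")
    omega = np.full(L, 180.0)
    phi[0] = np.nan
    psi[-1] = np.nan
    omega[-1] = np.nan
    chain = TorsionChain(phi, psi, omega)
    chain = perturb(chain, 2.0, np.random.default_rng(seed))
    return chain, torsions_to_cartesian(chain)


@dataclass(frozen=True)
class RefinementCase:
    """Paths and starting-quality numbers of one synthetic case."""

    native_pdb: Path
    initial_pdb: Path
    manifest: Path
    native_chain: TorsionChain
    initial_chain: TorsionChain
    initial_rmsd: float
    initial_gdt_ts: float


def make_refinement_case(L: int, deviation_sigma: float, seed: int,
                         outdir, motif: str = "helix") -> RefinementCase:
    """Write a (native, initial) PDB pair at a controlled deviation.

    The initial model is the native with Gaussian noise of std
    ``deviation_sigma`` degrees on every defined phi/psi. The manifest
    records the initial RMSD (CA) and GDT-TS, recomputable from the two
    PDB files.
    """
    if deviation_sigma < 0:
        raise InvalidArgumentError("deviation_sigma must be >= 0")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    native_chain, native_structure = make_native(L, motif, seed)
    initial_chain = perturb(native_chain, deviation_sigma,
                            np.random.default_rng(seed + 1))
    initial_structure = torsions_to_cartesian(initial_chain)
    native_pdb = outdir / "native.pdb"
    initial_pdb = outdir / "initial.pdb"
    write_pdb(native_structure, native_pdb)
    write_pdb(initial_structure, initial_pdb)
    rmsd = kabsch_rmsd(initial_structure, native_structure)
    gdt = gdt_ts(initial_structure, native_structure)
    manifest = outdir / "manifest.json"
    manifest.write_text(json.dumps({
        "L": L,
        "motif": motif,
        "deviation_sigma": deviation_sigma,
        "seed": seed,
        "initial_rmsd": rmsd,
        "initial_gdt_ts": gdt,
    }, indent=2))
    return RefinementCase(
        native_pdb=native_pdb, initial_pdb=initial_pdb, manifest=manifest,
        native_chain=native_chain, initial_chain=initial_chain,
        initial_rmsd=rmsd, initial_gdt_ts=gdt,
    )
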