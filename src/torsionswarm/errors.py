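"""Exception hierarchy.

All errors derive from :class:`TorsionSwarmError` so callers can catch the
package's failures with one clause; the argument-validation errors also
derive from :class:`ValueError` for idiomatic use.
"""


class TorsionSwarmError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(TorsionSwarmError, ValueError):
    """A precondition on an argument was violated."""


class MissingAtomError(TorsionSwarmError):
    """A required backbone atom is absent from a structure."""

    def __init__(self, residue_index: int, residue_name: str, atom_name: str):
        self.residue_index = residue_index
        self.residue_name = residue_name
        self.atom_name = atom_name
        super().__init__(
            f"residue {residue_index} ({residue_name}) is missing backbone "
            f"atom {atom_name}"
        )


class DegenerateGeometryError(TorsionSwarmError):
    """Atoms are collinear (or coincident), so a dihedral is undefined."""


class PDBParseError(TorsionSwarmError):
    """A PDB file could not be parsed into a usable backbone."""


class ObjectiveEvaluationError(TorsionSwarmError):
    """An energy model returned a non-finite value."""

    def __init__(self, model_name: str, value, particle_index: int | None = None):
        self.model_name = model_name
        self.value = value
        self.particle_index = particle_index
        where = f" (particle {particle_index})" if particle_index is not None else ""
        super().__init__(
            f"energy model {model_name!r} returned non-finite value {value!r}{where}"
        )


class EmptyArchiveError(TorsionSwarmError):
    """Ranking was requested on an empty archive."""
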