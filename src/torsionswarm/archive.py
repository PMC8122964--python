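"""Pareto archive: the evolving set of mutually non-dominated solutions.

Dominance is the standard minimization relation: a dominates b when a is
component-wise <= b and the two objective vectors differ. Offering a
solution removes every archived entry it dominates and inserts it unless
an archived entry dominates it; exact duplicates of an archived objective
vector are rejected (the first occurrence is kept).

The archive is unbounded by default; an optional capacity prunes the most
crowded entries (smallest crowding distance) when exceeded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgumentError

__all__ = ["ArchiveEntry", "ParetoArchive", "dominates"]


def dominates(a, b) -> bool:
    """True iff objective vector a dominates b (minimization)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise InvalidArgumentError("dominance needs equal dimensions")
    return bool(np.all(a <= b) and np.any(a < b))


@dataclass(frozen=True)
class ArchiveEntry:
    """One archived solution: its conformation (or decision vector), its
    objective vector and the generation at which it entered."""

    conformation: object
    objectives: np.ndarray
    generation_found: int = 0

    def __post_init__(self):
        obj = np.asarray(self.objectives, dtype=float)
        if not np.isfinite(obj).all():
            raise InvalidArgumentError("archive objectives must be finite")
        object.__setattr__(self, "objectives", obj)


class ParetoArchive:
    """Mutually non-dominated set with Algorithm-style offer semantics."""

    def __init__(self, capacity: int | None = None):
        if capacity is not None and capacity < 1:
            raise InvalidArgumentError("capacity must be >= 1 or None")
        self.capacity = capacity
        self.entries: list[ArchiveEntry] = []
        self._F: np.ndarray | None = None  # (n, M) mirror of entry objectives

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def objective_matrix(self) -> np.ndarray:
        """(n, M) array of archived objective vectors (n may be 0)."""
        if self._F is None:
            return np.empty((0, 0))
        return self._F.copy()

    def offer(self, entry: ArchiveEntry) -> bool:
        """Offer a solution; returns True iff it was accepted.

        Dominated or duplicate offers leave the archive unchanged; an
        accepted offer first evicts every entry it dominates. One vectorized
        pass over the (n, M) objective matrix per offer.
        """
        F = entry.objectives
        if self._F is None:
            self.entries.append(entry)
            self._F = F[None, :].copy()
            return True
        if self._F.shape[1] != F.shape[0]:
            raise InvalidArgumentError("objective dimension mismatch")
        le = (self._F <= F).all(axis=1)       # existing <= new everywhere
        ge = (self._F >= F).all(axis=1)       # existing >= new everywhere
        equal = le & ge
        if equal.any() or (le & ~equal).any():
            return False                      # duplicate or dominated
        evict = ge                            # ge & ~equal; equal is empty here
        if evict.any():
            keep = ~evict
            self.entries = [e for e, k in zip(self.entries, keep) if k]
            self._F = self._F[keep]
        self.entries.append(entry)
        self._F = np.vstack([self._F, F[None, :]])
        if self.capacity is not None and len(self.entries) > self.capacity:
            self._prune_to(self.capacity)
        return True

    def _prune_to(self, capacity: int) -> None:
        """Drop the most crowded entries until len == capacity."""
        while len(self.entries) > capacity:
            cd = _crowding_distance(self._F)
            worst = int(np.argmin(cd))
            self.entries.pop(worst)
            self._F = np.delete(self._F, worst, axis=0)

    def write_tsv(self, path) -> None:
        """Serialize objective vectors as a TSV (one row per entry)."""
        with open(path, "w") as fh:
            if not self.entries:
                fh.write("entry\tgeneration_found\n")
                return
            M = len(self.entries[0].objectives)
            cols = "\t".join(f"f{k + 1}" for k in range(M))
            fh.write(f"entry\tgeneration_found\t{cols}\n")
            for i, e in enumerate(self.entries):
                vals = "\t".join(f"{v:.10g}" for v in e.objectives)
                fh.write(f"{i}\t{e.generation_found}\t{vals}\n")


def _crowding_distance(F: np.ndarray) -> np.ndarray:
    """NSGA-II-style crowding distance; boundary points get +inf."""
    n, M = F.shape
    cd = np.zeros(n)
    for k in range(M):
        order = np.argsort(F[:, k], kind="stable")
        fk = F[order, k]
        span = fk[-1] - fk[0]
        cd[order[0]] = cd[order[-1]] = np.inf
        if span > 0 and n > 2:
            cd[order[1:-1]] += (fk[2:] - fk[:-2]) / span
    return cd
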