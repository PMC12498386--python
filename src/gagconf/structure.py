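"""Molecular containers: single conformers, ensembles, and atom selections.

Coordinates are Cartesian and in Å throughout the package; masses in amu;
residues are 1-indexed with the reducing end of a carbohydrate chain as
residue 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np

# Standard atomic masses (amu). Pseudo-atom names used by the synthetic
# generator carry their own masses (see PSEUDO_ATOM_MASSES) and are mapped
# here only for I/O round trips.
ELEMENT_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
    "NA": 22.990,
    "CL": 35.45,
}

# United pseudo-atoms for sulfate / N-sulfo / carboxylate / hydroxyl
# substituents: single sites with the mass of the whole group.
PSEUDO_ATOM_MASSES: dict[str, float] = {
    "SN": 95.10,   # -NH-SO3 (N-sulfo, on C2 of GlcNS)
    "S6": 110.13,  # -CH2-O-SO3 (6-O-sulfo arm, on C5 of GlcNS)
    "S2": 96.06,   # -O-SO3 (2-O-sulfo, on C2 of IdoA)
    "CX": 44.01,   # -COO (carboxylate, on C5 of IdoA)
    "O3": 17.01,   # -OH (hydroxyl, on C3)
    "O1": 17.01,   # anomeric -OH at the reducing end
}


class TopologyError(ValueError):
    """Raised when atom/residue bookkeeping is inconsistent."""


class SelectionError(ValueError):
    """Raised when an atom selection resolves to an unusable set."""


def mass_of(atom_name: str, element: str) -> float:
    """Mass for an atom, preferring the pseudo-atom table over elements."""
    if atom_name in PSEUDO_ATOM_MASSES:
        return PSEUDO_ATOM_MASSES[atom_name]
    key = element.upper()
    if key not in ELEMENT_MASSES:
        raise TopologyError(f"unknown element {element!r} for atom {atom_name!r}")
    return ELEMENT_MASSES[key]


@dataclass
class Structure:
    """One conformer: parallel per-atom arrays sharing one index.

    Parameters
    ----------
    atom_names, elements : per-atom labels.
    masses : amu, all positive.
    residue_indices : 1-based, non-decreasing along the atom list.
    residue_types : residue class label per atom (e.g. ``"GlcNS(6S)"``).
    positions : (n_atoms, 3) float array, Å.
    """

    atom_names: list[str]
    elements: list[str]
    masses: np.ndarray
    residue_indices: np.ndarray
    residue_types: list[str]
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        self.residue_indices = np.asarray(self.residue_indices, dtype=int)
        self.positions = np.asarray(self.positions, dtype=float)
        n = len(self.atom_names)
        if not (
            len(self.elements) == n
            and self.masses.shape == (n,)
            and self.residue_indices.shape == (n,)
            and len(self.residue_types) == n
            and self.positions.shape == (n, 3)
        ):
            raise TopologyError("inconsistent per-atom array lengths")
        if n == 0:
            raise TopologyError("structure has no atoms")
        if not np.all(np.isfinite(self.positions)):
            raise TopologyError("non-finite coordinates")
        if np.any(self.masses <= 0):
            raise TopologyError("non-positive atomic mass")
        if np.any(np.diff(self.residue_indices) < 0):
            raise TopologyError("residue indices must be non-decreasing")
        seen: set[tuple[int, str]] = set()
        for name, ri in zip(self.atom_names, self.residue_indices):
            key = (int(ri), name)
            if key in seen:
                raise TopologyError(
                    f"duplicate atom name {name!r} in residue {ri}"
                )
            seen.add(key)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def residue_ids(self) -> list[int]:
        """Sorted unique residue indices."""
        return sorted(set(int(i) for i in self.residue_indices))

    def residue_type_of(self, residue_index: int) -> str:
        mask = self.residue_indices == residue_index
        if not mask.any():
            raise TopologyError(f"no residue with index {residue_index}")
        return self.residue_types[int(np.nonzero(mask)[0][0])]

    def atom_index(self, residue_index: int, atom_name: str) -> int:
        """Index of a named atom within a residue; explicit error if absent."""
        for i in np.nonzero(self.residue_indices == residue_index)[0]:
            if self.atom_names[i] == atom_name:
                return int(i)
        raise TopologyError(
            f"residue {residue_index} has no atom {atom_name!r}"
        )

    def atom_position(self, residue_index: int, atom_name: str) -> np.ndarray:
        return self.positions[self.atom_index(residue_index, atom_name)]

    def with_positions(self, positions: np.ndarray) -> "Structure":
        """Same topology, new coordinates (no copy of label arrays)."""
        s = Structure.__new__(Structure)
        s.atom_names = self.atom_names
        s.elements = self.elements
        s.masses = self.masses
        s.residue_indices = self.residue_indices
        s.residue_types = self.residue_types
        s.positions = np.asarray(positions, dtype=float)
        if s.positions.shape != (self.n_atoms, 3):
            raise TopologyError("positions shape mismatch")
        return s

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Apply a rigid-body transform x -> R x + t."""
        return self.with_positions(self.positions @ np.asarray(rotation).T + translation)


@dataclass
class Ensemble:
    """Ordered conformers sharing one topology.

    ``coordinates`` has shape (n_frames, n_atoms, 3); ``topology`` supplies
    every per-atom label. ``frame_spacing_ps`` is the time between stored
    frames in picoseconds (purely metadata for axis labelling).
    """

    topology: Structure
    coordinates: np.ndarray
    frame_spacing_ps: float = 100.0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[1:] != (
            self.topology.n_atoms,
            3,
        ):
            raise TopologyError(
                f"coordinate array {self.coordinates.shape} does not match "
                f"topology with {self.topology.n_atoms} atoms"
            )
        if self.coordinates.shape[0] < 1:
            raise TopologyError("ensemble needs at least one frame")
        if not np.all(np.isfinite(self.coordinates)):
            raise TopologyError("non-finite coordinates in ensemble")

    @property
    def n_frames(self) -> int:
        return int(self.coordinates.shape[0])

    def frame(self, i: int) -> Structure:
        return self.topology.with_positions(self.coordinates[i])

    def frames(self) -> Iterator[Structure]:
        for i in range(self.n_frames):
            yield self.frame(i)

    @classmethod
    def from_structures(
        cls, structures: Sequence[Structure], frame_spacing_ps: float = 100.0
    ) -> "Ensemble":
        """Stack conformers, enforcing identical topology across frames."""
        if len(structures) == 0:
            raise TopologyError("cannot build an ensemble from zero frames")
        ref = structures[0]
        for k, s in enumerate(structures[1:], start=1):
            if (
                s.atom_names != ref.atom_names
                or not np.array_equal(s.residue_indices, ref.residue_indices)
                or not np.allclose(s.masses, ref.masses)
            ):
                raise TopologyError(f"frame {k} topology differs from frame 0")
        coords = np.stack([s.positions for s in structures])
        return cls(ref, coords, frame_spacing_ps)


class AtomSelection:
    """A reusable predicate over (atom_name, element, residue_index).

    Resolved lazily against a topology; the resolved index list is what
    geometry operations consume.
    """

    def __init__(
        self,
        predicate: Callable[[str, str, int], bool],
        description: str = "custom",
    ):
        self._predicate = predicate
        self.description = description

    def resolve(self, structure: Structure) -> np.ndarray:
        idx = np.array(
            [
                i
                for i in range(structure.n_atoms)
                if self._predicate(
                    structure.atom_names[i],
                    structure.elements[i],
                    int(structure.residue_indices[i]),
                )
            ],
            dtype=int,
        )
        return idx

    def resolve_nonempty(self, structure: Structure) -> np.ndarray:
        idx = self.resolve(structure)
        if idx.size == 0:
            raise SelectionError(f"selection {self.description!r} matches no atoms")
        return idx

    def __repr__(self) -> str:  # pragma: no cover
        return f"AtomSelection({self.description})"

    # -- common selections ------------------------------------------------

    @staticmethod
    def all() -> "AtomSelection":
        return AtomSelection(lambda n, e, r: True, "all")

    @staticmethod
    def heavy() -> "AtomSelection":
        return AtomSelection(lambda n, e, r: e.upper() != "H", "heavy")

    @staticmethod
    def ring_atoms() -> "AtomSelection":
        ring = {"C1", "C2", "C3", "C4", "C5", "O5"}
        return AtomSelection(lambda n, e, r: n in ring, "ring")

    @staticmethod
    def residues(indices: Iterable[int]) -> "AtomSelection":
        wanted = set(int(i) for i in indices)
        return AtomSelection(
            lambda n, e, r: r in wanted, f"residues {sorted(wanted)}"
        )

    @staticmethod
    def named(names: Iterable[str]) -> "AtomSelection":
        wanted = set(names)
        return AtomSelection(
            lambda n, e, r: n in wanted, f"named {sorted(wanted)}"
        )
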