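"""Core data model: structures, trajectories, torsion terms and atom selections.

All coordinates are stored in nanometres and all times in picoseconds.
Residue numbers are taken verbatim from the input (antibody work uses Eu
numbering); no renumbering is ever applied.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "SegmentClass",
    "AtomRecord",
    "TorsionTerm",
    "StructureModel",
    "Frame",
    "Trajectory",
    "SelectionSpec",
    "resolve_selection",
    "subsample",
    "ATOMIC_MASSES",
    "VDW_RADII",
]


class SegmentClass(str, Enum):
    """Coarse chemical class of an atom, inferred from its residue name."""

    PROTEIN = "protein"
    GLYCAN = "glycan"
    SOLVENT = "solvent"
    ION = "ion"


#: Standard atomic masses (u) for the elements that occur in protein/glycan systems.
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "F": 18.998, "CL": 35.45, "NA": 22.990, "K": 39.098,
    "MG": 24.305, "ZN": 65.38, "FE": 55.845,
}

#: Bondi van der Waals radii in nm, used as the default SASA radius set.
VDW_RADII = {
    "H": 0.120, "C": 0.170, "N": 0.155, "O": 0.152, "S": 0.180,
    "P": 0.180, "F": 0.147, "CL": 0.175, "NA": 0.227, "K": 0.275,
    "MG": 0.173, "ZN": 0.139, "FE": 0.160,
}


@dataclass(frozen=True)
class AtomRecord:
    """One atom with its identifiers.

    ``residue_number`` follows the numbering of the input file (Eu numbering
    for antibody constant domains).  ``glycan_index`` numbers glycan residues
    in attachment order and is set if and only if the atom is a glycan atom.
    """

    atom_id: int
    atom_name: str
    element: str
    residue_number: int
    residue_name: str
    chain_id: str
    segment_class: SegmentClass = SegmentClass.PROTEIN
    glycan_index: Optional[int] = None

    def __post_init__(self) -> None:
        is_glycan = self.segment_class == SegmentClass.GLYCAN
        if (self.glycan_index is not None) != is_glycan:
            raise ValueError(
                f"atom {self.atom_id}: glycan_index must be set iff the atom "
                f"is a glycan atom (segment_class={self.segment_class.value})"
            )


@dataclass(frozen=True)
class TorsionTerm:
    """One periodic torsional term V(phi) = K * [1 + cos(m*phi - delta)].

    Parameters
    ----------
    atom_ids : ordered quadruple of atom ids defining the dihedral
    force_constant_K : kJ/mol
    multiplicity_m : number of potential maxima per revolution (>= 1)
    phase_delta : phase shift in degrees (0 or 180 in common force fields)
    """

    atom_ids: tuple[int, int, int, int]
    force_constant_K: float
    multiplicity_m: int
    phase_delta: float

    def __post_init__(self) -> None:
        if len(self.atom_ids) != 4:
            raise ValueError("torsion term needs exactly 4 atom ids")
        if self.multiplicity_m < 1:
            raise ValueError("multiplicity_m must be >= 1")


class StructureModel:
    """An ordered collection of atoms plus bonds and torsion terms.

    Atom ids are unique, 1-based, and every bond/torsion refers to an
    existing atom.  Iteration order is file order.
    """

    def __init__(
        self,
        atoms: Sequence[AtomRecord],
        bonds: Iterable[tuple[int, int]] = (),
        torsion_terms: Sequence[TorsionTerm] = (),
    ) -> None:
        self.atoms = list(atoms)
        ids = [a.atom_id for a in self.atoms]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate atom ids: {dupes[:5]}")
        self._index = {a.atom_id: i for i, a in enumerate(self.atoms)}
        self.bonds = {tuple(sorted(b)) for b in bonds}
        self.torsion_terms = list(torsion_terms)
        known = set(ids)
        for a, b in self.bonds:
            if a not in known or b not in known:
                raise ValueError(f"bond ({a}, {b}) references unknown atom")
        for term in self.torsion_terms:
            for i in term.atom_ids:
                if i not in known:
                    raise ValueError(f"torsion term references unknown atom {i}")

    def __len__(self) -> int:
        return len(self.atoms)

    def atom(self, atom_id: int) -> AtomRecord:
        return self.atoms[self._index[atom_id]]

    def index_of(self, atom_id: int) -> int:
        """0-based positional index of an atom id."""
        return self._index[atom_id]

    def indices_of(self, atom_ids: Sequence[int]) -> np.ndarray:
        return np.asarray([self._index[i] for i in atom_ids], dtype=np.intp)

    def bonded_to(self, atom_id: int) -> list[int]:
        return sorted(
            (b if a == atom_id else a)
            for a, b in self.bonds
            if atom_id in (a, b)
        )

    def masses(self, atom_ids: Sequence[int]) -> np.ndarray:
        out = np.empty(len(atom_ids))
        for k, i in enumerate(atom_ids):
            el = self.atom(i).element.upper()
            try:
                out[k] = ATOMIC_MASSES[el]
            except KeyError:
                raise KeyError(f"no atomic mass tabulated for element {el!r}") from None
        return out


@dataclass
class Frame:
    """One trajectory frame: per-atom coordinates (nm), optional rectangular
    box edge lengths (nm) and a time stamp (ps)."""

    coordinates: np.ndarray
    time: float = 0.0
    box: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be an (n_atoms, 3) array")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3,) or np.any(self.box <= 0):
                raise ValueError("box must be 3 strictly positive edge lengths")


class Trajectory:
    """Time-ordered frames sharing one atom layout."""

    def __init__(self, frames: Sequence[Frame], frame_spacing: Optional[float] = None):
        if not frames:
            raise ValueError("trajectory needs at least one frame")
        n = frames[0].coordinates.shape[0]
        for k, fr in enumerate(frames):
            if fr.coordinates.shape[0] != n:
                raise ValueError(
                    f"frame {k}: atom count {fr.coordinates.shape[0]} != {n}"
                )
        times = np.asarray([fr.time for fr in frames])
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("frame times must be strictly increasing")
        if frame_spacing is None:
            frame_spacing = float(times[1] - times[0]) if len(times) > 1 else 1.0
        self.frames = list(frames)
        self.frame_spacing = float(frame_spacing)

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, k: int) -> Frame:
        return self.frames[k]

    def __iter__(self):
        return iter(self.frames)

    @property
    def n_atoms(self) -> int:
        return self.frames[0].coordinates.shape[0]

    def coordinates(self) -> np.ndarray:
        """Stacked (n_frames, n_atoms, 3) coordinate array."""
        return np.stack([fr.coordinates for fr in self.frames])

    def times(self) -> np.ndarray:
        return np.asarray([fr.time for fr in self.frames])


@dataclass(frozen=True)
class SelectionSpec:
    """Declarative atom selection.

    Criteria combine conjunctively; a spec with no criteria selects nothing.
    ``residue_ranges`` are inclusive [lo, hi] pairs; an atom matches if its
    residue number falls in any range.
    """

    chain_ids: Optional[frozenset[str]] = None
    residue_ranges: Optional[tuple[tuple[int, int], ...]] = None
    atom_names: Optional[frozenset[str]] = None
    segment_classes: Optional[frozenset[SegmentClass]] = None

    @classmethod
    def make(cls, chain_ids=None, residue_ranges=None, atom_names=None,
             segment_classes=None) -> "SelectionSpec":
        """Convenience constructor accepting plain lists/strings."""
        if segment_classes is not None:
            segment_classes = frozenset(
                SegmentClass(s) if not isinstance(s, SegmentClass) else s
                for s in segment_classes
            )
        return cls(
            chain_ids=frozenset(chain_ids) if chain_ids is not None else None,
            residue_ranges=tuple(tuple(r) for r in residue_ranges)
            if residue_ranges is not None else None,
            atom_names=frozenset(atom_names) if atom_names is not None else None,
            segment_classes=segment_classes,
        )

    def is_empty(self) -> bool:
        return (self.chain_ids is None and self.residue_ranges is None
                and self.atom_names is None and self.segment_classes is None)

    def matches(self, atom: AtomRecord) -> bool:
        if self.is_empty():
            return False
        if self.chain_ids is not None and atom.chain_id not in self.chain_ids:
            return False
        if self.atom_names is not None and atom.atom_name not in self.atom_names:
            return False
        if self.segment_classes is not None and atom.segment_class not in self.segment_classes:
            return False
        if self.residue_ranges is not None:
            for lo, hi in self.residue_ranges:
                if lo > hi:
                    raise ValueError(f"residue range [{lo}, {hi}] has lo > hi")
                if lo <= atom.residue_number <= hi:
                    break
            else:
                return False
        return True


def resolve_selection(model: StructureModel, spec: SelectionSpec) -> list[int]:
    """Atom ids matching *spec*, in file order.

    All present criteria must hold simultaneously (conjunction); a spec with
    no criteria resolves to the empty list.
    """
    if spec.residue_ranges is not None:
        for lo, hi in spec.residue_ranges:
            if lo > hi:
                raise ValueError(f"residue range [{lo}, {hi}] has lo > hi")
    return [a.atom_id for a in model.atoms if spec.matches(a)]


def subsample(traj: Trajectory, interval: float) -> Trajectory:
    """Keep the first frame and every frame offset from it by a multiple of
    *interval* (ps).

    The interval must be a positive multiple of the trajectory's frame
    spacing; trajectory analyses conventionally run on frames 2 ps apart.
    """
    if interval <= 0:
        raise ValueError("interval must be positive")
    step = interval / traj.frame_spacing
    if abs(step - round(step)) > 1e-9:
        raise ValueError(
            f"interval {interval} ps is not a multiple of the frame spacing "
            f"{traj.frame_spacing} ps"
        )
    step = int(round(step))
    return Trajectory(traj.frames[::step], frame_spacing=interval)
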