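"""Reading and writing structures, trajectories and torsion-term tables.

PDB is the mandatory interchange format: a single-model file for the
structure and a multi-model file (MODEL/ENDMDL) for trajectories, with the
periodic box taken from the CRYST1 record.  PDB stores Angstrom; everything
is converted to nm on read and back on write.
"""
from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio

from .model import (
    AtomRecord,
    Frame,
    SegmentClass,
    StructureModel,
    TorsionTerm,
    Trajectory,
)

__all__ = [
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "read_torsion_table",
    "write_torsion_table",
    "SOLVENT_RESIDUES",
    "GLYCAN_RESIDUES",
    "ION_RESIDUES",
]

#: Default residue-name lists driving segment classification.
SOLVENT_RESIDUES = {"HOH", "SOL", "WAT", "TIP", "SPC"}
GLYCAN_RESIDUES = {"NAG", "NDG", "MAN", "BMA", "FUC", "GAL", "GLC", "BGC", "SIA"}
ION_RESIDUES = {"NA", "CL", "K", "MG", "ZN", "BR", "CS", "LI"}

_NM_PER_ANGSTROM = 0.1


class PDBParseError(ValueError):
    """Raised for malformed PDB records, naming the offending line."""


def _prescan(path: str) -> tuple[list[int], set[tuple[int, int]]]:
    """Validate ATOM/HETATM records; collect model sizes and CONECT bonds.

    Returns one atom count per MODEL block (a single count for files
    without MODEL records) and the bonds declared by CONECT records, as
    serial-number pairs.  Raises :class:`PDBParseError` with the 1-based
    line number for records that are too short or carry unparseable
    coordinates.
    """
    counts: list[int] = []
    bonds: set[tuple[int, int]] = set()
    current = 0
    saw_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "CONECT":
                fields = [line[i:i + 5].strip() for i in range(6, 27, 5)]
                try:
                    serials = [int(f) for f in fields if f]
                except ValueError:
                    raise PDBParseError(
                        f"{path}: line {lineno}: unparseable CONECT record"
                    ) from None
                for other in serials[1:]:
                    bonds.add(tuple(sorted((serials[0], other))))
            elif rec in ("ATOM", "HETATM"):
                if len(line.rstrip("\n")) < 54:
                    raise PDBParseError(
                        f"{path}: line {lineno}: truncated {rec} record"
                    )
                try:
                    float(line[30:38]), float(line[38:46]), float(line[46:54])
                except ValueError:
                    raise PDBParseError(
                        f"{path}: line {lineno}: unparseable coordinates in "
                        f"{rec} record"
                    ) from None
                current += 1
            elif rec == "MODEL":
                saw_model = True
                current = 0
            elif rec == "ENDMDL":
                counts.append(current)
    if not saw_model:
        counts = [current]
    elif current and not counts:
        counts = [current]
    return counts, bonds


def _classify(res_name: str, solvent=None, glycan=None, ion=None) -> SegmentClass:
    name = res_name.strip().upper()
    if name in (solvent if solvent is not None else SOLVENT_RESIDUES):
        return SegmentClass.SOLVENT
    if name in (glycan if glycan is not None else GLYCAN_RESIDUES):
        return SegmentClass.GLYCAN
    if name in (ion if ion is not None else ION_RESIDUES):
        return SegmentClass.ION
    return SegmentClass.PROTEIN


def _guess_element(atom_name: str) -> str:
    stripped = atom_name.strip()
    if stripped[:2].upper() in ("CL", "NA", "MG", "ZN", "FE", "BR"):
        return stripped[:2].upper()
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return "C"


def _atoms_from_array(array: struc.AtomArray, solvent=None, glycan=None,
                      ion=None) -> list[AtomRecord]:
    n = array.array_length()
    if "atom_id" in array.get_annotation_categories() and np.all(array.atom_id > 0):
        atom_ids = array.atom_id.astype(int)
    else:
        atom_ids = np.arange(1, n + 1)
    # glycan residues are numbered in order of appearance, per chain,
    # mirroring the order in which they are attached to the glycan tree
    glycan_counters: dict[str, int] = {}
    glycan_ids: dict[tuple[str, int], int] = {}
    records = []
    for i in range(n):
        res_name = str(array.res_name[i])
        chain = str(array.chain_id[i]).strip() or "A"
        seg = _classify(res_name, solvent, glycan, ion)
        gidx = None
        if seg == SegmentClass.GLYCAN:
            key = (chain, int(array.res_id[i]))
            if key not in glycan_ids:
                glycan_counters[chain] = glycan_counters.get(chain, 0) + 1
                glycan_ids[key] = glycan_counters[chain]
            gidx = glycan_ids[key]
        element = str(array.element[i]).strip().upper()
        if not element:
            element = _guess_element(str(array.atom_name[i]))
        records.append(AtomRecord(
            atom_id=int(atom_ids[i]),
            atom_name=str(array.atom_name[i]).strip(),
            element=element,
            residue_number=int(array.res_id[i]),
            residue_name=res_name.strip(),
            chain_id=chain,
            segment_class=seg,
            glycan_index=gidx,
        ))
    return records


def _box_from(box_matrix: Optional[np.ndarray]) -> Optional[np.ndarray]:
    if box_matrix is None:
        return None
    diag = np.diagonal(box_matrix)
    if np.any(diag <= 0):
        return None
    off = box_matrix - np.diag(diag)
    if np.any(np.abs(off) > 1e-6):
        warnings.warn("non-rectangular box in CRYST1; using edge lengths only")
    return diag * _NM_PER_ANGSTROM


def read_structure(path, format: str = "pdb", *, solvent_residues=None,
                   glycan_residues=None, ion_residues=None) -> StructureModel:
    """Read a PDB file into a :class:`StructureModel`.

    Atoms keep file order and identifiers; the segment class of each atom is
    inferred from its residue name against configurable residue-name lists.
    """
    if format != "pdb":
        raise ValueError(f"unsupported structure format: {format!r}")
    _, bonds = _prescan(str(path))
    pdb = pdbio.PDBFile.read(str(path))
    array = pdb.get_structure(model=1, extra_fields=["atom_id"])
    atoms = _atoms_from_array(array, solvent_residues, glycan_residues,
                              ion_residues)
    return StructureModel(atoms, bonds)


def read_trajectory(path, format: str = "multi_model_pdb",
                    model: Optional[StructureModel] = None, *,
                    frame_spacing: float = 2.0) -> Trajectory:
    """Read a multi-model PDB as a trajectory.

    Frame times are ``k * frame_spacing`` ps.  When *model* is given, every
    frame's atom count is checked against it and a mismatch names the frame.
    The box is taken from the CRYST1 record when present (applied to all
    frames, as PDB stores a single cell).
    """
    if format not in ("multi_model_pdb", "pdb"):
        raise ValueError(f"unsupported trajectory format: {format!r}")
    counts, _ = _prescan(str(path))
    if model is not None:
        for k, c in enumerate(counts):
            if c != len(model):
                raise ValueError(
                    f"{path}: frame {k} has {c} atoms, structure has "
                    f"{len(model)}"
                )
    pdb = pdbio.PDBFile.read(str(path))
    stack = pdb.get_structure()
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    coords = np.asarray(stack.coord, dtype=float) * _NM_PER_ANGSTROM
    if stack.box is not None:
        boxes = np.atleast_3d(stack.box)
        box = _box_from(boxes[0] if boxes.ndim == 3 else boxes)
    else:
        box = None
    frames = [
        Frame(coords[k], time=k * frame_spacing, box=box)
        for k in range(coords.shape[0])
    ]
    return Trajectory(frames, frame_spacing=frame_spacing)


def _array_from_model(model: StructureModel, coords_nm: np.ndarray) -> struc.AtomArray:
    n = len(model)
    array = struc.AtomArray(n)
    array.coord = np.asarray(coords_nm, dtype=np.float32) / _NM_PER_ANGSTROM
    array.set_annotation("atom_id", np.asarray([a.atom_id for a in model.atoms]))
    array.chain_id = np.asarray([a.chain_id for a in model.atoms])
    array.res_id = np.asarray([a.residue_number for a in model.atoms])
    array.res_name = np.asarray([a.residue_name for a in model.atoms])
    array.atom_name = np.asarray([a.atom_name for a in model.atoms])
    array.element = np.asarray([a.element for a in model.atoms])
    array.hetero = np.asarray(
        [a.segment_class != SegmentClass.PROTEIN for a in model.atoms]
    )
    return array


def _append_conect(path, model: StructureModel) -> None:
    if not model.bonds:
        return
    with open(path, "a") as fh:
        for a, b in sorted(model.bonds):
            fh.write(f"CONECT{a:>5d}{b:>5d}\n")


def write_structure(path, model: StructureModel, frame: Frame) -> None:
    """Write a single-model PDB (coordinates converted to Angstrom).

    Bonds are emitted as CONECT records so connectivity-dependent analyses
    (hydrogen-bond donors) survive a file round-trip.
    """
    array = _array_from_model(model, frame.coordinates)
    if frame.box is not None:
        array.box = np.diag(frame.box / _NM_PER_ANGSTROM)
    pdb = pdbio.PDBFile()
    pdb.set_structure(array)
    pdb.write(str(path))
    _append_conect(str(path), model)


def write_trajectory(path, model: StructureModel, traj: Trajectory) -> None:
    """Write a trajectory as a multi-model PDB with CRYST1 from frame 0."""
    arrays = []
    for fr in traj:
        a = _array_from_model(model, fr.coordinates)
        arrays.append(a)
    stack = struc.stack(arrays)
    box0 = traj[0].box
    if box0 is not None:
        stack.box = np.broadcast_to(
            np.diag(box0 / _NM_PER_ANGSTROM), (len(traj), 3, 3)
        ).copy()
    pdb = pdbio.PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))
    _append_conect(str(path), model)


_TORSION_COLUMNS = ["atom1", "atom2", "atom3", "atom4", "K", "m", "delta"]


def read_torsion_table(path) -> list[TorsionTerm]:
    """Read torsion terms from TSV (atom1..atom4, K [kJ/mol], m, delta [deg])."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _TORSION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"torsion table missing columns: {missing}")
    return [
        TorsionTerm(
            atom_ids=(int(r.atom1), int(r.atom2), int(r.atom3), int(r.atom4)),
            force_constant_K=float(r.K),
            multiplicity_m=int(r.m),
            phase_delta=float(r.delta),
        )
        for r in df.itertuples()
    ]


def write_torsion_table(path, terms: Sequence[TorsionTerm]) -> None:
    df = pd.DataFrame(
        [
            {
                "atom1": t.atom_ids[0], "atom2": t.atom_ids[1],
                "atom3": t.atom_ids[2], "atom4": t.atom_ids[3],
                "K": t.force_constant_K, "m": t.multiplicity_m,
                "delta": t.phase_delta,
            }
            for t in terms
        ],
        columns=_TORSION_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)
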