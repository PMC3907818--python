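"""Inter-domain orientation descriptors, periodic-image contacts and
ring-stacking geometry.

The relative orientation of two rigid domains is described by the angle
between their principal axes and by a pseudo-dihedral: the torsion of the
two axes about the line connecting the domain centers of geometry.  Each
axis is the eigenvector of the largest eigenvalue of the covariance matrix
of atomic positions, with its sign kept continuous across frames.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence
import warnings

import numpy as np
from scipy.spatial.distance import cdist

from .dihedrals import dihedral_angle
from .model import Frame, StructureModel

__all__ = [
    "DomainFrameDescriptor",
    "center_of_geometry",
    "principal_axis",
    "interdomain_angle",
    "interdomain_dihedral",
    "periodic_contact",
    "ring_geometry",
]


@dataclass(frozen=True)
class DomainFrameDescriptor:
    """A domain's center of geometry and sign-continuous principal axis in
    one frame."""

    domain_label: str
    center: np.ndarray
    axis: np.ndarray


def center_of_geometry(frame: Frame, model: StructureModel,
                       sel: Sequence[int]) -> np.ndarray:
    """Unweighted mean position (nm) of the selected atoms."""
    if len(sel) == 0:
        raise ValueError("empty selection")
    return frame.coordinates[model.indices_of(sel)].mean(axis=0)


def principal_axis(frame: Frame, model: StructureModel, sel: Sequence[int],
                   prev_axis: Optional[np.ndarray] = None,
                   eigengap_tol: float = 1e-8) -> np.ndarray:
    """Leading eigenvector of the positional covariance matrix, unit length.

    The eigenvector sign is fixed by continuity with *prev_axis* (flip if the
    dot product is negative); without a previous axis the sign is chosen so
    that the largest-magnitude component is positive.  A (near-)degenerate
    leading eigenvalue is an error, since the axis is then meaningless.
    """
    if len(sel) < 3:
        raise ValueError("principal axis needs at least 3 atoms")
    coords = frame.coordinates[model.indices_of(sel)]
    cov = np.cov(coords.T, bias=True)
    evals, evecs = np.linalg.eigh(cov)
    gap = evals[2] - evals[1]
    if gap <= eigengap_tol * max(evals[2], 1e-300):
        raise ValueError(
            f"degenerate leading eigenvalue (eigengap {gap:.3e}); "
            "principal axis undefined"
        )
    axis = evecs[:, 2]
    axis = axis / np.linalg.norm(axis)
    if prev_axis is not None:
        if axis @ np.asarray(prev_axis) < 0:
            axis = -axis
    else:
        if axis[np.argmax(np.abs(axis))] < 0:
            axis = -axis
    return axis


def interdomain_angle(axis1: np.ndarray, axis2: np.ndarray) -> float:
    """Angle (deg, in [0, 180]) between two unit axes."""
    c = float(np.dot(axis1, axis2))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def interdomain_dihedral(axis1: np.ndarray, center1: np.ndarray,
                         center2: np.ndarray, axis2: np.ndarray) -> float:
    """Torsion (deg, in (-180, 180]) of two domain axes about the line
    connecting the two domain centers.

    Computed as the dihedral of the four points (center1 + axis1, center1,
    center2, center2 + axis2).  An axis parallel to the inter-center line
    leaves the torsion undefined and is an error.
    """
    c1 = np.asarray(center1, dtype=float)
    c2 = np.asarray(center2, dtype=float)
    sep = c2 - c1
    nsep = np.linalg.norm(sep)
    if nsep < 1e-12:
        raise ValueError("coincident domain centers")
    u = sep / nsep
    for name, ax in (("axis1", axis1), ("axis2", axis2)):
        if np.linalg.norm(np.cross(ax, u)) < 1e-6:
            raise ValueError(f"{name} is parallel to the inter-center axis; "
                             "torsion undefined")
    return dihedral_angle(c1 + np.asarray(axis1), c1, c2, c2 + np.asarray(axis2))


_NEIGHBOR_SHIFTS = np.array([
    (i, j, k)
    for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
    if (i, j, k) != (0, 0, 0)
], dtype=float)


def periodic_contact(frame: Frame, model: StructureModel,
                     solute_sel: Sequence[int], cutoff: float = 1.4) -> dict:
    """Shortest distance from the solute to any of its periodic images.

    Considers the 26 neighbor images of a rectangular box (sufficient when
    the cutoff is below half the smallest box edge — checked, warned
    otherwise).  Self-image pairs are included: even a single atom has a
    nearest nonzero image one box length away.  Returns
    ``{"flag": bool, "min_image_distance": nm}`` with ``flag`` true when the
    minimum image distance falls below *cutoff*, i.e. the solute can
    interact with its own periodic copy within the long-range cutoff.
    """
    if frame.box is None:
        raise ValueError("periodic contact analysis needs a box")
    box = frame.box
    if cutoff > box.min() / 2:
        warnings.warn(
            "cutoff exceeds half the smallest box edge; images beyond the "
            "26 neighbors could in principle be closer"
        )
    coords = frame.coordinates[model.indices_of(solute_sel)]
    best = np.inf
    for shift in _NEIGHBOR_SHIFTS * box:
        d = cdist(coords, coords + shift).min()
        best = min(best, float(d))
    return {"flag": best < cutoff, "min_image_distance": best}


def _plane_normal(coords: np.ndarray) -> np.ndarray:
    """Unit normal of the least-squares plane through a point set."""
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered
    evals, evecs = np.linalg.eigh(cov)
    if evals[1] < 1e-12 * max(evals[2], 1e-300):
        raise ValueError("ring atoms are (nearly) collinear; plane undefined")
    return evecs[:, 0]


def ring_geometry(frame: Frame, model: StructureModel,
                  ringA_sel: Sequence[int], ringB_sel: Sequence[int]) -> dict:
    """Centroid distance and plane angle between two rings.

    The plane angle is the angle between the least-squares plane normals,
    folded into [0, 90] (0 = parallel stacking, 90 = T-stack).
    """
    a = frame.coordinates[model.indices_of(ringA_sel)]
    b = frame.coordinates[model.indices_of(ringB_sel)]
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each ring needs at least 3 atoms")
    na, nb = _plane_normal(a), _plane_normal(b)
    c = abs(float(na @ nb))
    angle = float(np.degrees(np.arccos(np.clip(c, 0.0, 1.0))))
    dist = float(np.linalg.norm(a.mean(axis=0) - b.mean(axis=0)))
    return {"centroid_distance": dist, "plane_angle": angle}
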