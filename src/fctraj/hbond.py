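"""Geometric hydrogen-bond detection and prevalence statistics.

A donor-hydrogen-acceptor triplet is hydrogen bonded in a frame when the
hydrogen-acceptor distance is at most 0.25 nm and the donor-hydrogen-
acceptor angle (hydrogen at the vertex; 180 deg = linear) is at least
135 deg.  Each distinct (D, H, A) triplet is counted once per frame and its
prevalence is the percentage of frames in which it is bonded.  Prevalences
aggregate by summation over residue/domain/chain groups, so group-level
values routinely exceed 100%.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import Frame, SelectionSpec, StructureModel, Trajectory, resolve_selection

__all__ = [
    "HBondCriteria",
    "HBondRecord",
    "detect_frame",
    "candidate_triplets",
    "prevalence",
    "aggregate",
]

logger = logging.getLogger(__name__)

#: Elements that can act as hydrogen-bond donors or acceptors.
_POLAR_ELEMENTS = {"N", "O"}


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond criteria.

    ``max_h_acceptor_distance`` in nm (default 0.25) and ``min_dha_angle``
    in degrees (default 135).  Boundary comparisons are inclusive.
    """

    max_h_acceptor_distance: float = 0.25
    min_dha_angle: float = 135.0

    def __post_init__(self) -> None:
        if self.max_h_acceptor_distance <= 0:
            raise ValueError("distance criterion must be positive")
        if not (0 < self.min_dha_angle <= 180):
            raise ValueError("angle criterion must be in (0, 180]")


@dataclass(frozen=True)
class HBondRecord:
    """A unique donor-hydrogen-acceptor triplet and its prevalence, as the
    percentage of analyzed frames in which it satisfies the criteria."""

    donor_id: int
    hydrogen_id: int
    acceptor_id: int
    prevalence: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.prevalence <= 100.0):
            raise ValueError("prevalence must lie in [0, 100]")


def _dha_angles(d: np.ndarray, h: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Donor-hydrogen-acceptor angles in degrees, hydrogen at the vertex."""
    v1 = d - h
    v2 = a - h
    n1 = np.linalg.norm(v1, axis=-1)
    n2 = np.linalg.norm(v2, axis=-1)
    cosang = np.einsum("...i,...i->...", v1, v2) / (n1 * n2)
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def detect_frame(frame: Frame, model: StructureModel,
                 triplets: Sequence[tuple[int, int, int]],
                 criteria: HBondCriteria = HBondCriteria(),
                 ) -> set[tuple[int, int, int]]:
    """Triplets satisfying both geometric criteria in one frame."""
    if not triplets:
        return set()
    trip = np.asarray(triplets, dtype=int)
    try:
        didx = model.indices_of(trip[:, 0])
        hidx = model.indices_of(trip[:, 1])
        aidx = model.indices_of(trip[:, 2])
    except KeyError as exc:
        raise ValueError(f"triplet references unknown atom: {exc}") from None
    coords = frame.coordinates
    d, h, a = coords[didx], coords[hidx], coords[aidx]
    dist = np.linalg.norm(a - h, axis=1)
    ang = _dha_angles(d, h, a)
    ok = (dist <= criteria.max_h_acceptor_distance) & (ang >= criteria.min_dha_angle)
    return {tuple(t) for t in trip[ok]}


def candidate_triplets(model: StructureModel, donor_sel: SelectionSpec,
                       acceptor_sel: SelectionSpec) -> list[tuple[int, int, int]]:
    """All (donor, hydrogen, acceptor) triplets eligible under the selections.

    Donors are N/O atoms in *donor_sel* with at least one bonded hydrogen;
    acceptors are N/O atoms in *acceptor_sel*; donor and acceptor must be
    distinct atoms.  Donors without a bonded hydrogen (e.g. united-atom
    inputs) are skipped with a warning.
    """
    donor_ids = [i for i in resolve_selection(model, donor_sel)
                 if model.atom(i).element.upper() in _POLAR_ELEMENTS]
    acceptor_ids = [i for i in resolve_selection(model, acceptor_sel)
                    if model.atom(i).element.upper() in _POLAR_ELEMENTS]
    triplets = []
    for d in donor_ids:
        hydrogens = [j for j in model.bonded_to(d)
                     if model.atom(j).element.upper() == "H"]
        if not hydrogens:
            logger.warning("donor atom %d has no bonded hydrogen; skipped", d)
            continue
        for h in hydrogens:
            for a in acceptor_ids:
                if a != d:
                    triplets.append((d, h, a))
    return triplets


def prevalence(traj: Trajectory, model: StructureModel,
               triplets: Sequence[tuple[int, int, int]],
               criteria: HBondCriteria = HBondCriteria()) -> list[HBondRecord]:
    """Per-triplet prevalence over a trajectory.

    Returns one record per triplet observed in at least one frame (0%
    triplets are omitted), in triplet order.
    """
    if len(traj) < 1:
        raise ValueError("prevalence needs at least one frame")
    counts = {tuple(t): 0 for t in triplets}
    for frame in traj:
        for t in detect_frame(frame, model, triplets, criteria):
            counts[t] += 1
    n = len(traj)
    return [
        HBondRecord(donor_id=t[0], hydrogen_id=t[1], acceptor_id=t[2],
                    prevalence=100.0 * c / n)
        for t, c in counts.items() if c > 0
    ]


def aggregate(records: Sequence[HBondRecord], model: StructureModel,
              from_group: SelectionSpec, to_group: SelectionSpec) -> float:
    """Summed prevalence (%) of hydrogen bonds between two atom groups.

    A record contributes when its donor side (donor or hydrogen atom) lies
    in one group and its acceptor in the other, in either orientation; each
    unique triplet is counted once even if both endpoints fall in both
    groups.  Sums over many bonds may exceed 100 by design.
    """
    from_ids = set(resolve_selection(model, from_group))
    to_ids = set(resolve_selection(model, to_group))
    total = 0.0
    for rec in records:
        donor_side = {rec.donor_id, rec.hydrogen_id}
        forward = bool(donor_side & from_ids) and rec.acceptor_id in to_ids
        reverse = bool(donor_side & to_ids) and rec.acceptor_id in from_ids
        if forward or reverse:
            total += rec.prevalence
    return total
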