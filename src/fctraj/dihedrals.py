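"""Dihedral angles and transition counting against torsional-potential maxima.

A transition is counted whenever the dihedral angle crosses a maximum of the
torsional potential V(phi) = K * [1 + cos(m*phi - delta)] between subsequent
trajectory snapshots.  Between two snapshots the angle is assumed to move
along the shortest angular path (ties of exactly 180 deg resolved in the
positive direction); every maximum lying strictly inside that arc counts as
one crossing.  A sample landing exactly on a maximum is only counted once
the angle subsequently departs to the other side.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import Frame, StructureModel, TorsionTerm, Trajectory

__all__ = [
    "DihedralSeries",
    "dihedral_angle",
    "dihedral_series",
    "torsion_maxima",
    "count_transitions",
]

_TOL = 1e-9


def wrap_angle(angle_deg) -> np.ndarray | float:
    """Map angles into the canonical interval (-180, 180]."""
    a = np.asarray(angle_deg, dtype=float)
    out = -(np.mod(-a + 180.0, 360.0) - 180.0)
    return float(out) if np.isscalar(angle_deg) or out.ndim == 0 else out


@dataclass
class DihedralSeries:
    """Per-frame dihedral angles (degrees, in (-180, 180]) for one torsion."""

    term: TorsionTerm
    angles: np.ndarray

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if np.any(self.angles <= -180.0 - _TOL) or np.any(self.angles > 180.0 + _TOL):
            raise ValueError("angles must lie in (-180, 180]")


def dihedral_angle(p1, p2, p3, p4) -> float:
    """Dihedral angle in degrees, IUPAC sign convention (cis = 0, trans = 180).

    Looking down the p2->p3 axis, a clockwise rotation of the far bond
    relative to the near bond is positive; the result lies in (-180, 180].
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    if np.linalg.norm(b1) < _TOL or np.linalg.norm(b2) < _TOL or np.linalg.norm(b3) < _TOL:
        raise ValueError("degenerate dihedral: consecutive points coincide")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < _TOL or np.linalg.norm(n2) < _TOL:
        raise ValueError("degenerate dihedral: collinear bond vectors")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = n1 @ n2
    y = m1 @ n2
    return wrap_angle(np.degrees(np.arctan2(y, x)))


def dihedral_series(traj: Trajectory, model: StructureModel,
                    term: TorsionTerm) -> DihedralSeries:
    """Dihedral angle of a torsion term evaluated in every frame."""
    idx = model.indices_of(term.atom_ids)
    angles = np.array([
        dihedral_angle(*frame.coordinates[idx]) for frame in traj
    ])
    return DihedralSeries(term=term, angles=angles)


def torsion_maxima(term: TorsionTerm) -> list[float]:
    """Angles (deg, in (-180, 180], sorted) where V(phi) is maximal.

    For V(phi) = K[1 + cos(m*phi - delta)] with K > 0 the maxima sit where
    cos(m*phi - delta) = +1, i.e. phi = (delta + 360 k) / m for k = 0..m-1.
    """
    if term.force_constant_K <= 0:
        raise ValueError("torsion term with K <= 0 has no defined maxima")
    m = term.multiplicity_m
    maxima = {wrap_angle((term.phase_delta + 360.0 * k) / m) for k in range(m)}
    return sorted(maxima)


def _unwrap(angles: np.ndarray) -> np.ndarray:
    """Accumulate shortest-path steps; steps of exactly 180 go positive."""
    a = np.asarray(angles, dtype=float)
    out = np.empty_like(a)
    out[0] = a[0]
    for k in range(1, len(a)):
        delta = wrap_angle(a[k] - a[k - 1])
        if abs(delta + 180.0) < _TOL:  # wrap_angle maps -180 to 180 already
            delta = 180.0
        out[k] = out[k - 1] + delta
    return out


def count_transitions(series: DihedralSeries,
                      maxima: Sequence[float] | None = None) -> int:
    """Number of crossings of torsional-potential maxima along a series.

    The angle path between consecutive samples is the shortest arc; maxima
    strictly inside an arc each count once.  A sample exactly on a maximum
    is a pending crossing, realized only when the path departs to the side
    opposite the approach (so repeated sampling of a boundary value is never
    double counted).
    """
    if len(series.angles) < 2:
        raise ValueError("transition counting needs at least 2 frames")
    if maxima is None:
        maxima = torsion_maxima(series.term)
    maxima = sorted(wrap_angle(m) for m in maxima)
    theta = _unwrap(series.angles)

    def levels_between(lo: float, hi: float):
        """Maxima levels (mu + 360k) strictly inside (lo, hi)."""
        count = 0
        for mu in maxima:
            k_lo = int(np.ceil((lo - mu) / 360.0))
            k_hi = int(np.floor((hi - mu) / 360.0))
            for k in range(k_lo, k_hi + 1):
                level = mu + 360.0 * k
                if lo + _TOL < level < hi - _TOL:
                    count += 1
        return count

    def on_level(x: float) -> bool:
        return any(
            abs((x - mu) / 360.0 - round((x - mu) / 360.0)) * 360.0 < 1e-6
            for mu in maxima
        )

    count = 0
    pending_side = None  # side from which a currently-touched maximum was approached
    for k in range(1, len(theta)):
        a, b = theta[k - 1], theta[k]
        lo, hi = (a, b) if a <= b else (b, a)
        count += levels_between(lo, hi)
        if b == a:
            continue
        step_sign = 1.0 if b > a else -1.0
        if pending_side is not None:
            # departing a touched maximum: crossing iff we leave the other way
            if step_sign != pending_side:
                count += 1
            pending_side = None
        if on_level(b):
            # arrived exactly on a maximum; remember the approach side
            pending_side = -step_sign
    return count
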