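"""Roto-translational superposition and the positional statistics built on it.

RMSD is computed per frame against the first set of coordinates after a
roto-translational (Kabsch) fit on a chosen atom selection — conventionally
the backbone atoms C, CA and N of the domains of interest.  RMSF is the
per-atom fluctuation about the mean position of the fitted trajectory.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .model import Frame, StructureModel, Trajectory

__all__ = [
    "SuperpositionResult",
    "superpose",
    "apply_superposition",
    "rmsd_series",
    "rmsf",
    "radius_of_gyration",
]


@dataclass(frozen=True)
class SuperpositionResult:
    """Rigid transform x -> R x + t minimizing the weighted RMSD, plus the
    RMSD attained on the fit selection."""

    rotation: np.ndarray
    translation: np.ndarray
    fitted_rmsd: float


def superpose(ref_coords: np.ndarray, mov_coords: np.ndarray,
              weights: Optional[np.ndarray] = None) -> SuperpositionResult:
    """Kabsch superposition of *mov_coords* onto *ref_coords*.

    Uses the SVD formulation with reflection correction, so the returned
    rotation is always proper (det = +1).  Requires at least 3 points that
    are not all collinear.
    """
    ref = np.asarray(ref_coords, dtype=float)
    mov = np.asarray(mov_coords, dtype=float)
    if ref.shape != mov.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("ref and mov must be equal-shape (n, 3) arrays")
    n = ref.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 points")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be n non-negative values, not all zero")
    w = w / w.sum()

    ref_c = w @ ref
    mov_c = w @ mov
    P = (mov - mov_c) * w[:, None]
    Q = ref - ref_c
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    # collinear point sets leave the rotation about the line undetermined
    if S[1] <= 1e-12 * max(S[0], 1e-300):
        raise ValueError("degenerate geometry: points are (nearly) collinear")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ref_c - R @ mov_c
    fitted = (mov @ R.T + t) - ref
    rmsd = float(np.sqrt(np.sum(w * np.sum(fitted**2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, fitted_rmsd=rmsd)


def apply_superposition(result: SuperpositionResult, coords: np.ndarray) -> np.ndarray:
    return np.asarray(coords) @ result.rotation.T + result.translation


def _fit_frames(traj: Trajectory, model: StructureModel,
                fit_sel: Sequence[int]) -> np.ndarray:
    """All frames superposed onto frame 0 using the fit selection.

    Returns an (n_frames, n_atoms, 3) array of fitted coordinates.
    """
    if not len(fit_sel):
        raise ValueError("empty fit selection")
    idx = model.indices_of(fit_sel)
    coords = traj.coordinates()
    ref = coords[0, idx]
    out = np.empty_like(coords)
    out[0] = coords[0]
    for k in range(1, coords.shape[0]):
        res = superpose(ref, coords[k, idx])
        out[k] = apply_superposition(res, coords[k])
    return out


def rmsd_series(traj: Trajectory, model: StructureModel,
                fit_sel: Sequence[int], calc_sel: Sequence[int]) -> np.ndarray:
    """Per-frame RMSD (nm) of *calc_sel* relative to frame 0, after fitting
    each frame to frame 0 on *fit_sel*.

    The first value is exactly 0 by construction.
    """
    if not len(calc_sel):
        raise ValueError("empty calc selection")
    fitted = _fit_frames(traj, model, fit_sel)
    cidx = model.indices_of(calc_sel)
    ref = fitted[0, cidx]
    diffs = fitted[:, cidx] - ref
    out = np.sqrt(np.mean(np.sum(diffs**2, axis=2), axis=1))
    out[0] = 0.0
    return out


def rmsf(traj: Trajectory, model: StructureModel,
         fit_sel: Sequence[int], calc_sel: Sequence[int]) -> np.ndarray:
    """Per-atom root-mean-square fluctuation (nm) about the mean position of
    the fitted trajectory.

    Every frame is first superposed onto frame 0 using *fit_sel*; the
    fluctuation of each *calc_sel* atom is then measured about its own mean
    over the fitted frames.
    """
    if len(traj) < 2:
        raise ValueError("RMSF needs at least 2 frames")
    if not len(calc_sel):
        raise ValueError("empty calc selection")
    fitted = _fit_frames(traj, model, fit_sel)
    cidx = model.indices_of(calc_sel)
    sub = fitted[:, cidx]
    mean = sub.mean(axis=0)
    return np.sqrt(np.mean(np.sum((sub - mean)**2, axis=2), axis=0))


def radius_of_gyration(model: StructureModel, frame: Frame,
                       sel: Sequence[int], mass_weighted: bool = True) -> float:
    """Radius of gyration (nm) of a selection in one frame.

    Mass-weighted by default (the convention of common MD analysis suites);
    with ``mass_weighted=False`` all atoms count equally.
    """
    if not len(sel):
        raise ValueError("empty selection")
    idx = model.indices_of(sel)
    coords = frame.coordinates[idx]
    w = model.masses(sel) if mass_weighted else np.ones(len(idx))
    w = w / w.sum()
    center = w @ coords
    return float(np.sqrt(np.sum(w * np.sum((coords - center)**2, axis=1))))
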