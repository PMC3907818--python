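"""Synthetic multi-domain trajectories with fully known ground truth.

The generator emulates, kinematically, the system the analyses are built
for: a two-chain construct (chains A and B) with two rigid ellipsoidal
domains per chain (CH2 and CH3 bead clouds plus loop beads in the
engineered-loop residue ranges), a glycan-like branch per chain driven
through prescribed dihedral-angle paths, donor-H-acceptor triplets toggled
between bonded and unbonded geometry on deterministic schedules, and a
rectangular periodic box.  The CH3A-CH3B domain pair is driven through a
prescribed inter-axis angle and twist schedule by closed-form axis
construction, so every analysis result has an exact expected value.

Atoms that carry planned features (hydrogen-bond triplets, dihedral
quadruples) are exempt from thermal noise; Gaussian noise of width
``noise_sigma`` is added to all domain beads.  Everything is a pure
function of the spec and its seed.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .config import AnalysisConfig
from .io import write_structure, write_torsion_table, write_trajectory
from .model import (
    AtomRecord,
    Frame,
    SegmentClass,
    StructureModel,
    TorsionTerm,
    Trajectory,
)

__all__ = [
    "HBondPlanEntry",
    "DihedralPlanEntry",
    "SyntheticSpec",
    "GroundTruth",
    "build_toy_fc",
    "generate_trajectory",
    "write_toy_dataset",
]

# local bead template for one rigid ellipsoidal domain; long axis = local x.
# Symmetric about the origin with three distinct covariance eigenvalues, so
# the leading principal axis is exactly the local x direction.
_CORE_BEADS = np.array([
    [1.0, 0.0, 0.0], [-1.0, 0.0, 0.0],
    [0.75, 0.0, 0.0], [-0.75, 0.0, 0.0],
    [0.5, 0.0, 0.0], [-0.5, 0.0, 0.0],
    [0.25, 0.0, 0.0], [-0.25, 0.0, 0.0],
    [0.0, 0.35, 0.0], [0.0, -0.35, 0.0],
    [0.0, 0.0, 0.18], [0.0, 0.0, -0.18],
    [0.0, 0.0, 0.0],
])

#: loop label -> (residue number, local position) for CH3 loop beads
_LOOP_BEADS = {
    "AB": (360, np.array([0.9, 0.3, 0.0])),
    "CD": (387, np.array([0.0, -0.45, 0.1])),
    "EF": (417, np.array([-0.9, 0.3, 0.0])),
}

_CH2_CORE_RESIDUES = list(range(240, 253))
_CH3_CORE_RESIDUES = list(range(341, 354))


@dataclass(frozen=True)
class HBondPlanEntry:
    """One planned cross-chain hydrogen bond with a target prevalence (%).

    The donor (N) and its hydrogen live on chain A, the acceptor (O) on
    chain B.  The on/off schedule is a deterministic Bresenham spread of
    round(prevalence/100 * n_frames) bonded frames.
    """

    target_prevalence: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.target_prevalence <= 100.0):
            raise ValueError("target prevalence must lie in [0, 100]")


@dataclass(frozen=True)
class DihedralPlanEntry:
    """One glycan-linkage dihedral driven through a known angle path.

    ``path`` is the unwrapped angle (degrees) per frame; consecutive steps
    must stay below 180 deg so the shortest-arc reading is unambiguous.
    ``None`` selects a default path built for the spec's frame count.
    """

    chain: str
    multiplicity: int
    phase: float = 0.0
    force_constant: float = 5.92
    path: Optional[tuple[float, ...]] = None


@dataclass
class SyntheticSpec:
    """Generator parameters; the defaults define the standard toy system."""

    n_frames: int = 200
    frame_spacing: float = 2.0  # ps
    box: tuple[float, float, float] = (12.0, 12.0, 12.0)  # nm
    noise_sigma: float = 0.0  # nm, per coordinate, domain beads only
    angle_sweep: tuple[float, float] = (30.0, 60.0)  # deg, CH3A-CH3B axis angle
    twist_sweep: tuple[float, float] = (0.0, 90.0)  # deg, CH3A-CH3B torsion
    ch3_separation: float = 2.5  # nm between CH3 centers
    ch2_offset: float = 2.5  # nm from CH3 to CH2 center, along +y
    domain_scale: float = 1.0  # scales the bead template
    hbond_plan: tuple[HBondPlanEntry, ...] = (
        HBondPlanEntry(47.0), HBondPlanEntry(80.0), HBondPlanEntry(100.0),
    )
    dihedral_plan: Optional[tuple[DihedralPlanEntry, ...]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if self.dihedral_plan is None:
            self.dihedral_plan = (
                DihedralPlanEntry(chain="A", multiplicity=3),
                DihedralPlanEntry(chain="B", multiplicity=2),
            )

    def resolved_dihedral_paths(self) -> list[np.ndarray]:
        """Unwrapped per-frame angle paths, filling in plan defaults."""
        paths = []
        for k, entry in enumerate(self.dihedral_plan):
            if entry.path is not None:
                p = np.asarray(entry.path, dtype=float)
            elif k % 2 == 0:
                # monotone sweep; samples stay >= 1.2 deg from any multiple
                # of 120, so crossings are robust to format round-off
                p = -150.0 + 2.4 * np.arange(self.n_frames)
            else:
                # triangle wave oscillating across 180 deg; odd-valued
                # samples never land on the maxima at 0/180
                t = np.arange(self.n_frames)
                period = 20
                tri = np.abs((t % period) - period / 2) / (period / 2)
                p = 191.0 - 20.0 * tri
            if np.any(np.abs(np.diff(p)) >= 180.0):
                raise ValueError(
                    f"dihedral plan {k}: angle path step of >= 180 deg"
                )
            paths.append(p)
        return paths


@dataclass
class GroundTruth:
    """Exact expected values for every analysis of a generated trajectory."""

    centers: dict[str, np.ndarray]          # label -> (n_frames, 3) nm
    axes: dict[str, np.ndarray]             # label -> (n_frames, 3) unit
    descriptors: dict[str, np.ndarray]      # 'A'..'H' -> (n_frames,) deg
    hbond_triplets: list[tuple[int, int, int]]
    hbond_prevalence: list[float]           # realized %, exact
    hbond_schedules: list[np.ndarray]       # bool per frame
    dihedral_quadruples: list[tuple[int, int, int, int]]
    dihedral_angles: list[np.ndarray]       # wrapped (-180, 180] per frame
    transition_counts: list[int]
    periodic_contact: bool
    min_image_distance: float               # frame 0, noise-free positions
    contact_regime: str                     # "contact" | "separated"
    seed: int

    def to_json(self) -> str:
        data = {
            "descriptors": {k: v.tolist() for k, v in self.descriptors.items()},
            "hbond_triplets": [list(t) for t in self.hbond_triplets],
            "hbond_prevalence": self.hbond_prevalence,
            "dihedral_quadruples": [list(q) for q in self.dihedral_quadruples],
            "transition_counts": self.transition_counts,
            "periodic_contact": self.periodic_contact,
            "min_image_distance": self.min_image_distance,
            "contact_regime": self.contact_regime,
            "seed": self.seed,
        }
        return json.dumps(data, indent=1)


# -- closed-form axis construction ----------------------------------------


def _pair_axes(angle_deg: float, twist_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """Two unit axes realizing a given inter-axis angle and torsion about +x.

    Axis i is (cos psi_i, sin psi_i cos phi_i, sin psi_i sin phi_i); the
    torsion about the center line from axis-1's side to axis-2's side equals
    phi1 - phi2 and the inter-axis angle follows from the dot product.  The
    polar angles are chosen symmetrically about 90 deg, which covers any
    combination of angle and twist.
    """
    D = np.radians(angle_deg)
    T = np.radians(twist_deg)
    phi1, phi2 = T / 2.0, -T / 2.0
    cosD, cosT = np.cos(D), np.cos(T)
    if cosD <= cosT:  # wide angle: tilt the polar angles apart
        s2 = (cosT - cosD) / (1.0 + cosT) if (1.0 + cosT) > 1e-12 else 0.0
        e = np.arcsin(np.sqrt(np.clip(s2, 0.0, 1.0)))
        psi1, psi2 = np.pi / 2 - e, np.pi / 2 + e
    else:  # narrow angle: tilt both toward +x
        s2 = (1.0 - cosD) / (1.0 - cosT) if (1.0 - cosT) > 1e-12 else 0.0
        psi1 = psi2 = np.arcsin(np.sqrt(np.clip(s2, 0.0, 1.0)))
    def vec(psi, phi):
        return np.array([np.cos(psi),
                         np.sin(psi) * np.cos(phi),
                         np.sin(psi) * np.sin(phi)])
    return vec(psi1, phi1), vec(psi2, phi2)


def _angle_between(u: np.ndarray, v: np.ndarray) -> float:
    return float(np.degrees(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0))))


def _twist_about(u: np.ndarray, a1: np.ndarray, a2: np.ndarray) -> float:
    """Signed torsion (deg) of a1 relative to a2 about the unit line u,
    matching the four-point pseudo-dihedral convention."""
    p1 = a1 - (a1 @ u) * u
    p2 = a2 - (a2 @ u) * u
    y = float(u @ np.cross(p2, p1))
    x = float(p1 @ p2)
    ang = np.degrees(np.arctan2(y, x))
    return float(ang if ang > -180.0 else 180.0)


def _rotation_to(axis: np.ndarray) -> np.ndarray:
    """A rotation matrix whose first column is *axis* (deterministic roll)."""
    a = axis / np.linalg.norm(axis)
    helper = np.array([0.0, 0.0, 1.0])
    if abs(a @ helper) > 0.99:
        helper = np.array([0.0, 1.0, 0.0])
    b = np.cross(helper, a)
    b = b / np.linalg.norm(b)
    c = np.cross(a, b)
    return np.column_stack([a, b, c])


# -- structure construction ------------------------------------------------


class _ToyLayout:
    """Atom bookkeeping shared by build_toy_fc and generate_trajectory."""

    def __init__(self, spec: SyntheticSpec):
        self.spec = spec
        self.records: list[AtomRecord] = []
        self.bonds: list[tuple[int, int]] = []
        self.torsions: list[TorsionTerm] = []
        self.domain_atoms: dict[str, list[int]] = {}
        self.loop_atoms: dict[str, int] = {}
        self.hbond_triplets: list[tuple[int, int, int]] = []
        self.hbond_bases: list[np.ndarray] = []
        self.dihedral_quadruples: list[tuple[int, int, int, int]] = []
        self.dihedral_bases: list[np.ndarray] = []
        self._build()

    def _add(self, name, element, resnum, resname, chain,
             seg=SegmentClass.PROTEIN, gidx=None) -> int:
        atom_id = len(self.records) + 1
        self.records.append(AtomRecord(
            atom_id=atom_id, atom_name=name, element=element,
            residue_number=resnum, residue_name=resname, chain_id=chain,
            segment_class=seg, glycan_index=gidx,
        ))
        return atom_id

    def _build(self) -> None:
        spec = self.spec
        half = spec.ch3_separation / 2.0
        self.centers = {
            "CH3A": np.array([-half, 0.0, 0.0]),
            "CH3B": np.array([half, 0.0, 0.0]),
            "CH2A": np.array([-half, spec.ch2_offset, 0.0]),
            "CH2B": np.array([half, spec.ch2_offset, 0.0]),
        }
        for chain in ("A", "B"):
            for domain, residues in (("CH2", _CH2_CORE_RESIDUES),
                                     ("CH3", _CH3_CORE_RESIDUES)):
                label = f"{domain}{chain}"
                ids = [
                    self._add("CA", "C", res, "ALA", chain)
                    for res in residues
                ]
                self.domain_atoms[label] = ids
            for loop, (res, _pos) in _LOOP_BEADS.items():
                self.loop_atoms[f"loop{loop}{chain}"] = self._add(
                    "CA", "C", res, "GLY", chain)

        # planned hydrogen bonds: donor-H on chain A, acceptor on chain B,
        # each bond in its own geometrically isolated pocket
        for j, _entry in enumerate(spec.hbond_plan):
            base = np.array([-1.0 + 1.0 * j, -3.0, 0.0])
            d = self._add("N", "N", 450 + j, "ASN", "A")
            h = self._add("H", "H", 450 + j, "ASN", "A")
            a = self._add("O", "O", 450 + j, "SER", "B")
            self.bonds.append((d, h))
            self.hbond_triplets.append((d, h, a))
            self.hbond_bases.append(base)

        # glycan-like branches carrying the planned dihedral quadruples;
        # glycan residues are numbered per chain in attachment order
        glycan_counter: dict[str, int] = {}
        for k, entry in enumerate(spec.dihedral_plan):
            chain = entry.chain
            sign = -1.0 if chain == "A" else 1.0
            base = np.array([sign * half, spec.ch2_offset + 1.7 + 0.8 * k, 0.0])
            res0 = 601 + 2 * k
            g1 = glycan_counter.get(chain, 0) + 1
            g2 = g1 + 1
            glycan_counter[chain] = g2
            a1 = self._add("O5", "O", res0, "NAG", chain,
                           SegmentClass.GLYCAN, g1)
            a2 = self._add("C1", "C", res0, "NAG", chain,
                           SegmentClass.GLYCAN, g1)
            a3 = self._add("C4", "C", res0 + 1, "MAN", chain,
                           SegmentClass.GLYCAN, g2)
            a4 = self._add("O4", "O", res0 + 1, "MAN", chain,
                           SegmentClass.GLYCAN, g2)
            self.bonds += [(a1, a2), (a2, a3), (a3, a4)]
            quad = (a1, a2, a3, a4)
            self.torsions.append(TorsionTerm(
                atom_ids=quad, force_constant_K=entry.force_constant,
                multiplicity_m=entry.multiplicity, phase_delta=entry.phase,
            ))
            self.dihedral_quadruples.append(quad)
            self.dihedral_bases.append(base)

    def model(self) -> StructureModel:
        return StructureModel(self.records, self.bonds, self.torsions)


def build_toy_fc(spec: SyntheticSpec) -> StructureModel:
    """Build the toy two-chain, four-domain structure for a spec.

    Chains A and B each carry a CH2 and a CH3 bead domain plus three loop
    beads in the AB/CD/EF loop residue ranges; the hydrogen-bond plan adds
    explicit donor/H/acceptor sites and the dihedral plan adds glycan-like
    branches with their torsion terms.
    """
    return _ToyLayout(spec).model()


# -- trajectory generation -------------------------------------------------


def _schedule(entry: HBondPlanEntry, n: int) -> np.ndarray:
    """Deterministic on/off frames: k = round(p/100 * n) frames spread evenly."""
    k = int(round(entry.target_prevalence / 100.0 * n))
    f = np.arange(n)
    return np.floor((f + 1) * k / n) > np.floor(f * k / n)


def _dihedral_points(base: np.ndarray, angle_deg: float) -> np.ndarray:
    """Four points whose dihedral angle is exactly *angle_deg* (IUPAC sign)."""
    r = 0.15
    phi = np.radians(angle_deg)
    return np.array([
        base + [r, 0.0, 0.0],
        base,
        base + [0.0, 0.0, r],
        base + [r * np.cos(phi), -r * np.sin(phi), r],
    ])


def _hbond_points(base: np.ndarray, on: bool) -> np.ndarray:
    """Donor, hydrogen and acceptor positions for one planned bond.

    Bonded frames place the acceptor at 0.20 nm from H with a 170 deg
    D-H-A angle; unbonded frames at 0.40 nm, same angle.
    """
    dist = 0.20 if on else 0.40
    d = base
    h = base + np.array([0.10, 0.0, 0.0])
    ang = np.radians(180.0 - 170.0)
    a = h + dist * np.array([np.cos(ang), np.sin(ang), 0.0])
    return np.array([d, h, a])


def _min_image_distance(coords: np.ndarray, box: np.ndarray) -> float:
    """Brute-force nearest nonzero-image distance (generator-side oracle)."""
    best = np.inf
    for i in (-1, 0, 1):
        for j in (-1, 0, 1):
            for k in (-1, 0, 1):
                if (i, j, k) == (0, 0, 0):
                    continue
                shift = np.array([i, j, k]) * box
                diff = coords[:, None, :] - (coords[None, :, :] + shift)
                d = np.sqrt((diff ** 2).sum(axis=2)).min()
                best = min(best, float(d))
    return best


def _count_path_crossings(path: np.ndarray, maxima_deg: Sequence[float]) -> int:
    """Strict level crossings of an unwrapped piecewise-linear angle path."""
    count = 0
    for a, b in zip(path[:-1], path[1:]):
        lo, hi = (a, b) if a <= b else (b, a)
        for mu in maxima_deg:
            k_lo = int(np.ceil((lo - mu) / 360.0))
            k_hi = int(np.floor((hi - mu) / 360.0))
            for k in range(k_lo, k_hi + 1):
                level = mu + 360.0 * k
                if lo < level < hi:
                    count += 1
    return count


def generate_trajectory(model: StructureModel, spec: SyntheticSpec,
                        ) -> tuple[Trajectory, GroundTruth]:
    """Generate the rigid-body trajectory and its exact ground truth.

    The CH3A/CH3B axes follow the spec's angle and twist sweeps by
    closed-form construction; CH2 axes are constant.  Planned hydrogen-bond
    and dihedral atoms are placed exactly (never perturbed); Gaussian noise
    of width ``noise_sigma`` is added to all domain and loop beads.
    Bitwise reproducible from the seed.
    """
    layout = _ToyLayout(spec)
    if [a.atom_id for a in layout.records] != [a.atom_id for a in model.atoms]:
        raise ValueError("model was not built from this spec")
    n = spec.n_frames
    rng = np.random.default_rng(spec.seed)
    scale = spec.domain_scale

    angle_series = np.linspace(*spec.angle_sweep, n)
    twist_series = np.linspace(*spec.twist_sweep, n)

    # constant CH2 axes (largest component positive, matching the sign rule
    # the analysis uses on its first frame)
    axis_ch2a = np.array([0.3, 0.2, 0.93])
    axis_ch2a /= np.linalg.norm(axis_ch2a)
    axis_ch2b = np.array([-0.3, 0.2, 0.93])
    axis_ch2b /= np.linalg.norm(axis_ch2b)

    centers = layout.centers
    axes: dict[str, np.ndarray] = {
        label: np.empty((n, 3)) for label in centers
    }
    schedules = [_schedule(e, n) for e in spec.hbond_plan]
    paths = spec.resolved_dihedral_paths()
    for p in paths:
        if len(p) != n:
            raise ValueError("dihedral path length must equal n_frames")

    n_atoms = len(model)
    frames = []
    box = np.asarray(spec.box, dtype=float)
    for t in range(n):
        coords = np.zeros((n_atoms, 3))
        a3a, a3b = _pair_axes(angle_series[t], twist_series[t])
        frame_axes = {"CH3A": a3a, "CH3B": a3b,
                      "CH2A": axis_ch2a, "CH2B": axis_ch2b}
        for label, axis in frame_axes.items():
            axes[label][t] = axis
            rot = _rotation_to(axis)
            ids = layout.domain_atoms[label]
            local = _CORE_BEADS * scale
            pos = centers[label] + local @ rot.T
            for i, p_ in zip(ids, pos):
                coords[model.index_of(i)] = p_
            if label.startswith("CH3"):
                for loop, (res, lpos) in _LOOP_BEADS.items():
                    lid = layout.loop_atoms[f"loop{loop}{label[-1]}"]
                    coords[model.index_of(lid)] = (
                        centers[label] + rot @ (lpos * scale)
                    )
        for j, (d, h, a) in enumerate(layout.hbond_triplets):
            pts = _hbond_points(layout.hbond_bases[j], bool(schedules[j][t]))
            for i, p_ in zip((d, h, a), pts):
                coords[model.index_of(i)] = p_
        for k, quad in enumerate(layout.dihedral_quadruples):
            wrapped = paths[k][t]
            pts = _dihedral_points(layout.dihedral_bases[k], wrapped)
            for i, p_ in zip(quad, pts):
                coords[model.index_of(i)] = p_
        if spec.noise_sigma > 0:
            noisy_ids = [
                i for ids in layout.domain_atoms.values() for i in ids
            ] + list(layout.loop_atoms.values())
            idx = model.indices_of(noisy_ids)
            coords[idx] += rng.normal(0.0, spec.noise_sigma, (len(idx), 3))
        frames.append(Frame(coords, time=t * spec.frame_spacing, box=box.copy()))

    traj = Trajectory(frames, frame_spacing=spec.frame_spacing)

    # descriptors from the constructed axes/centers, by closed form
    pair_map = {
        "A": ("CH2A", "CH3A"), "B": ("CH2B", "CH3B"),
        "C": ("CH2A", "CH2B"), "D": ("CH3A", "CH3B"),
        "E": ("CH2A", "CH3A"), "F": ("CH2B", "CH3B"),
        "G": ("CH2A", "CH2B"), "H": ("CH3A", "CH3B"),
    }
    descriptors = {}
    for label, (d1, d2) in pair_map.items():
        vals = np.empty(n)
        sep = centers[d2] - centers[d1]
        u = sep / np.linalg.norm(sep)
        for t in range(n):
            if label in "ABCD":
                vals[t] = _angle_between(axes[d1][t], axes[d2][t])
            else:
                vals[t] = _twist_about(u, axes[d1][t], axes[d2][t])
        descriptors[label] = vals

    prevalences = [100.0 * int(s.sum()) / n for s in schedules]

    from .dihedrals import torsion_maxima, wrap_angle  # local import: no cycle
    counts = []
    wrapped_paths = []
    for term, path in zip(layout.torsions, paths):
        counts.append(_count_path_crossings(path, torsion_maxima(term)))
        wrapped_paths.append(np.asarray(wrap_angle(path)))

    # noise-free frame-0 positions for the periodicity / contact regimes
    coords0 = traj[0].coordinates if spec.noise_sigma == 0 else None
    if coords0 is None:
        quiet = SyntheticSpec(**{**spec.__dict__, "noise_sigma": 0.0})
        quiet_model = build_toy_fc(quiet)
        coords0 = generate_trajectory(quiet_model, quiet)[0][0].coordinates
    min_img = _min_image_distance(coords0, box)
    ch3a = coords0[model.indices_of(layout.domain_atoms["CH3A"])]
    ch3b = coords0[model.indices_of(layout.domain_atoms["CH3B"])]
    gap = np.sqrt(
        ((ch3a[:, None, :] - ch3b[None, :, :]) ** 2).sum(axis=2)
    ).min()
    contact_threshold = 2.0 * (0.17 + 0.14)  # carbon vdW + probe, both sides
    regime = "contact" if gap < contact_threshold else "separated"

    truth = GroundTruth(
        centers={k: np.tile(v, (n, 1)) for k, v in centers.items()},
        axes=axes,
        descriptors=descriptors,
        hbond_triplets=list(layout.hbond_triplets),
        hbond_prevalence=prevalences,
        hbond_schedules=schedules,
        dihedral_quadruples=list(layout.dihedral_quadruples),
        dihedral_angles=wrapped_paths,
        transition_counts=counts,
        periodic_contact=bool(min_img < 1.4),
        min_image_distance=min_img,
        contact_regime=regime,
        seed=spec.seed,
    )
    return traj, truth


def write_toy_dataset(out_dir, spec: Optional[SyntheticSpec] = None,
                      config: Optional[AnalysisConfig] = None) -> dict:
    """Write a complete analysis input set generated from a spec.

    Produces structure.pdb, trajectory.pdb (multi-model), torsions.tsv,
    config.yaml and ground_truth.json in *out_dir*, so the full pipeline can
    run on generator output alone.  Returns the paths.
    """
    spec = spec or SyntheticSpec()
    config = config or AnalysisConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = build_toy_fc(spec)
    traj, truth = generate_trajectory(model, spec)
    paths = {
        "structure": out / "structure.pdb",
        "trajectory": out / "trajectory.pdb",
        "torsions": out / "torsions.tsv",
        "config": out / "config.yaml",
        "ground_truth": out / "ground_truth.json",
    }
    write_structure(paths["structure"], model, traj[0])
    write_trajectory(paths["trajectory"], model, traj)
    write_torsion_table(paths["torsions"], model.torsion_terms)
    config.save(paths["config"])
    paths["ground_truth"].write_text(truth.to_json())
    return {k: str(v) for k, v in paths.items()}
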