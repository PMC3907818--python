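"""Shrake-Rupley SASA, interface decomposition and group accounting."""
import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from fctraj import SelectionSpec, group_area, interface_area, sasa
from fctraj.model import Frame
from conftest import make_model

R_C = 0.17  # Bondi carbon radius used by the default table
PROBE = 0.14


def latlon_sasa(coords, radii, probe, n_theta=400, n_phi=800):
    """High-resolution latitude-longitude quadrature oracle.

    Integrates the exposed fraction of each probe-inflated sphere on a
    dense angular grid with sin(theta) area weights — a different lattice
    and bookkeeping than the golden-spiral implementation.
    """
    coords = np.asarray(coords, dtype=float)
    inflated = np.asarray(radii, dtype=float) + probe
    theta = (np.arange(n_theta) + 0.5) * np.pi / n_theta
    phi = (np.arange(n_phi) + 0.5) * 2 * np.pi / n_phi
    tt, pp = np.meshgrid(theta, phi, indexing="ij")
    dirs = np.stack([np.sin(tt) * np.cos(pp), np.sin(tt) * np.sin(pp),
                     np.cos(tt)], axis=-1).reshape(-1, 3)
    weights = np.repeat(np.sin(theta), n_phi)
    weights = weights / weights.sum()
    total = 0.0
    for i in range(len(coords)):
        pts = coords[i] + inflated[i] * dirs
        exposed = np.ones(len(pts), dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            d = np.linalg.norm(pts - coords[j], axis=1)
            exposed &= d >= inflated[j]
        total += float((weights * exposed).sum()) * 4 * np.pi * inflated[i] ** 2
    return total


class TestSasa:
    def test_isolated_sphere_closed_form(self):
        model, frame = make_model([[0.0, 0, 0]], elements=["S"])
        res = sasa(frame, model, [1], radii={"S": 0.15}, probe=PROBE,
                   n_points=960)
        expected = 4 * np.pi * 0.29 ** 2
        assert res.total == pytest.approx(expected, rel=0.005)
        assert res.per_atom_area[1] == res.total

    def test_coincident_atoms_count_once(self):
        model, frame = make_model([[0.0, 0, 0], [0.0, 0, 0]])
        res = sasa(frame, model, [1, 2])
        one = 4 * np.pi * (R_C + PROBE) ** 2
        assert res.total == pytest.approx(one, rel=1e-9)

    def test_two_spheres_match_quadrature_oracle(self):
        coords = [[0.0, 0, 0], [0.3, 0, 0]]
        model, frame = make_model(coords)
        res = sasa(frame, model, [1, 2], n_points=960)
        oracle = latlon_sasa(coords, [R_C, R_C], PROBE)
        assert res.total == pytest.approx(oracle, rel=0.02)

    def test_rigid_transform_invariance(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 0.6, size=(8, 3))
        model, frame = make_model(coords)
        sel = list(range(1, 9))
        base = sasa(frame, model, sel).total
        R = Rotation.random(random_state=2).as_matrix()
        model2, frame2 = make_model(coords @ R.T + [5.0, 1.0, -2.0])
        # the point lattice rotates with nothing: areas agree only to the
        # lattice resolution
        moved = sasa(frame2, model2, sel).total
        assert moved == pytest.approx(base, rel=0.01)

    def test_adding_occluders_never_increases_total(self):
        rng = np.random.default_rng(1)
        coords = rng.uniform(0, 0.8, size=(10, 3))
        model, frame = make_model(coords)
        base_sel = list(range(1, 6))
        base = sasa(frame, model, base_sel)
        grown = sasa(frame, model, list(range(1, 11)))
        for i in base_sel:
            assert grown.per_atom_area[i] <= base.per_atom_area[i] + 1e-12

    def test_point_density_convergence(self):
        rng = np.random.default_rng(2)
        coords = rng.uniform(0, 0.5, size=(6, 3))
        model, frame = make_model(coords)
        sel = list(range(1, 7))
        a = sasa(frame, model, sel, n_points=960).total
        b = sasa(frame, model, sel, n_points=1920).total
        assert abs(a - b) / b < 0.01

    def test_missing_radius_names_element(self):
        model, frame = make_model([[0, 0, 0]], elements=["XX"])
        with pytest.raises(KeyError, match="XX"):
            sasa(frame, model, [1])

    def test_total_equals_per_atom_sum(self, default_dataset):
        model, traj, _ = default_dataset
        protein = [a.atom_id for a in model.atoms
                   if a.segment_class.value == "protein"]
        res = sasa(traj[0], model, protein)
        assert res.total == pytest.approx(sum(res.per_atom_area.values()),
                                          abs=1e-9)


class TestInterfaceArea:
    def test_fully_separated_dimer_buries_nothing(self):
        coords = np.array([[0.0, 0, 0], [0.4, 0, 0],
                           [5.0, 0, 0], [5.4, 0, 0]])
        model, frame = make_model(coords)
        res = interface_area(frame, model, [1, 2], [3, 4])
        assert res["buried_A"] == 0.0
        assert res["buried_B"] == 0.0

    def test_symmetric_dimer_buries_equally(self):
        # monomer B is the point reflection of monomer A through the dimer
        # center, so an exact symmetry operation swaps the two
        blob = np.array([[0.0, 0, 0], [0.3, 0, 0], [0.15, 0.25, 0]])
        shift = np.array([0.0, -0.5, 0.0])
        coords = np.vstack([blob, shift - blob])
        model, frame = make_model(coords)
        res = interface_area(frame, model, [1, 2, 3], [4, 5, 6],
                             n_points=1920)
        assert res["buried_A"] > 0.05
        assert res["buried_A"] == pytest.approx(res["buried_B"], rel=0.05)

    def test_two_blob_dimer_matches_oracle(self):
        rng = np.random.default_rng(3)
        blobA = rng.uniform(0, 0.5, size=(5, 3))
        blobB = rng.uniform(0, 0.5, size=(5, 3)) + [0.55, 0, 0]
        coords = np.vstack([blobA, blobB])
        model, frame = make_model(coords)
        res = interface_area(frame, model, list(range(1, 6)),
                             list(range(6, 11)), n_points=960)
        radii = [R_C] * 5
        # oracle buried(A) = quadrature SASA of A alone minus the quadrature
        # contribution of A's atoms inside the A+B complex
        alone = latlon_sasa(blobA, radii, PROBE)
        contrib = _latlon_contribution(coords, radii * 2, PROBE,
                                       atoms=range(5))
        assert res["buried_A"] == pytest.approx(alone - contrib, rel=0.05)

    def test_overlapping_selections_rejected(self):
        model, frame = make_model(np.zeros((3, 3)))
        with pytest.raises(ValueError, match="overlap"):
            interface_area(frame, model, [1, 2], [2, 3])


def _latlon_contribution(coords, radii, probe, atoms, n_theta=400, n_phi=800):
    """Quadrature SASA contribution of a subset of atoms within the full set."""
    coords = np.asarray(coords, dtype=float)
    inflated = np.asarray(radii, dtype=float) + probe
    theta = (np.arange(n_theta) + 0.5) * np.pi / n_theta
    phi = (np.arange(n_phi) + 0.5) * 2 * np.pi / n_phi
    tt, pp = np.meshgrid(theta, phi, indexing="ij")
    dirs = np.stack([np.sin(tt) * np.cos(pp), np.sin(tt) * np.sin(pp),
                     np.cos(tt)], axis=-1).reshape(-1, 3)
    weights = np.repeat(np.sin(theta), n_phi)
    weights = weights / weights.sum()
    total = 0.0
    for i in atoms:
        pts = coords[i] + inflated[i] * dirs
        exposed = np.ones(len(pts), dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            d = np.linalg.norm(pts - coords[j], axis=1)
            exposed &= d >= inflated[j]
        total += float((weights * exposed).sum()) * 4 * np.pi * inflated[i] ** 2
    return total


class TestGroupArea:
    def test_full_group_equals_total(self, default_dataset):
        model, traj, _ = default_dataset
        protein_ids = [a.atom_id for a in model.atoms
                       if a.segment_class.value == "protein"]
        res = sasa(traj[0], model, protein_ids)
        everything = SelectionSpec.make(segment_classes={"protein"})
        assert group_area(res, model, everything) == pytest.approx(
            res.total, abs=1e-9)

    def test_partition_sums_to_total(self, default_dataset):
        model, traj, _ = default_dataset
        protein_ids = [a.atom_id for a in model.atoms
                       if a.segment_class.value == "protein"]
        res = sasa(traj[0], model, protein_ids)
        parts = [SelectionSpec.make(chain_ids={"A"},
                                    segment_classes={"protein"}),
                 SelectionSpec.make(chain_ids={"B"},
                                    segment_classes={"protein"})]
        total = sum(group_area(res, model, p) for p in parts)
        assert total == pytest.approx(res.total, abs=1e-9)

    def test_loop_group_matches_hand_summation(self, default_dataset):
        model, traj, _ = default_dataset
        protein_ids = [a.atom_id for a in model.atoms
                       if a.segment_class.value == "protein"]
        res = sasa(traj[0], model, protein_ids)
        loops = SelectionSpec.make(chain_ids={"A"},
                                   residue_ranges=[(358, 362), (383, 391),
                                                   (413, 422)],
                                   segment_classes={"protein"})
        by_hand = sum(
            res.per_atom_area[a.atom_id] for a in model.atoms
            if a.chain_id == "A" and a.segment_class.value == "protein"
            and (358 <= a.residue_number <= 362
                 or 383 <= a.residue_number <= 391
                 or 413 <= a.residue_number <= 422))
        assert group_area(res, model, loops) == pytest.approx(by_hand,
                                                              abs=1e-12)
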