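"""Orientation descriptors, periodicity check and ring geometry."""
import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from fctraj import (
    Frame,
    center_of_geometry,
    interdomain_angle,
    interdomain_dihedral,
    periodic_contact,
    principal_axis,
    ring_geometry,
)
from conftest import make_model


def hexagon(radius=0.15):
    ang = np.radians(np.arange(6) * 60.0)
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang),
                            np.zeros(6)])


class TestCenterOfGeometry:
    def test_two_atoms(self):
        model, frame = make_model([[0, 0, 0], [2.0, 0, 0]])
        np.testing.assert_allclose(
            center_of_geometry(frame, model, [1, 2]), [1.0, 0, 0])

    def test_single_atom(self):
        model, frame = make_model([[1.0, -2.0, 3.0]])
        np.testing.assert_allclose(
            center_of_geometry(frame, model, [1]), [1.0, -2.0, 3.0])

    def test_cube_center(self):
        corners = [[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)]
        model, frame = make_model(corners)
        np.testing.assert_allclose(
            center_of_geometry(frame, model, list(range(1, 9))),
            [0.5, 0.5, 0.5])

    def test_empty_selection_rejected(self):
        model, frame = make_model([[0, 0, 0]])
        with pytest.raises(ValueError):
            center_of_geometry(frame, model, [])


class TestPrincipalAxis:
    def test_dominant_direction_with_jitter(self):
        rng = np.random.default_rng(0)
        coords = np.zeros((30, 3))
        coords[:, 0] = np.linspace(-1, 1, 30)
        coords[:, 1:] = rng.normal(scale=0.02, size=(30, 2))
        model, frame = make_model(coords)
        axis = principal_axis(frame, model, list(range(1, 31)))
        assert axis[0] > 0  # sign rule: largest component positive
        assert abs(axis @ [1.0, 0, 0]) > 0.999

    def test_prolate_cloud_recovers_long_axis(self):
        rng = np.random.default_rng(1)
        u = np.array([2.0, 1.0, -1.0])
        u /= np.linalg.norm(u)
        R = Rotation.align_vectors([u], [[1.0, 0, 0]])[0].as_matrix()
        local = rng.normal(size=(400, 3)) * [1.0, 0.2, 0.1]
        model, frame = make_model(local @ R.T)
        axis = principal_axis(frame, model, list(range(1, 401)))
        assert abs(axis @ u) >= 0.999

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(2)
        coords = rng.normal(size=(50, 3)) * [1.0, 0.4, 0.1]
        model, frame = make_model(coords)
        sel = list(range(1, 51))
        axis = principal_axis(frame, model, sel)
        R = Rotation.random(random_state=5).as_matrix()
        model2, frame2 = make_model(coords @ R.T)
        axis2 = principal_axis(frame2, model2, sel)
        assert min(np.linalg.norm(axis2 - R @ axis),
                   np.linalg.norm(axis2 + R @ axis)) < 1e-9

    def test_sign_continuity_with_previous_axis(self):
        coords = np.zeros((10, 3))
        coords[:, 0] = np.linspace(-1, 1, 10)
        coords[:, 1] = np.linspace(-0.1, 0.1, 10) ** 2
        model, frame = make_model(coords)
        sel = list(range(1, 11))
        axis = principal_axis(frame, model, sel,
                              prev_axis=np.array([-1.0, 0, 0]))
        assert axis[0] < 0

    def test_degenerate_eigenvalues_rejected(self):
        # perfect square in the xy-plane: two equal leading eigenvalues
        coords = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0.0]])
        model, frame = make_model(coords)
        with pytest.raises(ValueError, match="eigengap"):
            principal_axis(frame, model, [1, 2, 3, 4])


class TestInterdomainAngle:
    def test_identical_vectors(self):
        assert interdomain_angle(np.array([0, 0, 1.0]),
                                 np.array([0, 0, 1.0])) == 0.0

    def test_orthogonal_vectors(self):
        assert interdomain_angle(np.array([1.0, 0, 0]),
                                 np.array([0, 1.0, 0])) == pytest.approx(90.0)

    def test_symmetry_and_rotation_invariance(self):
        rng = np.random.default_rng(3)
        for seed in range(10):
            u, v = rng.normal(size=(2, 3))
            u, v = u / np.linalg.norm(u), v / np.linalg.norm(v)
            assert interdomain_angle(u, v) == pytest.approx(
                interdomain_angle(v, u))
            R = Rotation.random(random_state=seed).as_matrix()
            assert interdomain_angle(R @ u, R @ v) == pytest.approx(
                interdomain_angle(u, v), abs=1e-9)


class TestInterdomainDihedral:
    C1, C2 = np.zeros(3), np.array([2.0, 0, 0])

    def test_eclipsed_axes(self):
        z = np.array([0, 0, 1.0])
        assert interdomain_dihedral(z, self.C1, self.C2, z) == pytest.approx(
            0.0, abs=1e-9)

    def test_anti_axes(self):
        z = np.array([0, 0, 1.0])
        assert interdomain_dihedral(z, self.C1, self.C2, -z) == pytest.approx(
            180.0)

    def test_reflection_flips_sign(self):
        # axis1 lies in the x-z plane, which also contains the center line;
        # reflecting axis2 through that plane must negate the torsion
        a1 = np.array([0.2, 0.0, 0.98])
        a1 /= np.linalg.norm(a1)
        a2 = np.array([0.1, 0.5, 0.85])
        a2 /= np.linalg.norm(a2)
        base = interdomain_dihedral(a1, self.C1, self.C2, a2)
        refl = interdomain_dihedral(a1, self.C1, self.C2,
                                    a2 * np.array([1.0, -1.0, 1.0]))
        assert refl == pytest.approx(-base, abs=1e-9)
        assert base != 0.0

    def test_parallel_axis_rejected(self):
        x = np.array([1.0, 0, 0])
        with pytest.raises(ValueError, match="parallel"):
            interdomain_dihedral(x, self.C1, self.C2, np.array([0, 0, 1.0]))

    def test_twist_schedule_recovery(self, default_dataset):
        """The prescribed angle and twist sweeps of the CH3 pair come back
        exactly from the noise-free generated coordinates."""
        model, traj, truth = default_dataset
        n = len(traj)
        target_angle = np.linspace(30.0, 60.0, n)
        target_twist = np.linspace(0.0, 90.0, n)
        np.testing.assert_allclose(truth.descriptors["D"], target_angle,
                                   atol=1e-9)
        np.testing.assert_allclose(truth.descriptors["H"], target_twist,
                                   atol=1e-9)


class TestPeriodicContact:
    def test_single_atom_centered(self):
        model, _ = make_model([[1.5, 1.5, 1.5]])
        frame = Frame(np.array([[1.5, 1.5, 1.5]]), box=np.array([3.0, 3, 3]))
        res = periodic_contact(frame, model, [1], cutoff=1.4)
        assert res["min_image_distance"] == pytest.approx(3.0)
        assert res["flag"] is False

    def test_two_atoms_near_opposite_walls(self):
        coords = np.array([[0.5, 1.5, 1.5], [2.5, 1.5, 1.5]])
        model, _ = make_model(coords)
        frame = Frame(coords, box=np.array([3.0, 3.0, 3.0]))
        res = periodic_contact(frame, model, [1, 2], cutoff=1.4)
        assert res["min_image_distance"] == pytest.approx(1.0)
        assert res["flag"] is True

    def test_spanning_solute_contacts_itself(self):
        coords = np.array([[0.5, 1.5, 1.5], [1.5, 1.5, 1.5], [2.5, 1.5, 1.5]])
        model, _ = make_model(coords)
        frame = Frame(coords, box=np.array([3.0, 3.0, 3.0]))
        res = periodic_contact(frame, model, [1, 2, 3], cutoff=1.4)
        assert res["flag"] is True
        assert res["min_image_distance"] == pytest.approx(1.0)

    def test_translation_invariance(self):
        rng = np.random.default_rng(4)
        coords = rng.uniform(0, 1.0, size=(8, 3)) + 1.0
        box = np.array([4.0, 3.5, 5.0])
        model, _ = make_model(coords)
        base = periodic_contact(Frame(coords, box=box), model,
                                list(range(1, 9)), cutoff=1.4)
        for _ in range(100):
            shift = rng.uniform(-5, 5, size=3)
            res = periodic_contact(Frame(coords + shift, box=box), model,
                                   list(range(1, 9)), cutoff=1.4)
            assert res["flag"] == base["flag"]
            assert res["min_image_distance"] == pytest.approx(
                base["min_image_distance"], abs=1e-9)

    def test_missing_box_rejected(self):
        model, frame = make_model([[0, 0, 0]])
        with pytest.raises(ValueError, match="box"):
            periodic_contact(frame, model, [1])


class TestRingGeometry:
    def test_parallel_stack(self):
        a = hexagon()
        b = hexagon() + [0, 0, 0.4]
        model, frame = make_model(np.vstack([a, b]))
        res = ring_geometry(frame, model, list(range(1, 7)),
                            list(range(7, 13)))
        assert res["centroid_distance"] == pytest.approx(0.4)
        assert res["plane_angle"] == pytest.approx(0.0, abs=1e-9)

    def test_t_stack_is_90(self):
        a = hexagon()
        R = Rotation.from_euler("x", 90, degrees=True).as_matrix()
        b = hexagon() @ R.T + [0, 0.5, 0]
        model, frame = make_model(np.vstack([a, b]))
        res = ring_geometry(frame, model, list(range(1, 7)),
                            list(range(7, 13)))
        assert res["plane_angle"] == pytest.approx(90.0)

    def test_tilted_ring_angle(self):
        a = hexagon()
        R = Rotation.from_euler("x", 25, degrees=True).as_matrix()
        b = hexagon() @ R.T + [0, 0, 0.4]
        model, frame = make_model(np.vstack([a, b]))
        res = ring_geometry(frame, model, list(range(1, 7)),
                            list(range(7, 13)))
        assert res["plane_angle"] == pytest.approx(25.0, abs=1e-6)

    def test_collinear_ring_rejected(self):
        line = np.outer(np.arange(3.0), [1.0, 0, 0])
        model, frame = make_model(np.vstack([line, hexagon() + 2.0]))
        with pytest.raises(ValueError, match="collinear"):
            ring_geometry(frame, model, [1, 2, 3], [4, 5, 6, 7, 8, 9])
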