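"""Geometric kernels: centres of mass, axis vectors, angles, superposition."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import membpos as mp
from membpos.geometry import plane_normal


def _helix_frame(n_res=12, spacing=1.5, direction=(0, 0, 1.0)):
    direction = np.asarray(direction, dtype=float)
    direction /= np.linalg.norm(direction)
    pos = np.arange(n_res)[:, None] * spacing * direction
    return mp.Frame(
        atom_names=np.full(n_res, "CA", dtype=object),
        residue_numbers=np.arange(1, n_res + 1),
        residue_names=np.full(n_res, "ALA", dtype=object),
        positions=pos,
    )


class TestCenterOfMass:
    def test_uniform_midpoint(self):
        com = mp.center_of_mass(np.array([[0.0, 0, 0], [0, 0, 2.0]]))
        assert np.allclose(com, [0, 0, 1.0])

    def test_single_particle_is_itself(self):
        assert np.allclose(mp.center_of_mass(np.array([[1.0, 2, 3]])), [1, 2, 3])

    def test_mass_weighted_matches_hand_computation(self):
        # masses C, C, N, O at distinct corners; independent arithmetic.
        pos = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        masses = np.array([12.0, 12.0, 14.0, 16.0])
        expected = (pos * masses[:, None]).sum(0) / masses.sum()
        assert np.allclose(mp.center_of_mass(pos, masses=masses), expected)
        # element inference from atom names gives the same result
        com = mp.center_of_mass(
            pos, atom_names=np.array(["C1", "C2", "N1", "O1"]), weighting="element"
        )
        assert np.allclose(com, (pos * np.array([12.011, 12.011, 14.007, 15.999])[:, None]).sum(0)
                           / (2 * 12.011 + 14.007 + 15.999))

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            mp.center_of_mass(np.empty((0, 3)))


class TestAxisVector:
    def test_straight_helix_along_z(self):
        v = mp.axis_vector(_helix_frame(), (1, 12))
        assert np.allclose(v / np.linalg.norm(v), [0, 0, 1])

    def test_rotated_helix_matches_rotation_oracle(self):
        frame = _helix_frame()
        rot = Rotation.from_euler("x", 90, degrees=True)
        rotated = frame.with_positions(rot.apply(frame.positions))
        v = mp.axis_vector(rotated, (1, 12))
        expected = rot.apply([0, 0, 1.0])
        assert np.allclose(v / np.linalg.norm(v), expected, atol=1e-12)

    def test_insufficient_residues_rejected(self):
        with pytest.raises(ValueError, match="need at least 8"):
            mp.axis_vector(_helix_frame(5), (1, 5))


class TestAngles:
    @pytest.mark.parametrize(
        "v,expected",
        [((0, 0, 1), 0.0), ((1, 0, 0), 90.0), ((0, 1, 1), 45.0), ((0, 0, -1), 180.0)],
    )
    def test_angle_to_normal(self, v, expected):
        assert mp.angle_to_normal(np.array(v, dtype=float)) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "v,expected",
        [((0, 0, -1), 0.0), ((1, 0, 1), 45.0), ((1, 0, 0), 90.0)],
    )
    def test_tilt_angle_folds(self, v, expected):
        assert mp.tilt_angle(np.array(v, dtype=float)) == pytest.approx(expected)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            mp.angle_to_normal(np.zeros(3))

    def test_antipode_sum_is_180(self, rng):
        for _ in range(20):
            v = rng.normal(size=3)
            total = mp.angle_to_normal(v) + mp.angle_to_normal(-v)
            assert total == pytest.approx(180.0, abs=1e-9)
            assert mp.tilt_angle(v) == pytest.approx(mp.tilt_angle(-v), abs=1e-9)


def _heme_frame(points):
    points = np.asarray(points, dtype=float)
    return mp.Frame(
        atom_names=np.array(["NA", "NB", "NC", "ND"], dtype=object),
        residue_numbers=np.full(4, 600),
        residue_names=np.full(4, "HEM", dtype=object),
        positions=points,
    )


class TestHemeTilt:
    SQUARE_XY = [[1, 0, 5], [0, 1, 5], [-1, 0, 5], [0, -1, 5]]

    def test_flat_in_membrane_plane_is_90(self):
        frame = _heme_frame(self.SQUARE_XY)
        assert mp.heme_tilt(frame, np.arange(4)) == pytest.approx(90.0)

    def test_upright_plane_is_0(self):
        pts = [[1, 0, 0], [0, 0, 1], [-1, 0, 0], [0, 0, -1]]  # xz plane
        assert mp.heme_tilt(_heme_frame(pts), np.arange(4)) == pytest.approx(0.0)

    def test_rotation_oracle_30_degrees(self):
        rot = Rotation.from_euler("x", 30, degrees=True)
        pts = rot.apply(np.asarray(self.SQUARE_XY, dtype=float))
        assert mp.heme_tilt(_heme_frame(pts), np.arange(4)) == pytest.approx(
            60.0, abs=1e-9
        )

    def test_collinear_points_rejected(self):
        pts = [[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]]
        with pytest.raises(ValueError, match="collinear"):
            mp.heme_tilt(_heme_frame(pts), np.arange(4))

    def test_plane_normal_least_squares(self, rng):
        # noisy points around z=0 plane -> normal close to z
        pts = np.column_stack([rng.normal(size=(20,)), rng.normal(size=(20,)),
                               1e-3 * rng.normal(size=(20,))])
        n = plane_normal(pts)
        assert abs(n[2]) > 0.999


class TestAxialDistances:
    def test_prescribed_offsets_recovered(self, class_a_system):
        traj, truth, segmap = class_a_system
        resolved = mp.resolve_segments(traj, segmap)
        d_glob, d_link, d_fg = mp.axial_distances(traj.frame(0), resolved)
        assert d_glob == pytest.approx(truth["d_globular"][0], abs=1e-9)
        assert d_link == pytest.approx(truth["d_linker"][0], abs=1e-9)
        assert d_fg == pytest.approx(truth["d_fg"][0], abs=1e-9)

    def test_symmetric_bilayer_center_is_zero(self):
        spec = mp.SyntheticSpec(grid_n=4)
        bilayer = mp.build_bilayer(spec)
        assert bilayer.positions[:, 2].mean() == pytest.approx(0.0, abs=1e-12)


class TestSuperposition:
    def test_identical_frames_zero_rmsd(self, rng):
        pts = rng.normal(size=(30, 3))
        _, _, r = mp.superpose(pts, pts)
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_translation_removed(self, rng):
        pts = rng.normal(size=(30, 3))
        _, _, r = mp.superpose(pts + np.array([5.0, -3.0, 2.0]), pts)
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_random_rotation_removed(self, rng):
        pts = rng.normal(size=(30, 3))
        rot = Rotation.random(rng=1234)
        _, _, r = mp.superpose(rot.apply(pts), pts)
        assert r < 1e-9

    def test_fitted_rmsd_never_exceeds_raw(self, rng):
        for _ in range(10):
            a = rng.normal(size=(20, 3))
            b = rng.normal(size=(20, 3))
            _, _, fitted = mp.superpose(a, b)
            assert fitted <= mp.rmsd(a, b) + 1e-12

    def test_collinear_points_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError):
            mp.superpose(line, line)


class TestRmsfBfactor:
    def test_static_trajectory_is_zero(self):
        coords = np.tile(np.random.default_rng(0).normal(size=(1, 10, 3)), (5, 1, 1))
        resnums = np.arange(1, 11)
        _, b = mp.rmsf_bfactor(coords, np.arange(10), resnums)
        assert np.allclose(b, 0.0)

    def test_gaussian_jitter_analytic_limit(self, rng):
        # <|dr|^2> = 3 sigma^2 so B -> 8 pi^2 sigma^2 as frames grow
        sigma = 0.4
        base = rng.normal(size=(1, 40, 3))
        coords = base + rng.normal(0, sigma, size=(4000, 40, 3))
        resnums = np.repeat(np.arange(1, 11), 4)
        _, b = mp.rmsf_bfactor(coords, np.arange(40), resnums)
        expected = 8 * np.pi**2 * sigma**2
        assert np.allclose(b.mean(), expected, rtol=0.05)

    def test_doubling_sigma_quadruples_b(self, rng):
        base = rng.normal(size=(1, 30, 3))
        resnums = np.arange(1, 31)
        noise = rng.normal(size=(3000, 30, 3))
        _, b1 = mp.rmsf_bfactor(base + 0.3 * noise, np.arange(30), resnums)
        _, b2 = mp.rmsf_bfactor(base + 0.6 * noise, np.arange(30), resnums)
        assert np.allclose(b2, 4.0 * b1, rtol=1e-9)

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            mp.rmsf_bfactor(np.zeros((1, 5, 3)), np.arange(5), np.arange(1, 6))


class TestInvariances:
    def test_orientation_invariant_under_z_rotation_and_xy_translation(
        self, class_a_system, rng
    ):
        traj, _, segmap = class_a_system
        base = mp.orientation_series(traj, segmap)
        for _ in range(3):
            angle = rng.uniform(0, 360)
            shift = np.array([rng.uniform(-20, 20), rng.uniform(-20, 20), 0.0])
            rot = Rotation.from_euler("z", angle, degrees=True)
            coords = np.einsum("fij,kj->fik", traj.coordinates, rot.as_matrix())
            coords += shift
            moved = mp.Trajectory(
                atom_names=traj.atom_names,
                residue_numbers=traj.residue_numbers,
                residue_names=traj.residue_names,
                coordinates=coords,
                segment_ids=traj.segment_ids,
                box=traj.box,
            )
            series = mp.orientation_series(moved, segmap)
            diff = (series - base).abs().to_numpy()
            assert np.nanmax(diff) < 1e-9
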