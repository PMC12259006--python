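import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from allostate import structmetrics as sm
from allostate import synthdata
from allostate.containers import EnsembleSample
from allostate.structio import Trajectory, write_trajectory
from tests.conftest import make_chain


class TestKabsch:
    def test_identity_on_equal_clouds(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(10, 3))
        R, t = sm.kabsch_transform(x, x)
        assert np.abs(R - np.eye(3)).max() < 1e-12
        assert np.abs(t).max() < 1e-12

    def test_recovers_rigid_motion(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(12, 3))
        Rtrue = Rotation.random(random_state=2).as_matrix()
        y = x @ Rtrue.T + [3.0, -1.0, 7.0]
        R, t = sm.kabsch_transform(x, y)
        moved = sm.apply_transform(x, R, t)
        assert sm.rmsd(moved, y) < 1e-10
        assert np.linalg.det(R) == pytest.approx(1.0)

    def test_matches_numeric_minimization_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(10, 3))
        y = rng.normal(size=(10, 3))
        R, t = sm.kabsch_transform(x, y)
        best = sm.rmsd(sm.apply_transform(x, R, t), y)

        def objective(v):
            Rv = Rotation.from_rotvec(v[:3]).as_matrix()
            return sm.rmsd(x @ Rv.T + v[3:], y)

        oracle = min(
            minimize(objective, np.r_[rv, tv], method="Nelder-Mead",
                     options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000}).fun
            for rv in [np.zeros(3), [1.0, 0.5, -0.5], [-2.0, 1.0, 2.0], [0.0, 3.0, 0.0]]
            for tv in [np.zeros(3), y.mean(axis=0) - x.mean(axis=0)]
        )
        assert best <= oracle + 1e-6

    def test_collinear_points_raise(self):
        x = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        with pytest.raises(ValueError, match="collinear"):
            sm.kabsch_transform(x, x + 1.0)


class TestRMSD:
    def test_identical_is_zero(self):
        x = np.arange(12.0).reshape(4, 3)
        assert sm.rmsd(x, x) == 0.0

    def test_single_displaced_atom(self):
        x = np.zeros((4, 3))
        x[:, 0] = [0, 3, 6, 9]
        y = x.copy()
        y[2, 2] += 2.0
        assert sm.rmsd(x, y) == pytest.approx(1.0)  # sqrt(2^2 / 4)

    def test_align_and_measure_on_different_subsets(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(12, 3))
        Rtrue = Rotation.random(random_state=5).as_matrix()
        y = x @ Rtrue.T + 2.0
        y[8:] += rng.normal(0, 1, size=(4, 3))  # perturb the measured tail only
        align_sub = np.arange(8)
        meas_sub = np.arange(8, 12)
        got = sm.rmsd(x, y, subset=meas_sub, align=True, align_subset=align_sub)
        # oracle: compose the alignment and measurement by hand
        R, t = sm.kabsch_transform(x[align_sub], y[align_sub])
        manual = np.sqrt(np.mean(np.sum((sm.apply_transform(x, R, t)[meas_sub] - y[meas_sub]) ** 2, axis=-1)))
        assert got == pytest.approx(manual, abs=1e-12)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            sm.rmsd(np.zeros((3, 3)), np.zeros((4, 3)))


class TestLinchpinRMSD:
    def test_reference_frame_is_zero(self, toy_small):
        ref = toy_small.reference
        assert sm.linchpin_rmsd(ref.structure, ref) < 1e-12

    def test_rigid_sidechain_displacement(self, toy_small):
        ref = toy_small.reference
        coords = ref.structure.coords.copy()
        coords[0, ref.target_selection.indices] += [0.0, 0.0, 3.0]
        frame = Trajectory(ref.structure.topology, coords)
        assert sm.linchpin_rmsd(frame, ref) == pytest.approx(3.0, abs=1e-10)

    def test_pose_independence(self, toy_small):
        ref = toy_small.reference
        traj = toy_small.trajectory
        base = sm.linchpin_rmsd(traj, ref, frame_index=0)
        R = Rotation.random(random_state=6).as_matrix()
        moved = Trajectory(traj.topology, traj.coords[:1] @ R.T - 40.0)
        assert sm.linchpin_rmsd(moved, ref) == pytest.approx(base, abs=1e-9)

    def test_matches_manual_composition(self, toy_small):
        ref = toy_small.reference
        traj = toy_small.trajectory
        got = sm.linchpin_rmsd(traj, ref, frame_index=5)
        c = traj.coords[5]
        rc = ref.structure.coords[0]
        R, t = sm.kabsch_transform(c[ref.align_selection.indices], rc[ref.align_selection.indices])
        moved = sm.apply_transform(c, R, t)
        manual = np.sqrt(np.mean(np.sum(
            (moved[ref.target_selection.indices] - rc[ref.target_selection.indices]) ** 2, axis=-1)))
        assert got == pytest.approx(manual, abs=1e-12)


class TestSASA:
    def test_single_atom_analytic_sphere(self, single_atom_traj):
        area = sm.sasa(single_atom_traj, n_points=960)[0]
        assert area == pytest.approx(4 * np.pi * (1.7 + 1.4) ** 2, rel=1e-6)

    def test_distant_atoms_additive(self):
        coords = np.array([[[0, 0, 0], [100, 0, 0]]], float)
        traj = make_chain(["LIG"], [("C1", "O1")], coords=coords)
        areas = sm.sasa(traj, n_points=960)
        assert areas[0] == pytest.approx(4 * np.pi * 3.1**2, rel=1e-6)
        assert areas[1] == pytest.approx(4 * np.pi * (1.52 + 1.4) ** 2, rel=1e-6)

    def test_enclosed_atom_is_buried(self):
        # cage of 30 atoms on a sphere tight enough to occlude the centre
        pts = sm.sphere_points(30) * 3.0
        names = tuple(f"C{i}" for i in range(31))
        coords = np.vstack([np.zeros(3), pts])[None, :, :]
        traj = make_chain(["LIG"], [names], coords=coords)
        area = sm.sasa(traj, n_points=960)[0]
        assert area < 0.02 * 4 * np.pi * 3.1**2

    def test_missing_radius_raises(self):
        traj = make_chain(["LIG"], [("C1",)])
        with pytest.raises(KeyError, match="radius"):
            sm.sasa(traj, radii={"N": 1.55})

    def test_point_count_convergence(self):
        rng = np.random.default_rng(7)
        names = tuple(f"C{i}" for i in range(30))
        coords = rng.normal(0, 3.0, size=(1, 30, 3))
        traj = make_chain(["LIG"], [names], coords=coords)
        a = sm.sasa(traj, n_points=960).sum()
        b = sm.sasa(traj, n_points=3840).sum()
        assert abs(a - b) / b <= 0.01

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(8)
        names = tuple(f"C{i}" for i in range(10))
        coords = rng.normal(0, 3.0, size=(1, 10, 3))
        traj = make_chain(["LIG"], [names], coords=coords)
        a = sm.sasa(traj, n_points=960)
        R = Rotation.random(random_state=9).as_matrix()
        moved = make_chain(["LIG"], [names], coords=coords @ R.T + 11.0)
        b = sm.sasa(moved, n_points=960)
        # the point grid is not rotated with the molecule: small residual jitter
        assert np.abs(a - b).max() < 0.02 * (4 * np.pi * 3.1**2)

    def test_matches_mdtraj_oracle(self, ideal_helix, tmp_path):
        md = pytest.importorskip("mdtraj")
        path = tmp_path / "helix.pdb"
        write_trajectory(ideal_helix, path)
        t = md.load(str(path))
        ref = md.shrake_rupley(t, probe_radius=0.14, n_sphere_points=960).sum() * 100.0
        ours = sm.sasa(ideal_helix, n_points=960).sum()
        assert ours == pytest.approx(ref, rel=0.03)


class TestBundleSASA:
    def test_buried_interface_near_zero(self):
        # sidechain beads sandwiched inside a tight cage of blocker atoms
        cage = sm.sphere_points(40) * 3.2
        names = [("CA", "CB"), tuple(f"C{i}" for i in range(40))]
        coords = np.vstack([[0, 0, 2.8], [0, 0, 0], cage])[None, :, :]
        traj = make_chain(["LEU", "LIG"], names, coords=coords)
        val = sm.bundle_sasa(traj, [1], n_points=960)
        assert val < 5.0  # vs ~120 A^2 exposed

    def test_monotone_in_hinge_angle(self):
        from allostate.synthdata import TOY_INTERFACE_RESIDUES, _toy_frame, _toy_topology

        top = _toy_topology()
        vals = []
        for angle in (0, 10, 20, 35, 50, 65):
            traj = Trajectory(top, _toy_frame(angle, 0.0)[None, :, :])
            vals.append(sm.bundle_sasa(traj, TOY_INTERFACE_RESIDUES, n_points=480))
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_empty_residue_set_warns(self, toy_small):
        with pytest.warns(UserWarning, match="empty"):
            vals = sm.bundle_sasa_profile(toy_small.trajectory, [])
        assert np.all(vals == 0)

    def test_missing_residue_raises(self, toy_small):
        with pytest.raises(ValueError, match="not in topology"):
            sm.bundle_sasa(toy_small.trajectory, [99])

    def test_profile_matches_per_frame(self, toy_small):
        traj = Trajectory(toy_small.trajectory.topology, toy_small.trajectory.coords[:3])
        prof = sm.bundle_sasa_profile(traj, toy_small.interface_residues, n_points=192)
        singles = [sm.bundle_sasa(traj, toy_small.interface_residues, frame=f, n_points=192) for f in range(3)]
        assert np.allclose(prof, singles)


class TestSecondaryStructure:
    def test_ideal_helix_mostly_H(self, ideal_helix):
        ss = sm.assign_secondary_structure(ideal_helix)
        assert ss.fraction("H") >= 0.9

    def test_extended_chain_is_coil(self):
        ext = synthdata.generate_ideal_helix(12, phi=-140.0, psi=135.0)
        ss = sm.assign_secondary_structure(ext)
        # a lone strand has no bridge partner: neither helix nor sheet
        assert ss.fraction("H") == 0.0
        assert ss.fraction("E") == 0.0

    def test_matches_mdtraj_dssp_on_helix(self, ideal_helix, tmp_path):
        md = pytest.importorskip("mdtraj")
        path = tmp_path / "helix.pdb"
        write_trajectory(ideal_helix, path)
        ref = md.compute_dssp(md.load(str(path)), simplified=True)[0]
        ours = sm.assign_secondary_structure(ideal_helix).labels
        interior = slice(2, -2)
        agree = np.mean(ours[interior] == ref[interior])
        assert agree >= 0.9

    def test_symmetric_geometry_no_bond(self):
        # r_ON == r_OH and r_CH == r_CN makes the Kabsch-Sander energy vanish
        r_on = 3.0
        e = 0.084 * 332 * (1 / r_on + 1 / 4.0 - 1 / r_on - 1 / 4.0)
        assert e == pytest.approx(0.0, abs=1e-12)
        assert not e < -0.5

    def test_missing_backbone_warns_and_labels_C(self):
        traj = make_chain(["ALA", "ALA", "ALA"], [("N", "CA", "C", "O"), ("CA",), ("N", "CA", "C", "O")])
        with pytest.warns(UserWarning, match="missing backbone"):
            ss = sm.assign_secondary_structure(traj)
        assert ss.labels[1] == "C"


class TestStructuredProbability:
    def test_all_helix_interior_is_one(self, ideal_helix):
        sample = EnsembleSample(np.array([[0, 0]] * 5))
        df = sm.structured_probability(sample, [ideal_helix])
        interior = df[(df.resid > 3) & (df.resid < 18)]
        assert np.all(interior.p_structured == 1.0)

    def test_half_helix_half_coil(self, ideal_helix):
        ext = synthdata.generate_ideal_helix(20, phi=-140.0, psi=135.0)
        entries = np.array([[0, 0], [1, 0]] * 3)
        df = sm.structured_probability(entries_sample(entries), [ideal_helix, ext])
        interior = df[(df.resid > 3) & (df.resid < 18)]
        assert np.allclose(interior.p_structured, 0.5)

    def test_single_frame_values_binary(self, ideal_helix):
        sample = EnsembleSample(np.array([[0, 0]]))
        df = sm.structured_probability(sample, [ideal_helix])
        assert set(df.p_structured.unique()) <= {0.0, 1.0}


def entries_sample(entries):
    return EnsembleSample(np.asarray(entries))


class TestHBond:
    def test_collinear_short_bond(self):
        assert sm.hbond_present([0, 0, 0], [1.0, 0, 0], [2.9, 0, 0])

    def test_bent_geometry_rejected(self):
        # D-H...A angle of 60 degrees
        h = np.array([0.0, 0, 0])
        d = np.array([1.0, 0, 0])
        a = np.array([np.cos(np.radians(60)), np.sin(np.radians(60)), 0]) * 1.9
        assert not sm.hbond_present(d, h, a)

    def test_angle_boundary_is_strict(self):
        h = np.zeros(3)
        d = np.array([1.0, 0, 0])
        for eps, expected in ((-1e-6, False), (1e-6, True)):
            ang = np.radians(120 + eps)
            a = np.array([np.cos(ang), np.sin(ang), 0]) * 1.9
            assert sm.hbond_present(d, h, a, angle_min=120.0) is expected

    def test_distance_cutoff(self):
        assert not sm.hbond_present([0, 0, 0], [1.0, 0, 0], [3.6, 0, 0], d_max=2.5)
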