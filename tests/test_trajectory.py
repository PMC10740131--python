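"""Trajectory-metric tests: Kabsch RMSD (with a rotation-grid brute-force
oracle and an mdtraj cross-check), RMSF, Shrake-Rupley SASA, hydrogen-bond
counting, and file readers."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from quenchbind import (
    Frame,
    InvalidInputError,
    QuenchBindWarning,
    Trajectory,
    count_hbonds,
    kabsch_rmsd,
    read_pdb,
    read_xyz,
    rmsf,
    sasa,
)
from quenchbind.synthetic import GeneratorConfig, gen_toy_trajectory


def make_frame(coords, names=None, classes=None, radii=None):
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    names = names or tuple(f"C{i}" for i in range(n))
    return Frame(
        tuple(names), tuple(range(1, n + 1)), coords, classes=classes, radii=radii
    )


def random_rigid(coords, seed):
    rng = np.random.default_rng(seed)
    rot = Rotation.random(random_state=rng).as_matrix()
    return coords @ rot.T + rng.uniform(-2, 2, 3)


def brute_force_min_rmsd(p, q, n_grid=18):
    """Independent oracle: minimise RMSD over rotations by scanning a
    discretised Euler-angle grid and polishing the best cell numerically.
    Translation is removed by centring both clouds."""
    p = p - p.mean(axis=0)
    q = q - q.mean(axis=0)

    def rmsd_of(angles):
        r = Rotation.from_euler("zyx", angles).as_matrix()
        d = p @ r.T - q
        return math.sqrt(np.mean(np.sum(d * d, axis=1)))

    grid = np.linspace(-math.pi, math.pi, n_grid, endpoint=False)
    best, best_angles = math.inf, None
    for a in grid:
        for b in grid[: n_grid // 2]:
            for c in grid:
                v = rmsd_of((a, b, c))
                if v < best:
                    best, best_angles = v, (a, b, c)
    polish = minimize(rmsd_of, best_angles, method="Nelder-Mead",
                      options={"xatol": 1e-10, "fatol": 1e-14})
    return min(best, float(polish.fun))


class TestKabschRmsd:
    def test_identical_frames_zero(self):
        xyz = np.random.default_rng(0).normal(size=(6, 3))
        f = make_frame(xyz)
        assert kabsch_rmsd(f, f) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_transform_invariance(self):
        xyz = np.random.default_rng(1).normal(size=(8, 3))
        moved = make_frame(random_rigid(xyz, seed=2))
        assert kabsch_rmsd(make_frame(xyz), moved) < 1e-10

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        a = make_frame(rng.normal(size=(7, 3)))
        b = make_frame(rng.normal(size=(7, 3)))
        assert kabsch_rmsd(a, b) == pytest.approx(kabsch_rmsd(b, a), abs=1e-10)

    def test_matches_brute_force_oracle_on_perturbed_toy(self):
        # 4-atom toy with one displaced atom, then rigidly moved: the
        # analytic minimum must agree with the rotation-grid search
        base = np.array(
            [[0.0, 0.0, 0.0], [0.3, 0.0, 0.0], [0.0, 0.3, 0.0], [0.0, 0.0, 0.3]]
        )
        perturbed = base.copy()
        perturbed[3] += np.array([0.05, -0.04, 0.06])
        perturbed = random_rigid(perturbed, seed=4)
        ours = kabsch_rmsd(make_frame(base), make_frame(perturbed))
        oracle = brute_force_min_rmsd(perturbed, base)
        assert ours == pytest.approx(oracle, abs=1e-3)
        assert ours > 0.01  # genuinely non-degenerate case

    def test_matches_mdtraj(self):
        md = pytest.importorskip("mdtraj")
        rng = np.random.default_rng(5)
        xyz = rng.normal(size=(2, 12, 3)) * 0.3
        top = md.Topology()
        chain = top.add_chain()
        res = top.add_residue("LIG", chain)
        for i in range(12):
            top.add_atom(f"C{i}", md.element.carbon, res)
        t = md.Trajectory(xyz.copy(), top)
        ref_rmsd = float(md.rmsd(t, t, frame=0)[1])
        ours = kabsch_rmsd(make_frame(xyz[0]), make_frame(xyz[1]))
        assert ours == pytest.approx(ref_rmsd, abs=1e-5)

    def test_atom_count_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            kabsch_rmsd(
                make_frame(np.zeros((4, 3))), make_frame(np.zeros((5, 3)))
            )

    def test_reflected_structure_not_matched_by_improper_rotation(self):
        # chiral 4-point set vs its mirror image: a proper rotation cannot
        # superpose them, so RMSD must stay > 0
        base = np.array(
            [[0.0, 0.0, 0.0], [0.3, 0.0, 0.0], [0.0, 0.2, 0.0], [0.1, 0.1, 0.4]]
        )
        mirrored = base * np.array([1.0, 1.0, -1.0])
        assert kabsch_rmsd(make_frame(base), make_frame(mirrored)) > 1e-3


class TestRmsf:
    def test_static_trajectory_is_zero(self):
        xyz = np.random.default_rng(6).normal(size=(5, 3))
        traj = Trajectory(
            frames=tuple(make_frame(xyz) for _ in range(4)), times=(0, 1, 2, 3)
        )
        assert np.allclose(rmsf(traj), 0.0, atol=1e-12)

    def test_two_state_oscillation_closed_form(self):
        # one atom alternating +/- d about its mean: RMSF = d exactly
        base = np.array(
            [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0],
             [0.5, 0.5, 0.5]]
        )
        d = 0.07
        frames, mean = [], base.copy()
        for k in range(6):
            xyz = base.copy()
            xyz[4, 0] += d if k % 2 == 0 else -d
            frames.append(make_frame(xyz))
        fluct = rmsf(
            Trajectory(frames=tuple(frames), times=tuple(range(6))),
            align_to=make_frame(mean),
            fit_subset=[0, 1, 2, 3],  # rigid core: alignment is identity
        )
        assert fluct[4] == pytest.approx(d, rel=1e-6)
        assert np.allclose(fluct[:4], 0.0, atol=1e-9)

    def test_pure_rigid_motion_aligns_away(self):
        cfg = GeneratorConfig(seed=7)
        traj = gen_toy_trajectory(8, 6, cfg, rigid_motion=True, jitter_sigma=0.0)
        assert np.max(rmsf(traj)) < 1e-9

    def test_single_frame_rejected(self):
        xyz = np.zeros((4, 3))
        with pytest.raises(InvalidInputError):
            rmsf(Trajectory(frames=(make_frame(xyz),), times=(0.0,)))


class TestSasa:
    def test_single_sphere_analytic(self):
        f = make_frame(np.zeros((1, 3)), names=("O1",), radii=np.array([0.15]))
        # lone atom has no occluders; area = 4 pi (r + probe)^2
        # (superposition precondition does not apply here)
        out = sasa(f, probe_radius=0.14)
        analytic = 4 * math.pi * 0.29**2
        assert out.total == pytest.approx(analytic, rel=0.01)

    def test_coincident_spheres_count_once(self):
        # two identical atoms fully overlapping (separation << any radius):
        # each sphere hides half the other, total equals one sphere
        xyz = np.array([[0.0, 0.0, 0.0], [1e-6, 0.0, 0.0]])
        f = make_frame(xyz, radii=np.array([0.17, 0.17]))
        single = 4 * math.pi * (0.17 + 0.14) ** 2
        out = sasa(f)
        assert out.total == pytest.approx(single, rel=0.02)

    def test_distant_atoms_add(self):
        xyz = np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0]])
        f = make_frame(xyz, radii=np.array([0.17, 0.152]))
        expected = 4 * math.pi * ((0.17 + 0.14) ** 2 + (0.152 + 0.14) ** 2)
        assert sasa(f).total == pytest.approx(expected, rel=0.01)

    def test_hydrophobic_hydrophilic_split(self):
        xyz = np.array([[0.0, 0.0, 0.0], [5.0, 0.0, 0.0]])
        classes = (frozenset({"hydrophobic"}), frozenset({"hydrophilic"}))
        f = make_frame(xyz, classes=classes, radii=np.array([0.17, 0.152]))
        out = sasa(f)
        assert out.hydrophobic == pytest.approx(4 * math.pi * 0.31**2, rel=0.01)
        assert out.hydrophilic == pytest.approx(4 * math.pi * 0.292**2, rel=0.01)
        assert out.total == pytest.approx(out.hydrophobic + out.hydrophilic, rel=1e-9)

    def test_quadrature_convergence(self):
        rng = np.random.default_rng(8)
        xyz = rng.uniform(0, 0.5, size=(10, 3))
        f = make_frame(xyz, radii=np.full(10, 0.17))
        coarse = sasa(f, n_points=960).total
        fine = sasa(f, n_points=3840).total
        assert abs(coarse - fine) / fine < 0.01

    def test_rigid_invariance(self):
        rng = np.random.default_rng(9)
        xyz = rng.uniform(0, 0.6, size=(6, 3))
        f = make_frame(xyz, radii=np.full(6, 0.16))
        moved = make_frame(random_rigid(xyz, seed=10), radii=np.full(6, 0.16))
        assert sasa(moved).total == pytest.approx(sasa(f).total, rel=0.01)

    def test_matches_mdtraj_shrake_rupley(self):
        md = pytest.importorskip("mdtraj")
        rng = np.random.default_rng(11)
        xyz = rng.uniform(0, 0.5, size=(1, 8, 3))
        top = md.Topology()
        chain = top.add_chain()
        res = top.add_residue("LIG", chain)
        for i in range(8):
            top.add_atom(f"C{i}", md.element.carbon, res)
        ref = float(
            md.shrake_rupley(md.Trajectory(xyz.copy(), top), n_sphere_points=960).sum()
        )
        f = make_frame(xyz[0], radii=np.full(8, 0.17))
        assert sasa(f, n_points=960).total == pytest.approx(ref, rel=0.02)


class TestHbonds:
    def _oho(self, oo_dist, h_angle_deg=0.0):
        """Donor O with H pointing toward acceptor O, optional off-axis angle."""
        theta = math.radians(h_angle_deg)
        h = 0.10 * np.array([math.cos(theta), math.sin(theta), 0.0])
        coords = np.array([[0.0, 0.0, 0.0], h, [oo_dist, 0.0, 0.0]])
        classes = (
            frozenset({"donor"}),
            frozenset(),
            frozenset({"acceptor"}),
        )
        return make_frame(coords, names=("O1", "H1", "O2"), classes=classes)

    def test_textbook_linear_geometry_counts_one(self):
        assert count_hbonds(self._oho(0.28)) == 1

    def test_distance_cutoff(self):
        assert count_hbonds(self._oho(0.40)) == 0

    def test_angle_cutoff(self):
        assert count_hbonds(self._oho(0.28, h_angle_deg=45.0)) == 0

    def test_no_flags_warns_and_returns_zero(self):
        f = make_frame(np.random.default_rng(12).normal(size=(4, 3)),
                       classes=(frozenset(),) * 4)
        with pytest.warns(QuenchBindWarning):
            assert count_hbonds(f) == 0

    def test_rigid_invariance(self):
        f = self._oho(0.28)
        moved = Frame(
            f.atom_names, f.residue_ids, random_rigid(f.coords, seed=13),
            classes=f.classes,
        )
        assert count_hbonds(moved) == 1


class TestReaders:
    PDB_TEXT = """\
MODEL        1
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      10.751   5.144  -4.308  1.00  0.00           C
ATOM      4  O   ALA A   1       9.927   4.430  -4.877  1.00  0.00           O
ENDMDL
MODEL        2
ATOM      1  N   ALA A   1      11.204   6.234  -6.404  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.739   6.171  -5.047  1.00  0.00           C
ATOM      3  C   ALA A   1      10.851   5.244  -4.208  1.00  0.00           C
ATOM      4  O   ALA A   1      10.027   4.530  -4.777  1.00  0.00           O
ENDMDL
END
"""

    def test_pdb_multimodel_angstrom_to_nm(self, tmp_path):
        p = tmp_path / "toy.pdb"
        p.write_text(self.PDB_TEXT)
        traj = read_pdb(p)
        assert len(traj) == 2
        frame = traj.frames[0]
        assert len(frame) == 4
        assert frame.coords[0, 0] == pytest.approx(1.1104, abs=1e-4)  # A -> nm
        assert frame.elements == ("N", "C", "C", "O")
        assert frame.radii is not None and frame.classes is not None

    def test_xyz_roundtrip(self, tmp_path):
        p = tmp_path / "toy.xyz"
        p.write_text("3\nframe 1\nC 0.0 0.0 0.0\nO 1.5 0.0 0.0\nN 0.0 1.5 0.0\n"
                     "3\nframe 2\nC 0.1 0.0 0.0\nO 1.6 0.0 0.0\nN 0.0 1.6 0.0\n")
        traj = read_xyz(p)
        assert len(traj) == 2
        assert traj.frames[0].coords[1, 0] == pytest.approx(0.15)
        assert traj.frames[0].elements == ("C", "O", "N")

    def test_truncated_xyz_rejected(self, tmp_path):
        p = tmp_path / "bad.xyz"
        p.write_text("4\ncomment\nC 0 0 0\n")
        with pytest.raises(InvalidInputError):
            read_xyz(p)
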