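"""Core I/O: readers, selections, neighbor search, superposition, RMSD."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from memdiverge.core_io import (
    DegenerateGeometryError,
    Selection,
    Trajectory,
    kabsch_superpose,
    minimum_image_displacement,
    neighbor_pairs,
    read_topology,
    read_trajectory,
    rmsd_series,
    select,
    write_trajectory,
)
from memdiverge.synthetic_data import SyntheticTruth, gen_gating_toggle

from conftest import make_trajectory


# ---------------------------------------------------------------------------
# file reading
# ---------------------------------------------------------------------------

class TestReadTopology:
    def test_pdb_angstrom_to_nm(self, pdb_water_file):
        top = read_topology(pdb_water_file)
        np.testing.assert_allclose(top.frame0[0], [0.1, 0.2, 0.3], atol=1e-6)
        np.testing.assert_allclose(top.box0, [1.0, 1.0, 1.0], atol=1e-6)

    def test_gro_box_line(self, gro_minimal_file):
        top = read_topology(gro_minimal_file)
        np.testing.assert_allclose(top.box0, [10.0, 10.0, 10.0], atol=1e-6)
        np.testing.assert_allclose(top.frame0[0], [0.1, 0.2, 0.3], atol=1e-4)

    def test_water_oxygen_role_from_dictionary(self, pdb_water_file):
        top = read_topology(pdb_water_file)
        # independent lookup oracle over the shipped dictionaries
        from memdiverge.core_io import WATER_OXYGEN_NAMES, WATER_RESNAMES

        expected = [
            "water-oxygen"
            if (r in WATER_RESNAMES and n in WATER_OXYGEN_NAMES)
            else "unassigned"
            for n, r in zip(top.names, top.resnames)
        ]
        assert list(top.roles) == expected

    def test_unknown_residue_warns_not_fails(self, tmp_path):
        p = tmp_path / "odd.pdb"
        p.write_text(
            "ATOM      1  XX  XYZ A   1       1.000   2.000   3.000  1.00  0.00\n"
            "END\n"
        )
        with pytest.warns(UserWarning, match="unassigned"):
            top = read_topology(p)
        assert top.roles[0] == "unassigned"


class TestReadTrajectory:
    def test_multi_model_pdb_frame_count(self, tmp_path):
        lines = ["CRYST1   10.000   10.000   10.000  90.00  90.00  90.00 P 1\n"]
        for m in range(1, 6):
            lines.append(f"MODEL     {m:4d}\n")
            for i in range(3):
                lines.append(
                    f"ATOM  {i + 1:5d}  CA  GLY A{i + 1:4d}    "
                    f"{m + i:8.3f}{0.0:8.3f}{0.0:8.3f}  1.00  0.00\n"
                )
            lines.append("ENDMDL\n")
        p = tmp_path / "multi.pdb"
        p.write_text("".join(lines))
        top = read_topology(p)
        traj = read_trajectory(p, top)
        assert traj.n_frames == 5
        assert traj.dt is None  # PDB carries no time stamps

    def test_particle_count_mismatch_is_hard_error(self, tmp_path, pdb_water_file):
        top = read_topology(pdb_water_file)  # 3 atoms
        p = tmp_path / "four.pdb"
        p.write_text(
            "CRYST1   10.000   10.000   10.000  90.00  90.00  90.00 P 1\n"
            + "".join(
                f"ATOM  {i + 1:5d}  CA  GLY A{i + 1:4d}    "
                f"{1.0:8.3f}{2.0:8.3f}{3.0:8.3f}  1.00  0.00\n"
                for i in range(4)
            )
            + "END\n"
        )
        with pytest.raises(ValueError, match="mismatch"):
            read_trajectory(p, top)

    def test_xtc_round_trip_within_format_precision(self, tmp_path):
        traj, _ = gen_gating_toggle(SyntheticTruth(seed=2), n_frames=15)
        write_trajectory(traj, tmp_path / "t.xtc", tmp_path / "t.gro")
        top2 = read_topology(tmp_path / "t.gro")
        tr2 = read_trajectory(tmp_path / "t.xtc", top2)
        assert tr2.n_frames == traj.n_frames
        assert np.abs(tr2.coords - traj.coords).max() < 1e-3  # XTC precision


# ---------------------------------------------------------------------------
# selections
# ---------------------------------------------------------------------------

class TestSelections:
    def test_grammar(self):
        traj = make_trajectory(
            np.zeros((1, 4, 3)),
            [5.0, 5.0, 5.0],
            names=["CA", "CB", "PO4", "OW"],
            resnames=["GLY", "GLY", "POPC", "SOL"],
            resids=[1, 1, 2, 3],
        )
        top = traj.topology
        assert list(select(top, "protein and name CA").indices) == [0]
        assert list(select(top, "phosphate").indices) == [2]
        assert list(select(top, "water").indices) == [3]
        assert list(select(top, "resid 1-2").indices) == [0, 1, 2]
        assert list(select(top, "not (protein or water)").indices) == [2]
        with pytest.raises(ValueError):
            select(top, "name")

    def test_duplicate_indices_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            Selection(indices=np.array([1, 1, 2]))


# ---------------------------------------------------------------------------
# neighbor search
# ---------------------------------------------------------------------------

def brute_force_pairs(a, b, cutoff, box):
    """O(N^2) all-pairs minimum-image oracle."""
    out = []
    box = np.asarray(box, dtype=float)
    for i, pa in enumerate(a):
        for j, pb in enumerate(b):
            d = pa - pb
            d -= box * np.round(d / box)
            dist = np.linalg.norm(d)
            if dist <= cutoff:
                out.append((i, j, dist))
    return out


class TestNeighborPairs:
    def test_wraparound(self):
        pairs = neighbor_pairs(
            np.array([[0.0, 0.0, 0.0]]),
            np.array([[9.9, 0.0, 0.0]]),
            0.2,
            [10.0, 10.0, 10.0],
        )
        assert len(pairs) == 1
        assert pairs[0][2] == pytest.approx(0.1, abs=1e-6)

    def test_zero_cutoff_includes_coincident_points(self):
        pts = np.array([[1.0, 1.0, 1.0], [2.0, 2.0, 2.0]])
        pairs = neighbor_pairs(pts, pts.copy(), 0.0, [10.0, 10.0, 10.0])
        assert {(i, j) for i, j, _ in pairs} == {(0, 0), (1, 1)}

    def test_cutoff_beyond_half_box_raises(self):
        with pytest.raises(ValueError, match="half"):
            neighbor_pairs(np.zeros((1, 3)), np.zeros((1, 3)), 3.0, [5.0, 5.0, 5.0])

    def test_matches_brute_force_oracle(self, rng):
        a = rng.uniform(0, 5, size=(50, 3))
        b = rng.uniform(0, 5, size=(50, 3))
        got = neighbor_pairs(a, b, 1.0, [5.0, 5.0, 5.0])
        want = brute_force_pairs(a, b, 1.0, [5.0, 5.0, 5.0])
        assert {(i, j) for i, j, _ in got} == {(i, j) for i, j, _ in want}
        got_d = {(i, j): d for i, j, d in got}
        for i, j, d in want:
            assert got_d[(i, j)] == pytest.approx(d, abs=1e-5)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(2, 60))
    def test_property_equals_oracle_and_symmetric(self, seed, n):
        r = np.random.default_rng(seed)
        pts = r.uniform(0, 4, size=(n, 3))
        box = [4.0, 4.0, 4.0]
        got = {(i, j) for i, j, _ in neighbor_pairs(pts, pts, 0.8, box)}
        want = {(i, j) for i, j, _ in brute_force_pairs(pts, pts, 0.8, box)}
        assert got == want
        assert got == {(j, i) for i, j in got}  # symmetry

    def test_min_image_triangle_inequality(self, rng):
        box = np.array([4.0, 4.0, 4.0])
        pts = rng.uniform(0, 4, size=(12, 3))

        def d(i, j):
            return np.linalg.norm(
                minimum_image_displacement(pts[i] - pts[j], box)
            )

        for i in range(12):
            for j in range(12):
                for k in range(12):
                    assert d(i, j) <= d(i, k) + d(k, j) + 1e-12


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def grid_search_superpose(mobile, reference, coarse=20.0):
    """Independent oracle: exhaustive Euler-angle grid + local refinement."""
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

    cm, cr = mobile.mean(axis=0), reference.mean(axis=0)
    x, y = mobile - cm, reference - cr

    def rmsd_of(angles):
        rot = Rotation.from_euler("zyx", angles, degrees=True).as_matrix()
        return np.sqrt(((x @ rot.T - y) ** 2).sum(axis=1).mean())

    best_angles, best = None, np.inf
    grid = np.arange(-180, 180, coarse)
    for a in grid:
        for b in np.arange(-90, 91, coarse):
            for c in grid:
                v = rmsd_of((a, b, c))
                if v < best:
                    best, best_angles = v, (a, b, c)
    res = minimize(rmsd_of, best_angles, method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-12})
    return res.fun


class TestKabsch:
    def test_identity(self, rng):
        ref = rng.normal(size=(8, 3))
        s = kabsch_superpose(ref.copy(), ref)
        assert s.rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(s.rotation, np.eye(3), atol=1e-8)

    def test_pure_translation(self, rng):
        ref = rng.normal(size=(8, 3))
        s = kabsch_superpose(ref + np.array([1.0, 2.0, 3.0]), ref)
        assert s.rmsd == pytest.approx(0.0, abs=1e-10)

    def test_rotation_with_displacement_matches_grid_search(self, rng):
        ref = rng.normal(size=(10, 3))
        th = np.radians(37.0)
        rot = np.array(
            [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]]
        )
        mob = ref @ rot.T
        mob[0] += np.array([0.2, 0.0, 0.0])
        s = kabsch_superpose(mob, ref)
        oracle = grid_search_superpose(mob, ref)
        assert s.rmsd == pytest.approx(oracle, abs=1e-3)
        assert np.linalg.det(s.rotation) == pytest.approx(1.0, abs=1e-6)

    def test_rmsd_invariant_under_rigid_pretransform(self, rng):
        ref = rng.normal(size=(12, 3))
        mob = ref + rng.normal(0, 0.1, size=(12, 3))
        base = kabsch_superpose(mob, ref).rmsd
        from scipy.spatial.transform import Rotation

        for seed in range(3):
            r = Rotation.random(rng=np.random.default_rng(seed)).as_matrix()
            t = np.array([seed, -seed, 2.0])
            moved = mob @ r.T + t
            assert kabsch_superpose(moved, ref).rmsd == pytest.approx(base, abs=1e-9)

    def test_collinear_raises(self):
        pts = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(pts, pts + 0.1)

    def test_too_few_points_raises(self):
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestRMSDSeries:
    def _system(self, rng, n_frames=5):
        ref = rng.normal(size=(10, 3)) + 5.0
        coords = np.tile(ref, (n_frames, 1, 1))
        traj = make_trajectory(coords, [20.0, 20.0, 20.0])
        return traj, ref

    def test_identical_frames_zero(self, rng):
        traj, ref = self._system(rng)
        fit = Selection(np.arange(6), "fit")
        meas = Selection(np.arange(6, 10), "meas")
        out = rmsd_series(traj, ref, fit, meas)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-10)

    def test_rigidly_displaced_measure_selection(self, rng):
        traj, ref = self._system(rng)
        traj.coords[:, 6:, :] += np.array([0.0, 0.0, 0.5])
        fit = Selection(np.arange(6), "fit")
        meas = Selection(np.arange(6, 10), "meas")
        out = rmsd_series(traj, ref, fit, meas)
        np.testing.assert_allclose(out.values, 0.5, atol=1e-10)

    def test_empty_selection_raises(self, rng):
        traj, ref = self._system(rng)
        with pytest.raises(ValueError, match="empty"):
            rmsd_series(traj, ref, Selection(np.array([], dtype=int)), Selection(np.arange(3)))
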