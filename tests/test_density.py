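import numpy as np
import pytest
from scipy import stats
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from scramblekit.density_mapper import (
    AlignmentReference,
    DensityGrid,
    GridSpec,
    accumulate_density,
    kabsch_superpose,
    read_dx,
    rmsd_series,
    write_dx,
)
from scramblekit.trajectory_io import Selection, Trajectory

from conftest import make_frame


def rand_rotation(rng):
    return Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()


def horn_quaternion_rmsd(mobile, target):
    """Independent superposition oracle: Horn's closed-form quaternion
    eigenvalue method (no SVD), returning the optimal RMSD."""
    a = mobile - mobile.mean(axis=0)
    b = target - target.mean(axis=0)
    m = a.T @ b
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(k)[-1]
    e = np.sum(a**2) + np.sum(b**2) - 2.0 * lam
    return np.sqrt(max(e, 0.0) / len(a))


def grid_search_rmsd(mobile, target):
    """Brute-force oracle: numeric optimisation over Euler angles from
    multiple starting points."""
    a = mobile - mobile.mean(axis=0)
    b = target - target.mean(axis=0)

    def cost(angles):
        r = Rotation.from_euler("xyz", angles).as_matrix()
        return np.mean(np.sum((a @ r.T - b) ** 2, axis=1))

    best = np.inf
    for start in ([0, 0, 0], [1, 1, 1], [2, -1, 0.5], [-2, 0.3, -1.2],
                  [3, 1.5, 2.5], [0.5, -2.5, 1.0]):
        res = minimize(cost, start, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 5000})
        best = min(best, res.fun)
    return np.sqrt(best)


class TestKabsch:
    def test_identity(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 5, (10, 3))
        ref = AlignmentReference(coords, Selection("all", np.arange(10)))
        transform, rmsd = kabsch_superpose(make_frame(coords), ref)
        assert rmsd == pytest.approx(0.0, abs=1e-7)
        np.testing.assert_allclose(transform.rotation, np.eye(3), atol=1e-8)

    def test_rigid_motion_recovered(self):
        rng = np.random.default_rng(1)
        coords = rng.uniform(0, 5, (12, 3))
        r = rand_rotation(rng)
        t = np.array([1.0, -2.0, 0.5])
        moved = coords @ r.T + t
        ref = AlignmentReference(coords, Selection("all", np.arange(12)))
        transform, rmsd = kabsch_superpose(make_frame(moved), ref)
        assert rmsd == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(transform.apply(moved), coords, atol=1e-8)

    def test_proper_rotation_only(self):
        rng = np.random.default_rng(2)
        coords = rng.uniform(0, 5, (8, 3))
        mirrored = coords * np.array([1, 1, -1])
        ref = AlignmentReference(coords, Selection("all", np.arange(8)))
        transform, _ = kabsch_superpose(make_frame(mirrored), ref)
        assert np.linalg.det(transform.rotation) == pytest.approx(1.0)

    def test_perturbed_four_point_matches_grid_search(self):
        rng = np.random.default_rng(3)
        coords = rng.uniform(0, 3, (4, 3))
        mobile = coords.copy()
        mobile[0] += [0.2, -0.1, 0.15]
        ref = AlignmentReference(coords, Selection("all", np.arange(4)))
        _, rmsd = kabsch_superpose(make_frame(mobile), ref)
        assert rmsd == pytest.approx(grid_search_rmsd(mobile, coords), abs=1e-6)

    def test_matches_quaternion_oracle_randomized(self):
        rng = np.random.default_rng(4)
        for _ in range(300):
            n = int(rng.integers(3, 7))
            coords = rng.uniform(0, 4, (n, 3))
            while np.linalg.matrix_rank(coords - coords.mean(0), tol=1e-8) < 2:
                coords = rng.uniform(0, 4, (n, 3))
            mobile = coords @ rand_rotation(rng).T + rng.uniform(-2, 2, 3)
            mobile += rng.normal(0, 0.1, (n, 3))
            ref = AlignmentReference(coords, Selection("all", np.arange(n)))
            _, rmsd = kabsch_superpose(make_frame(mobile), ref)
            assert rmsd == pytest.approx(horn_quaternion_rmsd(mobile, coords),
                                         abs=1e-9)

    def test_rmsd_invariant_under_rigid_pretransform(self):
        rng = np.random.default_rng(5)
        coords = rng.uniform(0, 5, (9, 3))
        mobile = coords + rng.normal(0, 0.2, (9, 3))
        ref = AlignmentReference(coords, Selection("all", np.arange(9)))
        _, rmsd0 = kabsch_superpose(make_frame(mobile), ref)
        pre = mobile @ rand_rotation(rng).T + np.array([3.0, 1.0, -4.0])
        _, rmsd1 = kabsch_superpose(make_frame(pre), ref)
        assert rmsd1 == pytest.approx(rmsd0, abs=1e-9)

    def test_collinear_fit_rejected(self):
        coords = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="collinear"):
            AlignmentReference(coords, Selection("all", np.arange(5)))


class TestRmsdSeries:
    def test_reference_copies_are_zero(self):
        rng = np.random.default_rng(6)
        coords = rng.uniform(0, 5, (10, 3))
        ref = AlignmentReference(coords, Selection("all", np.arange(10)))
        traj = Trajectory.from_frames(
            [make_frame(coords, time=float(t)) for t in range(5)])
        _, rmsd = rmsd_series(traj, ref)
        np.testing.assert_allclose(rmsd, 0.0, atol=1e-10)

    def test_single_displaced_particle_closed_form(self):
        # fit on a static subset; one of N report particles displaced by d
        rng = np.random.default_rng(7)
        n_fit, n_rep = 10, 8
        coords = rng.uniform(0, 5, (n_fit + n_rep, 3))
        fit = Selection("fit", np.arange(n_fit))
        report = Selection("rep", np.arange(n_fit, n_fit + n_rep))
        ref = AlignmentReference(coords, fit)
        d = 0.7
        moved = coords.copy()
        moved[n_fit + 2, 0] += d
        traj = Trajectory.from_frames([make_frame(moved)])
        _, rmsd = rmsd_series(traj, ref, report=report)
        assert rmsd[0] == pytest.approx(d / np.sqrt(n_rep), abs=1e-10)

    def test_helix_subset_below_full_backbone(self):
        # helices static, loops mobile: subset RMSD must not exceed full RMSD
        rng = np.random.default_rng(8)
        n = 60
        coords = rng.uniform(0, 6, (n, 3))
        helix = Selection("helix", np.arange(0, 30))
        full = Selection("full", np.arange(n))
        moved = coords.copy()
        moved[30:] += rng.normal(0, 0.4, (30, 3))  # loops move
        ref = AlignmentReference(coords, full)
        traj = Trajectory.from_frames([make_frame(moved)])
        _, rmsd_full = rmsd_series(traj, ref, report=full)
        _, rmsd_helix = rmsd_series(traj, ref, report=helix)
        assert rmsd_helix[0] <= rmsd_full[0]

    def test_empty_report_rejected(self):
        rng = np.random.default_rng(9)
        coords = rng.uniform(0, 5, (5, 3))
        ref = AlignmentReference(coords, Selection("all", np.arange(5)))
        traj = Trajectory.from_frames([make_frame(coords)])
        with pytest.raises(ValueError, match="empty"):
            rmsd_series(traj, ref, report=Selection("none", np.array([], dtype=int)))


class TestDensity:
    def grid(self, spacing=0.5, n=10, origin=(0.0, 0.0, 0.0)):
        return GridSpec(origin=origin, spacing=(spacing,) * 3, shape=(n, n, n))

    def test_static_particle_density(self):
        pos = np.array([[1.25, 1.25, 1.25]])
        traj = Trajectory.from_frames(
            [make_frame(pos, time=float(t) * 10.0, box_lengths=(5, 5, 5))
             for t in range(100)])
        grid = accumulate_density(traj, Selection("p", np.array([0])), self.grid())
        dens = grid.density
        vox = grid.spec.voxel_volume
        assert dens[2, 2, 2] == pytest.approx(1.0 / vox)
        assert np.count_nonzero(dens) == 1

    def test_conservation_identity(self):
        rng = np.random.default_rng(10)
        frames = [make_frame(rng.uniform(-1, 6, (40, 3)), time=float(t) * 10.0,
                             box_lengths=(5, 5, 5)) for t in range(7)]
        traj = Trajectory.from_frames(frames)
        grid = accumulate_density(traj, Selection("p", np.arange(40)), self.grid())
        total = np.sum(grid.density) * grid.spec.voxel_volume
        assert total == pytest.approx(grid.mean_in_bounds_count, rel=1e-12)

    def test_out_of_bounds_counted(self):
        pos = np.array([[1.0, 1.0, 1.0], [20.0, 20.0, 20.0]])
        traj = Trajectory.from_frames([make_frame(pos, box_lengths=(30, 30, 30))])
        grid = accumulate_density(traj, Selection("p", np.arange(2)), self.grid())
        assert grid.n_out_of_bounds == 1

    def test_uniform_particles_poisson_dispersion(self):
        rng = np.random.default_rng(11)
        frames = [make_frame(rng.uniform(0, 5, (200, 3)), time=float(t) * 10.0,
                             box_lengths=(5, 5, 5)) for t in range(30)]
        traj = Trajectory.from_frames(frames)
        grid = accumulate_density(traj, Selection("p", np.arange(200)), self.grid())
        counts = grid.counts.ravel()
        # index of dispersion ~ chi2_{n-1}/(n-1) under Poisson
        disp = counts.var(ddof=1) / counts.mean()
        n = len(counts)
        lo = stats.chi2.ppf(0.005, n - 1) / (n - 1)
        hi = stats.chi2.ppf(0.995, n - 1) / (n - 1)
        assert lo < disp < hi

    def test_linearity_of_accumulation(self):
        rng = np.random.default_rng(12)
        frames = [make_frame(rng.uniform(0, 5, (20, 3)), time=float(t) * 10.0,
                             box_lengths=(5, 5, 5)) for t in range(8)]
        sel = Selection("p", np.arange(20))
        whole = accumulate_density(Trajectory.from_frames(frames), sel, self.grid())
        h1 = accumulate_density(Trajectory.from_frames(frames[:4]), sel, self.grid())
        frames_b = [make_frame(f.positions, time=f.time, box_lengths=(5, 5, 5))
                    for f in frames[4:]]
        h2 = accumulate_density(Trajectory.from_frames(frames_b), sel, self.grid())
        combined = (h1.density * h1.n_frames + h2.density * h2.n_frames) / 8
        np.testing.assert_allclose(whole.density, combined, atol=1e-12)

    def test_alignment_before_binning(self):
        # rigidly rotated frames must land on the reference grid cells
        rng = np.random.default_rng(13)
        coords = rng.uniform(1, 4, (6, 3))
        ref = AlignmentReference(coords, Selection("all", np.arange(6)))
        frames = []
        for t in range(5):
            r = rand_rotation(rng)
            frames.append(make_frame(coords @ r.T + rng.uniform(-1, 1, 3),
                                     time=float(t) * 10.0, box_lengths=(5, 5, 5)))
        traj = Trajectory.from_frames(frames)
        grid = accumulate_density(traj, Selection("all", np.arange(6)),
                                  self.grid(spacing=0.25, n=20), ref=ref)
        unaligned = accumulate_density(traj, Selection("all", np.arange(6)),
                                       self.grid(spacing=0.25, n=20))
        # aligned accumulation concentrates mass on exactly 6 voxels
        assert np.count_nonzero(grid.counts >= 5) == 6
        assert np.count_nonzero(unaligned.counts >= 5) < 6

    def test_zero_frames_rejected(self):
        traj = Trajectory.from_frames([])
        with pytest.raises(ValueError, match="no frames"):
            accumulate_density(traj, Selection("p", np.array([0])), self.grid(),
                               interval=10.0)


class TestOpenDX:
    def make_grid(self, seed=0):
        rng = np.random.default_rng(seed)
        spec = GridSpec(origin=(-1.0, 0.5, 2.0), spacing=(0.1, 0.2, 0.3),
                        shape=(4, 5, 6))
        counts = rng.integers(0, 50, (4, 5, 6)).astype(float)
        return DensityGrid(spec=spec, counts=counts, n_frames=10)

    def test_round_trip_exact(self, tmp_path):
        grid = self.make_grid()
        path = tmp_path / "map.dx"
        write_dx(grid, path)
        origin, spacing, values = read_dx(path)
        np.testing.assert_array_equal(origin, grid.spec.origin)
        np.testing.assert_array_equal(spacing, grid.spec.spacing)
        np.testing.assert_array_equal(values, grid.density)

    def test_header_counts_match_shape(self, tmp_path):
        grid = self.make_grid()
        path = tmp_path / "map.dx"
        write_dx(grid, path)
        text = path.read_text()
        assert "counts 4 5 6" in text
        assert "items 120" in text

    def test_external_reader_parses(self, tmp_path):
        gridData = pytest.importorskip("gridData")
        grid = self.make_grid()
        path = tmp_path / "map.dx"
        write_dx(grid, path)
        g = gridData.Grid(str(path))
        np.testing.assert_allclose(g.grid, grid.density, rtol=1e-12)
        np.testing.assert_allclose(g.origin, grid.spec.origin, atol=1e-12)
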