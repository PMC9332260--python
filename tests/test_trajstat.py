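"""Trajectory statistics: superposition, RMSD/R_g/SASA, RMSF, MDDF, density maps."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from luxtherm.synthgen import TrajectoryModelParams, gen_solvated_frames, gen_trajectory, toy_chain
from luxtherm.trajstat import (
    Structure,
    Trajectory,
    delta_rmsf,
    kabsch_superpose,
    mddf,
    profile_correlation,
    radius_of_gyration,
    residue_density_map,
    rmsd_series,
    rmsf,
    sasa,
    tail_mean,
)


def brute_force_min_rmsd(moving, target):
    """Independent oracle: numerical minimization over rotation vectors."""
    mc, tc = moving.mean(axis=0), target.mean(axis=0)
    a, b = moving - mc, target - tc

    def cost(rotvec):
        rot = Rotation.from_rotvec(rotvec).as_matrix()
        return np.sqrt(((a @ rot.T - b) ** 2).sum(axis=1).mean())

    best = min(
        (minimize(cost, x0, method="Nelder-Mead",
                  options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000})
         for x0 in [np.zeros(3), np.array([1.0, 0.5, -0.5]), np.array([-2.0, 1.0, 2.0])]),
        key=lambda r: r.fun,
    )
    return best.fun


class TestKabsch:
    def test_identity_on_equal_sets(self, chain30):
        rot, trans, rmsd = kabsch_superpose(chain30.coords, chain30.coords)
        assert np.allclose(rot, np.eye(3), atol=1e-10)
        assert np.allclose(trans, 0.0, atol=1e-10)
        assert rmsd < 1e-12

    def test_exact_recovery_of_constructed_transform(self):
        pts = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        rot_true = np.array([[0.0, -1, 0], [1, 0, 0], [0, 0, 1]])  # 90 deg about z
        moved = pts @ rot_true.T + np.array([1.0, 2.0, 3.0])
        rot, trans, rmsd = kabsch_superpose(moved, pts)
        assert rmsd < 1e-12
        assert np.allclose(rot @ rot_true, np.eye(3), atol=1e-10)

    def test_agrees_with_numerical_optimizer_on_random_pairs(self, rng):
        for _ in range(5):
            moving = rng.normal(size=(5, 3))
            target = rng.normal(size=(5, 3))
            _, _, rmsd = kabsch_superpose(moving, target)
            assert rmsd == pytest.approx(brute_force_min_rmsd(moving, target), abs=1e-6)

    def test_proper_rotation_even_for_reflected_targets(self, rng):
        moving = rng.normal(size=(6, 3))
        target = moving * np.array([1.0, 1.0, -1.0])  # mirror image
        rot, _, _ = kabsch_superpose(moving, target)
        assert np.linalg.det(rot) == pytest.approx(1.0)

    def test_collinear_points_rejected(self):
        line = np.outer(np.arange(5.0), np.array([1.0, 0, 0]))
        with pytest.raises(ValueError):
            kabsch_superpose(line, line)

    def test_superposed_rmsd_never_exceeds_raw(self, rng):
        for _ in range(5):
            a = rng.normal(size=(8, 3))
            b = a + rng.normal(scale=0.3, size=(8, 3))
            _, _, fitted = kabsch_superpose(a, b)
            raw = np.sqrt(((a - b) ** 2).sum(axis=1).mean())
            assert fitted <= raw + 1e-12


class TestRmsdSeries:
    def test_rigid_motion_only_gives_zero(self, chain30):
        p = TrajectoryModelParams(reference=chain30, n_frames=10, rigid_motion=True, seed=1)
        assert rmsd_series(gen_trajectory(p), "CA").max() < 1e-9

    def test_single_displaced_atom_matches_oracle(self, chain30):
        frame = chain30.coords.copy()
        frame[7] += np.array([1.0, 0.0, 0.0])
        traj = Trajectory(reference=chain30, frames=frame[None])
        expected = brute_force_min_rmsd(frame, chain30.coords)
        assert rmsd_series(traj, "CA")[0] == pytest.approx(expected, abs=1e-6)

    def test_tail_mean_matches_full_mean_for_stationary_series(self, chain30):
        p = TrajectoryModelParams(
            reference=chain30, rmsf_targets=np.full(30, 1.0), n_frames=600, seed=3
        )
        series = rmsd_series(gen_trajectory(p), "CA")
        assert tail_mean(series, 0.1) == pytest.approx(series.mean(), rel=0.05)

    def test_empty_selection_rejected(self, chain30):
        traj = Trajectory(reference=chain30, frames=chain30.coords[None])
        with pytest.raises(ValueError):
            rmsd_series(traj, "CB")


class TestRadiusOfGyration:
    def test_two_unit_masses(self):
        assert radius_of_gyration(np.array([[1.0, 0, 0], [-1, 0, 0]]), np.ones(2)) == 1.0

    def test_single_atom(self):
        assert radius_of_gyration(np.array([[3.0, 2, 1]]), np.array([5.0])) == 0.0

    def test_cube_vertices(self):
        cube = np.array([[x, y, z] for x in (-1, 1) for y in (-1, 1) for z in (-1, 1)], float)
        assert radius_of_gyration(cube, np.ones(8)) == pytest.approx(np.sqrt(3.0))

    def test_zero_mass_rejected(self):
        with pytest.raises(ValueError):
            radius_of_gyration(np.zeros((2, 3)), np.zeros(2))


def dense_grid_sasa(coords, radii, probe, n=10_000, seed=0):
    """Independent oracle: random sphere sampling at high density."""
    rng = np.random.default_rng(seed)
    total = 0.0
    inflated = radii + probe
    for i in range(len(coords)):
        v = rng.normal(size=(n, 3))
        pts = coords[i] + inflated[i] * v / np.linalg.norm(v, axis=1)[:, None]
        exposed = np.ones(n, dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            exposed &= ((pts - coords[j]) ** 2).sum(axis=1) > inflated[j] ** 2
        total += exposed.mean() * 4 * np.pi * inflated[i] ** 2
    return total


class TestSasa:
    def atom_pair(self, separation):
        return Structure(
            name=np.array(["C1", "C2"]), element=np.array(["C", "C"]),
            res_id=np.array([1, 2]), res_name=np.array(["UNK", "UNK"]),
            chain_id=np.array(["A", "A"]),
            coords=np.array([[0.0, 0, 0], [separation, 0, 0]]),
            mass=np.array([12.0, 12.0]), radius=np.array([1.7, 1.7]),
        )

    def test_isolated_atom_closed_form(self):
        s = self.atom_pair(100.0)
        total, per_atom = sasa(s)
        single = 4 * np.pi * 3.1**2
        assert per_atom[0] == pytest.approx(single, rel=1e-12)
        assert total == pytest.approx(2 * single, rel=1e-12)

    def test_partial_overlap_matches_dense_oracle(self):
        s = self.atom_pair(3.0)
        total, _ = sasa(s, n_points=256)
        oracle = dense_grid_sasa(s.coords, s.radius, 1.4)
        assert total == pytest.approx(oracle, rel=0.02)

    def test_per_atom_values_bounded_and_sum_to_total(self, chain10):
        total, per_atom = sasa(chain10)
        assert total == pytest.approx(per_atom.sum())
        caps = 4 * np.pi * (chain10.radius + 1.4) ** 2
        assert np.all(per_atom >= 0) and np.all(per_atom <= caps + 1e-9)

    def test_translation_invariance(self, chain10):
        t0, _ = sasa(chain10)
        t1, _ = sasa(chain10, coords=chain10.coords + np.array([5.0, -3.0, 2.0]))
        assert t1 == pytest.approx(t0, rel=1e-12)

    def test_too_few_sphere_points_rejected(self, chain10):
        with pytest.raises(ValueError):
            sasa(chain10, n_points=16)


class TestRmsf:
    def test_static_trajectory_gives_zeros(self, chain30):
        p = TrajectoryModelParams(reference=chain30, n_frames=5, seed=0)
        assert rmsf(gen_trajectory(p), "CA").rmsf.max() < 1e-12

    def test_isotropic_displacement_chi_moment(self, chain30):
        # per-coordinate sd 0.5 A -> RMSF = 0.5*sqrt(3) ~ 0.866 A
        p = TrajectoryModelParams(
            reference=chain30, rmsf_targets=np.full(30, 0.5 * np.sqrt(3.0)),
            n_frames=2000, seed=7,
        )
        prof = rmsf(gen_trajectory(p), "CA")
        assert np.abs(prof.rmsf / (0.5 * np.sqrt(3.0)) - 1).mean() < 0.05

    def test_generator_targets_recovered_despite_rigid_motion(self):
        ref = toy_chain(100)
        targets = np.linspace(0.5, 3.0, 100)
        p = TrajectoryModelParams(
            reference=ref, rmsf_targets=targets, n_frames=2000,
            rigid_motion=True, box=400.0, seed=2,
        )
        prof = rmsf(gen_trajectory(p), "CA")
        rel_err = np.abs(prof.rmsf / targets - 1)
        assert rel_err.mean() < 0.05
        assert rel_err.max() < 0.10  # end-of-chain atoms carry the residual

    def test_two_frames_minimum(self, chain30):
        traj = Trajectory(reference=chain30, frames=chain30.coords[None])
        with pytest.raises(ValueError):
            rmsf(traj, "CA")


class TestDeltaRmsf:
    def make_profile(self, chain30, scale, seed):
        p = TrajectoryModelParams(
            reference=chain30, rmsf_targets=scale * np.linspace(0.5, 2.0, 30),
            n_frames=1500, seed=seed,
        )
        return rmsf(gen_trajectory(p), "CA")

    def test_identical_profiles_give_zero(self, chain30):
        prof = self.make_profile(chain30, 1.0, 11)
        delta = delta_rmsf(prof, prof)
        assert np.all(delta.rmsf == 0.0)

    def test_doubled_targets_shift_by_reference(self, chain30):
        ref_prof = self.make_profile(chain30, 1.0, 11)
        hot_prof = self.make_profile(chain30, 2.0, 12)
        delta = delta_rmsf(hot_prof, ref_prof)
        targets = np.linspace(0.5, 2.0, 30)
        assert np.abs(delta.rmsf - targets).mean() < 0.08

    def test_antisymmetry(self, chain30):
        a = self.make_profile(chain30, 1.0, 11)
        b = self.make_profile(chain30, 1.5, 13)
        assert np.allclose(delta_rmsf(a, b).rmsf, -delta_rmsf(b, a).rmsf)

    def test_mismatched_residues_rejected(self, chain30, chain10):
        a = self.make_profile(chain30, 1.0, 11)
        p = TrajectoryModelParams(reference=chain10, rmsf_targets=np.ones(10), n_frames=10, seed=0)
        b = rmsf(gen_trajectory(p), "CA")
        with pytest.raises(ValueError):
            delta_rmsf(a, b)


class TestProfileCorrelation:
    def prof(self, ids, values):
        from luxtherm.trajstat import FluctuationProfile

        return FluctuationProfile(residue_ids=np.asarray(ids), rmsf=np.asarray(values, float))

    def test_perfect_anticorrelation(self):
        assert profile_correlation(self.prof([1, 2, 3], [1, 2, 3]),
                                   self.prof([1, 2, 3], [3, 2, 1])) == pytest.approx(-1.0)

    def test_self_correlation(self):
        p = self.prof([1, 2, 3, 4], [0.3, 1.0, 0.2, 0.8])
        assert profile_correlation(p, p) == pytest.approx(1.0)

    def test_window_selects_residue_range(self):
        p = self.prof(range(1, 11), np.arange(10.0))
        q = self.prof(range(1, 11), np.r_[np.arange(5.0), -np.arange(5.0)])
        assert profile_correlation(p, q, window=(1, 5)) == pytest.approx(1.0)
        assert profile_correlation(p, q, window=(6, 10)) == pytest.approx(-1.0)

    def test_independent_profiles_mostly_uncorrelated(self):
        rng = np.random.default_rng(99)
        hits = 0
        n_rep = 1000
        for _ in range(n_rep):
            r = np.corrcoef(rng.normal(size=30), rng.normal(size=30))[0, 1]
            if abs(r) < 0.5:
                hits += 1
        assert hits / n_rep > 0.95

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            profile_correlation(self.prof([1, 2, 3], [1, 1, 1]),
                                self.prof([1, 2, 3], [1, 2, 3]))


def brute_force_mddf_counts(traj, edges):
    counts = np.zeros(edges.size - 1)
    for f in range(traj.n_frames):
        for mol in np.unique(traj.cosolvent_mol):
            d_min = np.inf
            for ca in traj.cosolvent[f][traj.cosolvent_mol == mol]:
                for sa in traj.frames[f]:
                    diff = ca - sa
                    if traj.box is not None:
                        diff = diff - traj.box * np.round(diff / traj.box)
                    d_min = min(d_min, float(np.linalg.norm(diff)))
            for b in range(edges.size - 1):
                if edges[b] <= d_min < edges[b + 1] or (
                    b == edges.size - 2 and d_min == edges[-1]
                ):
                    counts[b] += 1
    return counts


class TestMddf:
    def solvated(self, n_frames=200, count=100, enrichment=None, seed=3, box=80.0):
        p = TrajectoryModelParams(
            reference=toy_chain(10, spacing=8.0), n_frames=n_frames,
            cosolvent_count=count, enrichment=enrichment or {}, box=box, seed=seed,
        )
        return gen_solvated_frames(p)

    def test_uniform_cosolvent_normalizes_to_one(self):
        traj = self.solvated(n_frames=800)
        prof = mddf(traj, "all", bin_width=1.0, r_max=12.0, seed=9)
        far = prof.mddf[prof.r > 6.0]
        assert np.abs(far - 1.0).max() < 0.10

    def test_no_cosolvent_within_range_gives_zero_bins(self, chain10):
        cos = np.full((2, 3, 3), 200.0)
        traj = Trajectory(reference=chain10, frames=np.repeat(chain10.coords[None], 2, 0),
                          cosolvent=cos, box=500.0)
        prof = mddf(traj, "all", r_max=10.0, seed=0)
        assert prof.counts.sum() == 0
        assert np.all(prof.mddf == 0.0)

    def test_toy_histogram_matches_exhaustive_enumeration(self, chain10):
        rng = np.random.default_rng(5)
        frames = np.repeat(chain10.coords[None], 2, 0) + rng.normal(scale=0.1, size=(2, 10, 3))
        cos = rng.uniform(0, 40.0, size=(2, 6, 3))
        mol = np.array([0, 0, 1, 1, 2, 2])  # three 2-atom molecules
        traj = Trajectory(reference=chain10, frames=frames, cosolvent=cos,
                          cosolvent_mol=mol, box=90.0)
        prof = mddf(traj, "all", bin_width=1.0, r_max=40.0, seed=1)
        edges = np.arange(0.0, 40.5, 1.0)
        assert np.array_equal(prof.counts, brute_force_mddf_counts(traj, edges))

    def test_r_max_beyond_half_box_rejected(self):
        traj = self.solvated(n_frames=2, count=3)
        with pytest.raises(ValueError):
            mddf(traj, "all", r_max=60.0)

    def test_missing_cosolvent_rejected(self, chain10):
        traj = Trajectory(reference=chain10, frames=chain10.coords[None].repeat(2, 0))
        with pytest.raises(ValueError):
            mddf(traj, "all")


class TestResidueDensityMap:
    def test_no_cosolvent_gives_zero_matrix(self, chain10):
        traj = Trajectory(reference=chain10, frames=chain10.coords[None].repeat(2, 0))
        dens = residue_density_map(traj, np.arange(1, 11))
        assert dens.shape == (10, 8)
        assert np.all(dens == 0.0)

    def test_programmed_enrichment_recovered(self):
        p = TrajectoryModelParams(
            reference=toy_chain(10, spacing=8.0), n_frames=600,
            cosolvent_count=150, enrichment={5: 5.0}, box=80.0, seed=4,
        )
        dens = residue_density_map(gen_solvated_frames(p), np.arange(1, 11))
        totals = dens.sum(axis=1)
        ratio = totals[4] / np.median(np.delete(totals, 4))
        assert ratio == pytest.approx(5.0, rel=0.30)

    def test_probabilities_stable_under_frame_doubling(self):
        p = TrajectoryModelParams(
            reference=toy_chain(10, spacing=8.0), n_frames=300,
            cosolvent_count=120, enrichment={5: 4.0}, box=80.0, seed=6,
        )
        p2 = TrajectoryModelParams(
            reference=toy_chain(10, spacing=8.0), n_frames=600,
            cosolvent_count=120, enrichment={5: 4.0}, box=80.0, seed=6,
        )
        d1 = residue_density_map(gen_solvated_frames(p), np.array([5]))
        d2 = residue_density_map(gen_solvated_frames(p2), np.array([5]))
        assert d1.sum() == pytest.approx(d2.sum(), rel=0.25)

    def test_unknown_residue_rejected(self, chain10):
        traj = Trajectory(reference=chain10, frames=chain10.coords[None].repeat(2, 0))
        with pytest.raises(ValueError):
            residue_density_map(traj, np.array([99]))

    def test_empty_residue_list_rejected(self, chain10):
        traj = Trajectory(reference=chain10, frames=chain10.coords[None].repeat(2, 0))
        with pytest.raises(ValueError):
            residue_density_map(traj, np.array([], dtype=int))
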