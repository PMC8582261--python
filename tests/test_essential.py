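"""Covariance modes, GROMOS clustering, and the EDS accept/project driver."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import pathmetad as pm
from pathmetad.core import AtomSelection, Structure, Trajectory
from pathmetad.dynamics import ACCEL
from pathmetad.errors import InsufficientDataError, ParameterError
from pathmetad.essential import pairwise_fitted_rmsd, subspace_radial_correction


def _rigid_orthogonal_fields(base, n_fields, seed):
    """Mean-zero displacement fields orthogonal to rigid translations/rotations."""
    rng = np.random.default_rng(seed)
    m = base.shape[0]
    centred = base - base.mean(axis=0)
    generators = []
    for k in range(3):  # translations
        g = np.zeros((m, 3))
        g[:, k] = 1.0
        generators.append(g.ravel())
    for axis in np.eye(3):  # infinitesimal rotations about the centroid
        generators.append(np.cross(np.tile(axis, (m, 1)), centred).ravel())
    G = np.array(generators)
    fields = []
    for _ in range(n_fields):
        v = rng.normal(size=3 * m)
        for g in G:
            v -= (v @ g) / (g @ g) * g
        for f in fields:
            v -= (v @ f) * f
        v /= np.linalg.norm(v)
        fields.append(v)
    return [f.reshape(m, 3) for f in fields]


class TestCovarianceModes:
    def test_rigid_copies_have_zero_variance(self, small_structure):
        frames = []
        for i in range(6):
            R = Rotation.from_euler("xyz", [10 * i, 5 * i, -7 * i], degrees=True).as_matrix()
            frames.append(small_structure.with_coords(small_structure.coords @ R.T + i))
        sub = pm.covariance_modes(Trajectory(frames), pm.select_all(small_structure))
        assert sub.eigenvalues.max() <= 1e-10

    def test_two_constructed_modes_recovered(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(10, 3)) * 4
        v1, v2 = _rigid_orthogonal_fields(base, 2, seed=1)
        n = 256
        t = np.arange(n)
        # sinusoids over full periods: variances exactly 4 and 1 A^2
        a = 2.0 * np.sqrt(2.0) * np.sin(2 * np.pi * 8 * t / n)
        b = 1.0 * np.sqrt(2.0) * np.cos(2 * np.pi * 5 * t / n)
        coords = base[None] + a[:, None, None] * np.sqrt(10) * v1 + b[:, None, None] * np.sqrt(10) * v2
        # fields are unit-norm over 3M; scale so *per-structure* displacement
        # has total variance matching eigenvalues of the 3M covariance
        traj = Trajectory.from_coords(coords, Structure(base))
        sub = pm.covariance_modes(traj, pm.select_all(Structure(base)))
        assert sub.eigenvalues[0] == pytest.approx(4.0 * 10, rel=0.05)
        assert sub.eigenvalues[1] == pytest.approx(1.0 * 10, rel=0.05)
        # residual modes only pick up second-order fitting-induced mixing
        assert sub.eigenvalues[2:].max() < 1e-3 * sub.eigenvalues[0]

    def test_eigenvalue_sum_matches_independent_fluctuation_variance(self, two_state):
        traj = pm.make_interpolated_trajectory(two_state.state_a, two_state.state_b,
                                               12, noise_sigma=0.3, seed=2)
        sel = pm.select_all(two_state.state_a)
        sub = pm.covariance_modes(traj, sel)
        # independent route: scipy alignment of every frame onto the returned mean
        total = 0.0
        mean = sub.mean
        for fr in traj.coords:
            rot, _ = Rotation.align_vectors(mean - mean.mean(axis=0),
                                            fr - fr.mean(axis=0))
            aligned = (fr - fr.mean(axis=0)) @ rot.as_matrix().T + mean.mean(axis=0)
            total += ((aligned - mean) ** 2).sum()
        total /= len(traj)
        assert sub.eigenvalues.sum() == pytest.approx(total, rel=1e-6)

    def test_cumulative_variance_reaches_one(self, two_state):
        traj = pm.make_interpolated_trajectory(two_state.state_a, two_state.state_b,
                                               8, noise_sigma=0.2, seed=3)
        sub = pm.covariance_modes(traj, pm.select_all(two_state.state_a))
        assert sub.cumulative_variance()[-1] == pytest.approx(1.0, abs=1e-12)

    def test_single_frame_rejected(self, small_structure):
        with pytest.raises(InsufficientDataError):
            pm.covariance_modes(Trajectory([small_structure]), pm.select_all(small_structure))

    def test_orthonormal_eigenvectors(self, two_state):
        traj = pm.make_interpolated_trajectory(two_state.state_a, two_state.state_b,
                                               10, noise_sigma=0.25, seed=4)
        sub = pm.covariance_modes(traj, pm.select_all(two_state.state_a))
        G = sub.eigenvectors @ sub.eigenvectors.T
        assert np.allclose(G, np.eye(len(G)), atol=1e-8)


def brute_force_gromos(dist, cutoff):
    """Independent Daura clustering from a distance matrix (test oracle)."""
    n = len(dist)
    adj = dist <= cutoff
    np.fill_diagonal(adj, True)
    remaining = set(range(n))
    assignments = {}
    centroids = []
    cluster = 0
    while remaining:
        counts = {i: sum(1 for j in remaining if adj[i, j]) for i in remaining}
        best = max(sorted(remaining), key=lambda i: (counts[i], -i))
        members = [j for j in sorted(remaining) if adj[best, j]]
        for j in members:
            assignments[j] = cluster
            remaining.discard(j)
        centroids.append(best)
        cluster += 1
    return assignments, centroids


def random_clustered_trajectory(seed, n_frames=40, n_atoms=6):
    rng = np.random.default_rng(seed)
    centers = rng.normal(size=(3, n_atoms, 3)) * 5
    coords = np.array([
        centers[rng.integers(3)] + rng.normal(size=(n_atoms, 3)) * 0.4
        for _ in range(n_frames)
    ])
    return Trajectory.from_coords(coords, Structure(coords[0]))


class TestClusterGromos:
    def test_identical_frames_one_cluster(self, small_structure):
        traj = Trajectory([small_structure] * 5)
        res = pm.cluster_gromos(traj, pm.select_all(small_structure), cutoff=0.15)
        assert res.n_clusters == 1
        assert set(res.assignments) == {0}

    def test_zero_cutoff_all_singletons(self):
        rng = np.random.default_rng(1)
        coords = rng.normal(size=(6, 5, 3)) * 3
        traj = Trajectory.from_coords(coords, Structure(coords[0]))
        res = pm.cluster_gromos(traj, pm.select_all(traj.template), cutoff=0.0)
        assert res.n_clusters == 6

    def test_two_separated_bundles(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(5, 3)) * 3
        b = rng.normal(size=(5, 3)) * 3  # independent shape: far in fitted RMSD
        coords = np.array([a + rng.normal(size=(5, 3)) * 0.1 for _ in range(7)]
                          + [b + rng.normal(size=(5, 3)) * 0.1 for _ in range(5)])
        traj = Trajectory.from_coords(coords, Structure(a))
        res = pm.cluster_gromos(traj, pm.select_all(traj.template), cutoff=0.15)
        assert res.n_clusters == 2
        assert len(set(res.assignments[:7])) == 1
        assert len(set(res.assignments[7:])) == 1

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force(self, seed):
        traj = random_clustered_trajectory(seed)
        sel = pm.select_all(traj.template)
        res = pm.cluster_gromos(traj, sel, cutoff=0.15)
        dist = pairwise_fitted_rmsd(traj.coords)
        ref_assign, ref_centroids = brute_force_gromos(dist, 1.5)
        assert res.centroids == ref_centroids
        assert all(res.assignments[i] == ref_assign[i] for i in range(len(traj)))

    def test_centroid_membership_and_cover(self):
        traj = random_clustered_trajectory(99)
        res = pm.cluster_gromos(traj, pm.select_all(traj.template), cutoff=0.15)
        assert (res.assignments >= 0).all()
        for c, frame in enumerate(res.centroids):
            assert res.assignments[frame] == c


def _harmonic_provider(target, k=2.0):
    def f(x):
        d = x - target
        return 0.5 * k * (d * d).sum(), -k * d
    return f


class TestEDS:
    def _subspace(self, structure, seed=0):
        rng = np.random.default_rng(seed)
        coords = structure.coords[None] + rng.normal(size=(30, structure.n_atoms, 3)) * 0.5
        traj = Trajectory.from_coords(coords, structure)
        return pm.covariance_modes(traj, pm.select_all(structure))

    def test_radial_correction_restores_subspace_distance(self, small_structure):
        sub = self._subspace(small_structure)
        target = small_structure.coords + 2.0
        rng = np.random.default_rng(5)
        current = small_structure.coords + rng.normal(size=small_structure.coords.shape)
        trial = current + rng.normal(size=current.shape) * 0.5
        k = 8
        c_t = sub.project(target, k)
        r_cur = np.linalg.norm(sub.project(current, k) - c_t)
        corrected = subspace_radial_correction(trial, current, target, sub, k)
        r_corr = np.linalg.norm(sub.project(corrected, k) - c_t)
        r_tri = np.linalg.norm(sub.project(trial, k) - c_t)
        if r_tri > r_cur:
            assert r_corr == pytest.approx(r_cur, abs=1e-8)
        else:
            assert np.allclose(corrected, trial)

    def test_accepting_step_returned_unchanged(self, small_structure):
        # strong pull toward target at T=0: the trial strictly decreases RMSD
        # (the target must differ non-rigidly, or fitted RMSD is already zero)
        sub = self._subspace(small_structure)
        target = small_structure.with_coords(small_structure.coords * 0.8)
        params = pm.EDSParams(subspace_size=5, selection=pm.select_all(small_structure),
                              temperature=1e-12, seed=0)
        rng = np.random.default_rng(0)
        v = np.zeros_like(small_structure.coords)
        nxt, v2, accepted, _ = pm.eds_step(
            small_structure, v, sub, target,
            _harmonic_provider(target.coords, k=5.0), params, rng)
        assert accepted
        r0, _ = pm.displacement_metrics(small_structure, target,
                                        pm.select_all(small_structure), fit=True)
        r1, _ = pm.displacement_metrics(nxt, target, pm.select_all(small_structure), fit=True)
        assert r1 < r0

    def test_run_from_target_stays_there(self, small_structure):
        sub = self._subspace(small_structure)
        params = pm.EDSParams(subspace_size=5, selection=pm.select_all(small_structure), seed=1)
        traj = pm.run_eds(small_structure, small_structure, sub, 50,
                          _harmonic_provider(small_structure.coords), params)
        assert traj.rmsd_to_target.max() <= 1e-9

    def test_zero_steps(self, small_structure):
        sub = self._subspace(small_structure)
        params = pm.EDSParams(subspace_size=5, selection=pm.select_all(small_structure), seed=1)
        traj = pm.run_eds(small_structure, small_structure, sub, 0,
                          _harmonic_provider(small_structure.coords), params)
        assert len(traj) == 1
        with pytest.raises(ParameterError):
            pm.run_eds(small_structure, small_structure, sub, -1,
                       _harmonic_provider(small_structure.coords), params)

    def test_deterministic_with_seed(self, small_structure):
        sub = self._subspace(small_structure)
        target = small_structure.with_coords(small_structure.coords + 1.0)
        params = pm.EDSParams(subspace_size=5, selection=pm.select_all(small_structure), seed=42)
        f = _harmonic_provider(target.coords)
        t1 = pm.run_eds(small_structure, target, sub, 100, f, params)
        t2 = pm.run_eds(small_structure, target, sub, 100, f, params)
        assert np.array_equal(t1.coords, t2.coords)

    def test_monotone_rmsd_on_harmonic_fixture(self, small_structure):
        sub = self._subspace(small_structure)
        target = small_structure.with_coords(small_structure.coords * 0.8 + 2.0)
        params = pm.EDSParams(subspace_size=10, selection=pm.select_all(small_structure), seed=7)
        traj = pm.run_eds(small_structure, target, sub, 500,
                          _harmonic_provider(target.coords, k=1.0), params)
        assert np.all(np.diff(traj.rmsd_to_target) <= 1e-6)

    def test_overdamped_relaxation_rate(self, small_structure):
        """With a harmonic pull to the target, RMSD decays at the Langevin rate."""
        k, m, gamma = 1.0, 12.0, 20.0
        sub = self._subspace(small_structure)
        start = small_structure.with_coords(small_structure.coords + 4.0 * np.eye(3)[0]
                                            * np.linspace(0, 1, small_structure.n_atoms)[:, None])
        target = small_structure
        params = pm.EDSParams(subspace_size=10, selection=pm.select_all(small_structure),
                              step_size=0.01, temperature=1e-9, friction=gamma,
                              mass=m, seed=3)
        n = 3000
        traj = pm.run_eds(start, target, sub, n, _harmonic_provider(target.coords, k), params)
        r = traj.rmsd_to_target
        tau = m * gamma / (ACCEL * k)  # overdamped relaxation time, ps
        t = np.arange(n + 1) * params.step_size
        expected = r[0] * np.exp(-t / tau)
        window = t < 2 * tau
        assert np.allclose(r[window], expected[window], rtol=0.25)

    def test_subspace_io_roundtrip(self, small_structure, tmp_path):
        sub = self._subspace(small_structure)
        p = tmp_path / "sub.txt"
        pm.save_subspace(str(p), sub)
        back = pm.load_subspace(str(p))
        assert np.allclose(back.mean, sub.mean, atol=1e-8)
        assert np.allclose(back.eigenvalues, sub.eigenvalues, atol=1e-8)
        assert np.allclose(back.eigenvectors, sub.eigenvectors, atol=1e-8)
        assert np.array_equal(back.selection.indices, sub.selection.indices)
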