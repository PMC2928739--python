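import numpy as np
import pytest

from ensembledyn import (
    Basin,
    SelectionMask,
    SyntheticSpec,
    basin_centers,
    cluster_conformations,
    generate_multibasin_ensemble,
    helix_reference,
    joined_ensemble_analysis,
    pca_fit,
    pca_project,
    representative_structures,
)

from conftest import trajectory_from_frames


def three_basin_spec(seed=30, n_frames=1000, weights=(0.5, 0.15, 0.35)):
    return SyntheticSpec(
        chains=[("A", 20)],
        n_frames=n_frames,
        seed=seed,
        basins=[
            Basin(offset=0.0, spread=0.3, weight=weights[0]),
            Basin(offset=5.0, spread=0.3, weight=weights[1]),
            Basin(offset=7.0, spread=0.3, weight=weights[2]),
        ],
    )


class TestClustering:
    def test_identical_frames_form_one_full_cluster(self):
        ref = helix_reference([("A", 10)])
        traj = trajectory_from_frames(np.repeat(ref[None], 8, axis=0))
        model = cluster_conformations(traj, ref, radius=1.7)
        assert model.n_clusters == 1
        assert model.occupancy.iloc[0, 0] == pytest.approx(100.0)

    def test_planted_occupancies_recovered(self):
        spec = three_basin_spec()
        (traj,) = generate_multibasin_ensemble(spec)
        model = cluster_conformations(traj, helix_reference(spec.chains), radius=1.7)
        assert model.n_clusters == 3
        got = np.sort(model.occupancy.iloc[0].to_numpy())
        assert np.abs(got - np.sort([50.0, 15.0, 35.0])).max() < 3.0

    def test_cluster_count_nonincreasing_in_radius(self):
        spec = three_basin_spec(seed=31)
        (traj,) = generate_multibasin_ensemble(spec)
        ref = helix_reference(spec.chains)
        counts = [
            cluster_conformations(traj, ref, radius=r).n_clusters
            for r in (1.5, 1.7, 2.0, 10.0)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        assert counts[-1] == 1

    def test_assignment_is_nearest_centroid(self):
        spec = three_basin_spec(seed=32, n_frames=300)
        (traj,) = generate_multibasin_ensemble(spec)
        model = cluster_conformations(traj, helix_reference(spec.chains), radius=1.7)
        frames = model._frames[0]
        d = np.stack(
            [
                np.sqrt(np.mean(np.sum((frames - c) ** 2, axis=2), axis=1))
                for c in model.centroids
            ]
        )
        assert np.array_equal(model.assignments[0], np.argmin(d, axis=0))

    def test_objective_nonincreasing_over_iterations(self):
        spec = three_basin_spec(seed=33, n_frames=400)
        (traj,) = generate_multibasin_ensemble(spec)
        model = cluster_conformations(traj, helix_reference(spec.chains), radius=1.7)
        obj = model.objective_path
        assert all(a >= b - 1e-9 for a, b in zip(obj, obj[1:]))

    def test_reproducible_given_inputs_and_seed(self):
        spec = three_basin_spec(seed=34, n_frames=300)
        (traj,) = generate_multibasin_ensemble(spec)
        ref = helix_reference(spec.chains)
        m1 = cluster_conformations(traj, ref, radius=1.7, seed=5, shuffle_seeding=True)
        m2 = cluster_conformations(traj, ref, radius=1.7, seed=5, shuffle_seeding=True)
        assert np.array_equal(m1.centroids, m2.centroids)
        assert np.array_equal(m1.assignments[0], m2.assignments[0])

    def test_invalid_radius_rejected(self):
        ref = helix_reference([("A", 5)])
        traj = trajectory_from_frames(np.repeat(ref[None], 3, axis=0))
        with pytest.raises(ValueError, match="radius"):
            cluster_conformations(traj, ref, radius=-1.0)


class TestJoinedEnsemble:
    def test_identical_ensembles_get_identical_rows(self):
        spec = three_basin_spec(seed=35, n_frames=300)
        (traj,) = generate_multibasin_ensemble(spec)
        ref = helix_reference(spec.chains)
        model, timelines = joined_ensemble_analysis(traj, traj, ref, radius=1.7)
        occ = model.occupancy
        assert np.allclose(occ.iloc[0], occ.iloc[1])
        assert all(np.isclose(occ.sum(axis=1), 100.0, atol=1e-6))
        assert len(timelines) == 2
        assert len(timelines[0]) == traj.n_frames

    def test_confined_versus_spread_ensembles(self):
        """One ensemble confined to basin 1, the other spread 50/15/35: the
        occupancy rows show the confinement, the shape of a restricted
        conformational space."""
        spec = three_basin_spec(seed=36, n_frames=1000)
        confined, spread = generate_multibasin_ensemble(
            spec, weights_per_trajectory=[[1.0, 0.0, 0.0], [0.5, 0.15, 0.35]]
        )
        ref = helix_reference(spec.chains)
        model, _ = joined_ensemble_analysis(confined, spread, ref, radius=1.7)
        occ = model.occupancy.to_numpy()
        assert occ[0].max() == pytest.approx(100.0, abs=1e-9)
        row_b = np.sort(occ[1])
        assert np.abs(row_b - np.sort([50.0, 15.0, 35.0])).max() < 3.0

    def test_disjoint_ensembles_share_no_cluster(self):
        spec = three_basin_spec(seed=37, n_frames=400)
        a, b = generate_multibasin_ensemble(
            spec, weights_per_trajectory=[[1.0, 0.0, 0.0], [0.0, 0.4, 0.6]]
        )
        ref = helix_reference(spec.chains)
        model, _ = joined_ensemble_analysis(a, b, ref, radius=1.7)
        occ = model.occupancy.to_numpy()
        shared = (occ[0] > 0) & (occ[1] > 0)
        assert not shared.any()


class TestRepresentativeStructures:
    def test_single_frame_cluster_is_its_own_medoid(self):
        ref = helix_reference([("A", 8)])
        traj = trajectory_from_frames(ref[None])
        model = cluster_conformations(traj, ref, radius=1.0)
        reps = representative_structures(model)
        assert reps[0]["frame"] == 0
        assert np.allclose(reps[0]["coordinates"], model._frames[0][0])

    def test_equidistant_tie_breaks_to_earliest_frame(self):
        ref = helix_reference([("A", 6)])
        off = np.zeros_like(ref)
        off[0] = [0.5, 0.0, 0.0]
        frames = np.stack([ref + off, ref - off])  # equidistant from mean
        traj = trajectory_from_frames(frames)
        static = SelectionMask(traj.topology, range(1, 6))  # identity alignment
        model = cluster_conformations(traj, ref, fit_mask=static, radius=5.0)
        reps = representative_structures(model)
        assert model.n_clusters == 1
        assert reps[0]["frame"] == 0

    def test_medoids_close_to_planted_basin_centers(self):
        spec = three_basin_spec(seed=38, n_frames=600)
        (traj,) = generate_multibasin_ensemble(spec)
        centers = basin_centers(spec)
        ref = helix_reference(spec.chains)
        model = cluster_conformations(traj, ref, radius=1.7)
        reps = representative_structures(model)
        from ensembledyn import kabsch_superpose

        # compare in the analysis frame: centers aligned the same way as frames
        aligned_centers = [kabsch_superpose(c, ref).apply(c) for c in centers]
        for rep in reps.values():
            d = [
                np.sqrt(np.mean(np.sum((rep["coordinates"] - c) ** 2, axis=1)))
                for c in aligned_centers
            ]
            assert min(d) < 3 * 0.3 * np.sqrt(3)  # within the basin spread


class TestPCA:
    def test_rank_one_data_gives_single_component(self):
        ref = helix_reference([("A", 10)])
        direction = np.zeros((10, 3))
        direction[4] = [1.0, 0.0, 0.0]
        amplitudes = np.linspace(-1, 1, 20)
        frames = ref[None] + amplitudes[:, None, None] * direction[None]
        traj = trajectory_from_frames(frames)
        model = pca_fit(traj, ref, fit_mask=SelectionMask(traj.topology, range(3)))
        assert model.proportions[0] == pytest.approx(1.0, abs=1e-9)
        unit = direction.ravel() / np.linalg.norm(direction)
        assert abs(np.dot(model.components[0], unit)) > 0.999

    def test_planted_two_mode_variances_recovered(self):
        """Two orthogonal planted modes with variances 4 and 1 give variance
        proportions 0.8 / 0.2 within 0.03 at 2000 frames."""
        ref = helix_reference([("A", 12)])
        rng = np.random.default_rng(39)
        # modes vanish on the first 3 residues so the fit anchor is static
        m1 = rng.standard_normal((12, 3))
        m1[:3] = 0.0
        m1 /= np.linalg.norm(m1)
        m2 = rng.standard_normal((12, 3))
        m2[:3] = 0.0
        m2 -= np.sum(m2 * m1) * m1
        m2 /= np.linalg.norm(m2)
        amps = rng.standard_normal((2000, 2)) * [2.0, 1.0]
        frames = ref[None] + amps[:, 0, None, None] * m1 + amps[:, 1, None, None] * m2
        traj = trajectory_from_frames(frames)
        model = pca_fit(traj, ref, fit_mask=SelectionMask(traj.topology, range(3)))
        assert abs(model.proportions[0] - 0.8) < 0.03
        assert abs(model.proportions[1] - 0.2) < 0.03

    def test_eigenvalue_sum_equals_total_variance(self):
        """Trace identity, against a direct covariance computation."""
        spec = SyntheticSpec(chains=[("A", 9)], n_frames=150, seed=40, variance=0.2)
        from ensembledyn import generate_gaussian_trajectory

        traj = generate_gaussian_trajectory(spec)
        ref = helix_reference(spec.chains)
        model = pca_fit(traj, ref)
        from ensembledyn.superpose import align_trajectory

        flat = align_trajectory(traj, ref).coordinates.reshape(traj.n_frames, -1)
        total = np.var(flat, axis=0, ddof=1).sum()
        assert model.eigenvalues.sum() == pytest.approx(total, abs=1e-8)
        # independent eigendecomposition oracle for the spectrum
        cov = np.cov(flat.T, ddof=1)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        assert np.allclose(model.eigenvalues, eig[: len(model.eigenvalues)], atol=1e-8)

    def test_model_invariants(self):
        spec = SyntheticSpec(chains=[("A", 7)], n_frames=60, seed=41, variance=0.3)
        from ensembledyn import generate_gaussian_trajectory

        traj = generate_gaussian_trajectory(spec)
        model = pca_fit(traj, helix_reference(spec.chains))
        ev = model.eigenvalues
        assert np.all(ev >= -1e-12)
        assert np.all(np.diff(ev) <= 1e-9)
        assert model.proportions.sum() == pytest.approx(1.0, abs=1e-9)
        gram = model.components @ model.components.T
        assert np.abs(gram - np.eye(gram.shape[0])).max() < 1e-8

    def test_full_projection_reconstructs_centered_coordinates(self):
        spec = SyntheticSpec(chains=[("A", 6)], n_frames=50, seed=42, variance=0.2)
        from ensembledyn import generate_gaussian_trajectory

        traj = generate_gaussian_trajectory(spec)
        ref = helix_reference(spec.chains)
        model = pca_fit(traj, ref)
        proj = pca_project(traj, model)
        recon = proj @ model.components
        from ensembledyn.superpose import align_trajectory

        centered = align_trajectory(traj, ref).coordinates.reshape(
            traj.n_frames, -1
        ) - model.mean.ravel()
        assert np.abs(recon - centered).max() < 1e-8

    def test_mean_conformation_projects_to_origin(self):
        spec = SyntheticSpec(chains=[("A", 6)], n_frames=40, seed=43, variance=0.2)
        from ensembledyn import generate_gaussian_trajectory

        traj = generate_gaussian_trajectory(spec)
        ref = helix_reference(spec.chains)
        model = pca_fit(traj, ref)
        mean_traj = trajectory_from_frames(model.mean[None])
        # the mean frame is already in the aligned frame of reference
        proj = pca_project(mean_traj, model)
        assert np.abs(proj).max() < 1e-6

    def test_component_index_out_of_range(self):
        spec = SyntheticSpec(chains=[("A", 5)], n_frames=20, seed=44)
        from ensembledyn import generate_gaussian_trajectory

        traj = generate_gaussian_trajectory(spec)
        model = pca_fit(traj, helix_reference(spec.chains))
        with pytest.raises(IndexError):
            pca_project(traj, model, components=[99])

    def test_two_basins_separate_in_pc_plane(self):
        spec = SyntheticSpec(
            chains=[("A", 15)], n_frames=800, seed=45,
            basins=[Basin(0.0, 0.3, 0.5), Basin(6.0, 0.3, 0.5)],
        )
        (traj,) = generate_multibasin_ensemble(spec)
        ref = helix_reference(spec.chains)
        model = pca_fit(traj, ref)
        proj = pca_project(traj, model, components=[0])
        # PC1 separation between the two point clouds matches the planted
        # center separation (6 A of coordinate RMSD = 6*sqrt(N) in 3N space)
        one_d = np.sort(proj[:, 0])
        gap_centers = abs(one_d[: len(one_d) // 3].mean() - one_d[-len(one_d) // 3 :].mean())
        planted = 6.0 * np.sqrt(15)
        assert gap_centers == pytest.approx(planted, rel=0.15)
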