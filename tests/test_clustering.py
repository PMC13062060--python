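"""GROMOS clustering against an independent brute-force implementation."""

import numpy as np
import pytest

from rcvkit.clustering import cluster_report, gromos_cluster, pairwise_rmsd_matrix
from rcvkit.superpose import kabsch_fit
from rcvkit.synthetic import StateMixtureSpec, StateSpec, make_state_mixture_trajectory
from rcvkit.trajectory import Trajectory, resolve_selection


def brute_force_gromos(matrix, cutoff):
    """Reference implementation with explicit python loops.

    Repeatedly pick the remaining frame with the most remaining neighbours
    (distance < cutoff, self included; ties to the lowest index), extract it
    and its neighbours as a cluster, relabel by descending population.
    """
    n = len(matrix)
    remaining = set(range(n))
    clusters = []
    while remaining:
        best_count, best_frame = -1, None
        for i in sorted(remaining):
            count = sum(1 for j in remaining if i == j or matrix[i][j] < cutoff)
            if count > best_count:
                best_count, best_frame = count, i
        members = {j for j in remaining if best_frame == j or matrix[best_frame][j] < cutoff}
        clusters.append((best_frame, members))
        remaining -= members
    clusters.sort(key=lambda c: -len(c[1]))  # python sort is stable
    assignments = [None] * n
    for cid, (_center, members) in enumerate(clusters):
        for j in members:
            assignments[j] = cid
    return assignments, [c[0] for c in clusters], [len(c[1]) for c in clusters]


def random_distance_matrix(rng, n):
    m = rng.uniform(0.0, 5.0, size=(n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return m


class TestGromosCluster:
    def test_all_close_one_cluster(self):
        m = np.full((4, 4), 0.5)
        np.fill_diagonal(m, 0.0)
        res = gromos_cluster(m, cutoff=1.0)
        assert res.n_clusters == 1
        assert res.populations.tolist() == [4]

    def test_all_far_singletons(self):
        m = np.full((5, 5), 9.0)
        np.fill_diagonal(m, 0.0)
        res = gromos_cluster(m, cutoff=1.0)
        assert res.n_clusters == 5
        assert res.populations.tolist() == [1] * 5

    def test_two_blob_fixture_matches_brute_force(self):
        # frames 0-2 mutually close, frames 3-5 mutually close, blobs far apart
        m = np.full((6, 6), 8.0)
        for blob in ([0, 1, 2], [3, 4, 5]):
            for i in blob:
                for j in blob:
                    m[i, j] = 0.4 if i != j else 0.0
        res = gromos_cluster(m, cutoff=1.0)
        exp_assign, exp_centers, exp_pops = brute_force_gromos(m.tolist(), 1.0)
        assert res.assignments.tolist() == exp_assign
        assert res.populations.tolist() == exp_pops
        assert res.centroid_frames.tolist() == exp_centers

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 21))
        m = random_distance_matrix(rng, n)
        cutoff = float(rng.uniform(0.5, 4.0))
        res = gromos_cluster(m, cutoff)
        exp_assign, exp_centers, exp_pops = brute_force_gromos(m.tolist(), cutoff)
        assert res.assignments.tolist() == exp_assign
        assert res.centroid_frames.tolist() == exp_centers
        assert res.populations.sum() == n

    def test_cutoff_monotonicity(self):
        rng = np.random.default_rng(99)
        m = random_distance_matrix(rng, 15)
        counts = [gromos_cluster(m, c).n_clusters for c in (0.5, 1.0, 2.0, 4.0, 6.0)]
        assert counts == sorted(counts, reverse=True)

    def test_deterministic_on_ties(self):
        m = np.array([[0.0, 0.5, 9.0], [0.5, 0.0, 9.0], [9.0, 9.0, 0.0]])
        a = gromos_cluster(m, 1.0)
        b = gromos_cluster(m, 1.0)
        assert a.assignments.tolist() == b.assignments.tolist()
        assert a.centroid_frames[0] == 0  # lowest index wins the 0/1 tie

    def test_nan_rejected(self):
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            gromos_cluster(m, 1.0)


class TestPairwiseRMSDMatrix:
    def test_identical_frames_zero(self, dimer):
        _, topo, ref, sels = dimer
        traj = Trajectory(topo, np.repeat(ref.frames, 2, axis=0))
        m = pairwise_rmsd_matrix(traj, sels["lid"])
        np.testing.assert_allclose(m, 0.0, atol=1e-12)

    def test_translation_zero_in_pairwise_fit_mode(self, dimer):
        _, topo, ref, sels = dimer
        frames = np.concatenate([ref.frames, ref.frames + 5.0])
        traj = Trajectory(topo, frames)
        m = pairwise_rmsd_matrix(traj, sels["lid"], align_mode="pairwise_fit")
        assert m[0, 1] == pytest.approx(0.0, abs=1e-10)

    def test_prealigned_matches_per_pair_oracle(self, dimer, rng):
        _, topo, ref, sels = dimer
        frames = ref.frames + rng.normal(scale=0.5, size=(5,) + ref.frames.shape[1:])
        traj = Trajectory(topo, frames)
        idx = resolve_selection(topo, sels["lid"])
        m = pairwise_rmsd_matrix(traj, sels["lid"], align_mode="prealigned")
        for i in range(5):
            for j in range(5):
                expected = np.sqrt(np.mean(np.sum((frames[i, idx] - frames[j, idx]) ** 2, axis=1)))
                assert m[i, j] == pytest.approx(expected, abs=1e-10)

    def test_pairwise_fit_matches_kabsch_oracle(self, dimer, rng):
        _, topo, ref, sels = dimer
        frames = ref.frames + rng.normal(scale=0.4, size=(4,) + ref.frames.shape[1:])
        traj = Trajectory(topo, frames)
        idx = resolve_selection(topo, sels["rim"])
        m = pairwise_rmsd_matrix(traj, sels["rim"], align_mode="pairwise_fit")
        for i in range(4):
            for j in range(i + 1, 4):
                _, _, expected = kabsch_fit(frames[j, idx], frames[i, idx])
                assert m[i, j] == pytest.approx(expected, abs=1e-10)


class TestClusterReport:
    def test_fractions(self):
        m = np.full((4, 4), 9.0)
        np.fill_diagonal(m, 0.0)
        df = cluster_report(gromos_cluster(m, 1.0))
        np.testing.assert_allclose(df["fraction"], 0.25)

        m2 = np.zeros((4, 4))
        df2 = cluster_report(gromos_cluster(m2 + 0.1 - np.diag([0.1] * 4), 1.0))
        assert df2["fraction"].tolist() == [1.0]

    def test_two_state_populations_match_weights(self, dimer):
        _, topo, ref, sels = dimer
        spec = StateMixtureSpec(
            states=(
                StateSpec(offsets=(), weight=0.7),
                StateSpec(offsets=(("lid", (0.0, 0.0, 4.0)),), weight=0.3),
            ),
            noise_sigma=0.05,
            n_frames=300,
            seed=11,
        )
        traj, labels, _ = make_state_mixture_trajectory(topo, ref, spec, sels)
        m = pairwise_rmsd_matrix(traj, sels["lid"])
        res = gromos_cluster(m, cutoff=1.8)
        assert res.n_clusters == 2
        # multinomial 3-sigma band around the 0.7/0.3 ground truth
        frac = res.populations[0] / 300
        assert abs(frac - 0.7) < 3 * np.sqrt(0.7 * 0.3 / 300)
        # cluster assignment agrees with true state labels up to relabelling
        majority = np.array([np.bincount(res.assignments[labels == k]).argmax() for k in (0, 1)])
        assert majority[0] != majority[1]

    def test_centroid_pdbs_written(self, dimer, tmp_path):
        _, topo, ref, sels = dimer
        traj = Trajectory(topo, np.repeat(ref.frames, 3, axis=0))
        m = pairwise_rmsd_matrix(traj, sels["lid"])
        res = gromos_cluster(m, 1.0, component_name="lid")
        cluster_report(res, traj, output_dir=tmp_path)
        assert (tmp_path / "centroid_lid_0.pdb").exists()
        assert (tmp_path / "clusters_lid.csv").exists()
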