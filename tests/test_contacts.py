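"""Contact maps, differential maps, and Shrake-Rupley SASA."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from rcvkit.contacts import (
    SASASeries,
    contact_map,
    differential_contact_map,
    sasa_histogram,
    sasa_shrake_rupley,
)
from rcvkit.trajectory import Atom, Topology, Trajectory


def _linear_system(residue_positions, n_frames=1):
    """One CA atom per residue at the given positions, chain A."""
    atoms = [Atom(i, "CA", "C", "GLY", i + 1, "A") for i in range(len(residue_positions))]
    frames = np.tile(np.asarray(residue_positions, dtype=float)[None], (n_frames, 1, 1))
    return Trajectory(Topology(atoms), frames)


class TestContactMap:
    def test_permanent_contact_frequency_one(self):
        traj = _linear_system([(0, 0, 0), (3, 0, 0)], n_frames=4)
        m = contact_map(traj, cutoff=4.5)
        assert m.values[0, 1] == 1.0

    def test_far_apart_zero(self):
        traj = _linear_system([(0, 0, 0), (20, 0, 0)], n_frames=4)
        assert contact_map(traj, cutoff=4.5).values[0, 1] == 0.0

    def test_matches_brute_force_scan(self, rng):
        # 4 residues x 3 frames against an exhaustive all-pairs distance scan
        frames = rng.uniform(0, 8, size=(3, 4, 3))
        atoms = [Atom(i, "CA", "C", "GLY", i + 1, "A") for i in range(4)]
        traj = Trajectory(Topology(atoms), frames)
        m = contact_map(traj, cutoff=4.5)
        for i in range(4):
            for j in range(4):
                if i == j:
                    assert m.values[i, j] == 1.0
                    continue
                expected = np.mean(
                    [np.linalg.norm(frames[f, i] - frames[f, j]) < 4.5 for f in range(3)]
                )
                assert m.values[i, j] == pytest.approx(expected)

    def test_invariant_under_rigid_motion(self, rng):
        frames = rng.uniform(0, 8, size=(2, 5, 3))
        atoms = [Atom(i, "CA", "C", "GLY", i + 1, "A") for i in range(5)]
        base = contact_map(Trajectory(Topology(atoms), frames), cutoff=4.5).values
        R = Rotation.from_euler("xyz", [0.5, 1.0, -0.7]).as_matrix()
        moved = contact_map(
            Trajectory(Topology(atoms), frames @ R.T + np.array([3.0, -2.0, 9.0])), cutoff=4.5
        ).values
        np.testing.assert_allclose(moved, base)

    def test_hydrogens_excluded_from_min_distance(self):
        # H within cutoff but heavy atoms far apart -> no contact
        atoms = [
            Atom(0, "CA", "C", "GLY", 1, "A"),
            Atom(1, "H", "H", "GLY", 1, "A"),
            Atom(2, "CA", "C", "GLY", 2, "A"),
        ]
        frames = np.array([[[0, 0, 0], [5.0, 0, 0], [8.0, 0, 0]]])
        m = contact_map(Trajectory(Topology(atoms), frames), cutoff=4.5)
        assert m.values[0, 1] == 0.0


class TestDifferentialContactMap:
    def test_identical_maps_zero(self):
        traj = _linear_system([(0, 0, 0), (3, 0, 0)], n_frames=2)
        a = contact_map(traj, cutoff=4.5, label="A")
        d = differential_contact_map(a, a)
        np.testing.assert_allclose(d.values, 0.0)

    def test_gained_pair_plus_one(self):
        a = contact_map(_linear_system([(0, 0, 0), (20, 0, 0)]), cutoff=4.5)
        b = contact_map(_linear_system([(0, 0, 0), (3, 0, 0)]), cutoff=4.5)
        d = differential_contact_map(a, b)
        assert d.values[0, 1] == 1.0

    def test_antisymmetric_under_swap(self, rng):
        fa = rng.uniform(0, 6, size=(3, 4, 3))
        fb = rng.uniform(0, 6, size=(3, 4, 3))
        atoms = [Atom(i, "CA", "C", "GLY", i + 1, "A") for i in range(4)]
        a = contact_map(Trajectory(Topology(atoms), fa), cutoff=4.5)
        b = contact_map(Trajectory(Topology(atoms), fb), cutoff=4.5)
        ab = differential_contact_map(a, b).values
        ba = differential_contact_map(b, a).values
        np.testing.assert_allclose(ab, -ba)

    def test_detached_block_localized(self):
        # residues 1-2 and 3-4 in contact when intact; 3-4 moved away in "detached"
        intact = _linear_system([(0, 0, 0), (3, 0, 0), (6, 0, 0), (9, 0, 0)], n_frames=2)
        detached = _linear_system([(0, 0, 0), (3, 0, 0), (60, 0, 0), (63, 0, 0)], n_frames=2)
        d = differential_contact_map(
            contact_map(intact, cutoff=4.5), contact_map(detached, cutoff=4.5)
        )
        assert d.values[1, 2] == -1.0  # interface pair lost
        assert d.values[0, 1] == 0.0  # intra-block contacts unchanged
        assert d.values[2, 3] == 0.0

    def test_axis_mismatch_rejected(self):
        a = contact_map(_linear_system([(0, 0, 0), (3, 0, 0)]), cutoff=4.5)
        b = contact_map(_linear_system([(0, 0, 0), (3, 0, 0), (6, 0, 0)]), cutoff=4.5)
        with pytest.raises(ValueError, match="axes"):
            differential_contact_map(a, b)


class TestShrakeRupley:
    def test_isolated_sphere_closed_form(self):
        area = sasa_shrake_rupley(np.zeros((1, 3)), np.array([1.8]), probe=1.4, n_points=960)
        assert area[0] == pytest.approx(4 * np.pi * 3.2**2, rel=0.005)

    def test_disjoint_spheres_additive(self):
        coords = np.array([[0.0, 0, 0], [100.0, 0, 0]])
        areas = sasa_shrake_rupley(coords, np.array([1.8, 1.8]), probe=1.4, n_points=960)
        single = sasa_shrake_rupley(np.zeros((1, 3)), np.array([1.8]), probe=1.4, n_points=960)
        assert areas.sum() == pytest.approx(2 * single[0], rel=1e-9)

    def test_two_overlapping_spheres_match_spherical_cap(self):
        # equal spheres R = r + probe = 3.2, centers d = 3.0 apart:
        # each loses a cap of height h = R - d/2
        r, probe, d = 1.8, 1.4, 3.0
        R = r + probe
        h = R - d / 2
        expected_per_atom = 4 * np.pi * R**2 - 2 * np.pi * R * h
        coords = np.array([[0.0, 0, 0], [d, 0, 0]])
        areas = sasa_shrake_rupley(coords, np.array([r, r]), probe=probe, n_points=960)
        assert areas[0] == pytest.approx(expected_per_atom, rel=0.02)
        assert areas[1] == pytest.approx(expected_per_atom, rel=0.02)

    def test_occlusion_monotonicity(self):
        lone = sasa_shrake_rupley(np.zeros((1, 3)), np.array([1.7]), n_points=480)[0]
        crowded = sasa_shrake_rupley(
            np.array([[0.0, 0, 0], [3.0, 0, 0]]), np.array([1.7, 1.7]), n_points=480
        )[0]
        assert crowded <= lone

    def test_missing_radius_rejected(self):
        with pytest.raises(ValueError, match="radius"):
            sasa_shrake_rupley(np.zeros((1, 3)), np.array([np.nan]))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="n_points"):
            sasa_shrake_rupley(np.zeros((1, 3)), np.array([1.5]), n_points=16)


class TestSasaHistogram:
    def test_constant_series_single_bin(self):
        s = SASASeries(values=np.full(20, 130.0), selection_name="x")
        density, edges = sasa_histogram(s, bin_width=10.0)
        assert density.max() == pytest.approx(1.0 / 10.0)
        assert (density > 0).sum() == 1

    def test_two_equal_masses(self):
        s = SASASeries(values=np.array([5.0] * 10 + [25.0] * 10), selection_name="x")
        density, edges = sasa_histogram(s, bin_width=10.0)
        occupied = density[density > 0]
        np.testing.assert_allclose(occupied, 0.5 / 10.0)

    def test_density_integrates_to_one(self, rng):
        s = SASASeries(values=rng.normal(100, 15, size=400).clip(0), selection_name="x")
        density, edges = sasa_histogram(s, bin_width=5.0)
        assert np.sum(density * np.diff(edges)) == pytest.approx(1.0)

    def test_gaussian_mean_recovered(self, rng):
        mu, sd, n = 120.0, 10.0, 2000
        s = SASASeries(values=rng.normal(mu, sd, size=n), selection_name="x")
        density, edges = sasa_histogram(s, bin_width=2.0)
        centers = (edges[:-1] + edges[1:]) / 2
        est = np.sum(centers * density * np.diff(edges))
        assert abs(est - mu) < 3 * sd / np.sqrt(n) + 2.0  # + bin-width bias bound
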