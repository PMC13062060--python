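"""Kabsch superposition and component RMSD series."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from rcvkit.superpose import (
    RMSDSeries,
    apply_transform,
    kabsch_fit,
    rmsd,
    rmsd_series,
    summarize_pooled,
)
from rcvkit.synthetic import StateMixtureSpec, StateSpec, make_state_mixture_trajectory
from rcvkit.trajectory import ComponentSelection, Trajectory


def brute_force_fit_rmsd(mobile, reference, n_grid=12):
    """Independent rigid-fit oracle: Euler-angle grid + local refinement.

    The optimal translation for any rotation matches the centroids, so the
    search is over rotations only.
    """
    mc = mobile - mobile.mean(axis=0)
    rc = reference - reference.mean(axis=0)

    def objective(euler):
        R = Rotation.from_euler("zyx", euler).as_matrix()
        return rmsd(mc @ R.T, rc)

    best = np.inf
    grid = np.linspace(-np.pi, np.pi, n_grid, endpoint=False)
    for a in grid:
        for b in grid[: n_grid // 2]:
            for c in grid:
                val = objective([a, b, c])
                if val < best:
                    best, best_euler = val, [a, b, c]
    res = minimize(objective, best_euler, method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 5000})
    return min(best, res.fun)


class TestKabschFit:
    def test_identity_on_identical_points(self, rng):
        pts = rng.normal(size=(6, 3))
        R, t, r = kabsch_fit(pts, pts)
        assert r == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-10)

    def test_rigid_motion_recovered(self, rng):
        pts = rng.normal(size=(5, 3))
        Rz = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = pts @ Rz.T + np.array([5.0, 0.0, 0.0])
        _, _, r = kabsch_fit(moved, pts)
        assert r == pytest.approx(0.0, abs=1e-10)

    def test_matches_grid_search_oracle(self, rng):
        for _ in range(5):
            ref = rng.normal(size=(4, 3)) * 3
            mob = ref + rng.normal(scale=0.4, size=ref.shape)
            _, _, r = kabsch_fit(mob, ref)
            assert r == pytest.approx(brute_force_fit_rmsd(mob, ref), abs=1e-3)

    def test_matches_scipy_align_vectors(self, rng):
        """Cross-check against scipy's independent Wahba solver."""
        ref = rng.normal(size=(8, 3))
        mob = ref + rng.normal(scale=0.3, size=ref.shape)
        _, _, r = kabsch_fit(mob, ref)
        rot, rssd = Rotation.align_vectors(
            ref - ref.mean(0), mob - mob.mean(0)
        )
        assert r == pytest.approx(rssd / np.sqrt(len(ref)), abs=1e-9)

    def test_rotation_is_proper_orthonormal(self, rng):
        for _ in range(10):
            mob = rng.normal(size=(5, 3))
            ref = rng.normal(size=(5, 3))
            R, _, _ = kabsch_fit(mob, ref)
            np.testing.assert_allclose(R.T @ R, np.eye(3), atol=1e-10)
            assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-10)

    def test_fitted_never_exceeds_unaligned(self, rng):
        for _ in range(10):
            mob = rng.normal(size=(6, 3)) * 2
            ref = rng.normal(size=(6, 3)) * 2
            _, _, fitted = kabsch_fit(mob, ref)
            assert fitted <= rmsd(mob, ref) + 1e-12

    def test_point_count_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            kabsch_fit(np.zeros((4, 3)), np.zeros((5, 3)))


class TestRMSDSeries:
    def test_zero_for_identical_trajectory(self, dimer):
        _, topo, ref, sels = dimer
        traj = Trajectory(topo, np.repeat(ref.frames, 4, axis=0))
        s = rmsd_series(traj, ref, sels["core"], sels["lid"])
        np.testing.assert_allclose(s.values, 0.0, atol=1e-10)

    def test_align_equals_measure_collapses_to_kabsch(self, dimer, rng):
        _, topo, ref, sels = dimer
        frames = ref.frames + rng.normal(scale=0.3, size=(3,) + ref.frames.shape[1:])
        traj = Trajectory(topo, frames)
        s = rmsd_series(traj, ref, sels["lid"], sels["lid"])
        from rcvkit.trajectory import resolve_selection

        idx = resolve_selection(topo, sels["lid"])
        for f in range(3):
            _, _, expected = kabsch_fit(frames[f, idx], ref.frames[0, idx])
            assert s.values[f] == pytest.approx(expected, abs=1e-10)

    def test_two_state_medians_match_generator_analytic(self, dimer):
        _, topo, ref, sels = dimer
        spec = StateMixtureSpec(
            states=(
                StateSpec(offsets=(("lid", (0.0, 0.0, 1.0)),), weight=0.5),
                StateSpec(offsets=(("lid", (0.0, 0.0, 4.0)),), weight=0.5),
            ),
            noise_sigma=0.0,
            n_frames=100,
            seed=7,
        )
        traj, labels, analytic = make_state_mixture_trajectory(topo, ref, spec, sels)
        s = rmsd_series(traj, ref, sels["core"], sels["lid"])
        for k in range(2):
            state_vals = s.values[labels == k]
            assert np.median(state_vals) == pytest.approx(analytic[k]["lid"], abs=1e-9)

    def test_invariant_under_global_rigid_motion(self, dimer, rng):
        _, topo, ref, sels = dimer
        frames = ref.frames + rng.normal(scale=0.2, size=(4,) + ref.frames.shape[1:])
        traj = Trajectory(topo, frames)
        base = rmsd_series(traj, ref, sels["core"], sels["lid"]).values
        R = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        moved = Trajectory(topo, frames @ R.T + np.array([10.0, -3.0, 7.0]))
        shifted = rmsd_series(moved, ref, sels["core"], sels["lid"]).values
        np.testing.assert_allclose(shifted, base, atol=1e-8)


class TestSummarizePooled:
    def _series(self, values, source=("r0", "A")):
        sel = ComponentSelection("lid", (("A", 25, 32),), "backbone")
        return RMSDSeries("lid", np.asarray(values, dtype=float), None, sel, source)

    def test_hand_computed_quartiles(self):
        # linear-interpolation quartiles of [1,2,3]: q1=1.5, q3=2.5
        s = summarize_pooled([self._series([1.0, 2.0, 3.0])])
        assert s.median == 2.0
        assert s.iqr == (1.5, 2.5)
        assert s.n_samples == 3

    def test_duplicate_series_leaves_median_unchanged(self):
        one = summarize_pooled([self._series([1.0, 2.0, 5.0])])
        two = summarize_pooled([self._series([1.0, 2.0, 5.0]), self._series([1.0, 2.0, 5.0], ("r1", "B"))])
        assert two.median == one.median
        assert two.n_samples == 6

    def test_constant_series(self):
        s = summarize_pooled([self._series([2.5] * 10)])
        assert s.median == 2.5
        assert s.iqr == (2.5, 2.5)

    def test_mixed_components_rejected(self):
        sel = ComponentSelection("rim", (("A", 35, 38),), "backbone")
        other = RMSDSeries("rim", np.array([1.0]), None, sel)
        with pytest.raises(ValueError, match="components"):
            summarize_pooled([self._series([1.0]), other])
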