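"""Observables against brute-force oracles; clustering; percentage errors."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hepcg.analysis import (
    cluster_frames,
    compute_observables,
    end_to_end_distance,
    percentage_error,
    radius_of_gyration,
    rmsd_anchors,
    sites_from_anchors,
)
from hepcg.dynamics import RunConfig, run_simulation
from hepcg.errors import AlignmentError, ParameterError
from hepcg.params import CGParameters
from hepcg.topology import build_chain


from oracles import brute_force_dbscan, quaternion_rmsd


class TestEED:
    def test_straight_chain(self):
        frame = np.zeros((7, 3))
        frame[:, 0] = 4.5 * np.arange(7)
        assert end_to_end_distance(frame) == pytest.approx(27.0)

    def test_closed_ring(self):
        t = np.linspace(0, 2 * np.pi, 13)
        ring = np.column_stack([np.cos(t), np.sin(t), np.zeros_like(t)])
        assert end_to_end_distance(ring) == pytest.approx(0.0, abs=1e-12)

    def test_brute_force_oracle(self, rng):
        frame = rng.normal(size=(10, 3)) * 8
        expected = np.sqrt(((frame[-1] - frame[0]) ** 2).sum())
        assert end_to_end_distance(frame) == pytest.approx(expected, rel=1e-12)


class TestRg:
    def test_single_point(self):
        assert radius_of_gyration(np.array([[1.0, 2.0, 3.0]])) == 0.0

    def test_two_points(self):
        pts = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        assert radius_of_gyration(pts) == pytest.approx(5.0)

    def test_brute_force_oracle(self, rng):
        pts = rng.normal(size=(20, 3)) * 6
        com = pts.mean(axis=0)
        expected = np.sqrt(np.mean(np.sum((pts - com) ** 2, axis=1)))
        assert radius_of_gyration(pts) == pytest.approx(expected, rel=1e-12)

    def test_rg_bounded_by_half_max_pairwise_distance(self, rng):
        pts = rng.normal(size=(15, 3)) * 5
        dmax = max(
            np.linalg.norm(pts[i] - pts[j])
            for i in range(15) for j in range(i + 1, 15)
        )
        assert radius_of_gyration(pts) <= dmax / 2 + 1e-12


class TestRMSD:
    def test_identical_frames(self, rng):
        x = rng.normal(size=(9, 3))
        assert rmsd_anchors(x, x) == pytest.approx(0.0, abs=1e-12)

    def test_rotated_copy_is_zero(self, rng):
        from scipy.spatial.transform import Rotation

        x = rng.normal(size=(9, 3)) * 5
        y = x @ Rotation.random(random_state=8).as_matrix().T + np.array([3.0, 1.0, -2.0])
        assert rmsd_anchors(x, y) < 1e-9

    def test_quaternion_oracle(self, rng):
        for _ in range(20):
            x = rng.normal(size=(12, 3)) * 5
            y = rng.normal(size=(12, 3)) * 5
            assert rmsd_anchors(x, y) == pytest.approx(quaternion_rmsd(x, y), abs=1e-9)

    def test_symmetry(self, rng):
        x = rng.normal(size=(7, 3))
        y = rng.normal(size=(7, 3))
        assert rmsd_anchors(x, y) == pytest.approx(rmsd_anchors(y, x), abs=1e-12)

    def test_count_mismatch(self, rng):
        with pytest.raises(AlignmentError):
            rmsd_anchors(rng.normal(size=(5, 3)), rng.normal(size=(6, 3)))


class TestClustering:
    def test_all_identical_frames(self, rng):
        frame = rng.normal(size=(8, 3))
        report = cluster_frames(np.repeat(frame[None], 5, axis=0))
        assert report.n_clusters == 1
        assert report.noise_count == 0

    def test_single_frame_below_min_size_is_noise(self, rng):
        report = cluster_frames(rng.normal(size=(1, 8, 3)), min_size=2)
        assert report.n_clusters == 0
        assert report.noise_count == 1

    def test_two_separated_bundles(self, rng):
        base1 = rng.normal(size=(8, 3)) * 3
        base2 = base1 + np.array([0, 0, 1]) * np.linspace(0, 40, 8)[:, None]
        frames = np.concatenate(
            [
                base1[None] + rng.normal(scale=0.05, size=(4, 8, 3)),
                base2[None] + rng.normal(scale=0.05, size=(4, 8, 3)),
            ]
        )
        report = cluster_frames(frames, eps=4.0, min_size=2)
        assert report.n_clusters == 2
        assert report.noise_count == 0
        labels = report.labels
        assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1
        assert labels[0] != labels[4]
        for lab, rep in report.representatives.items():
            assert labels[rep] == lab

    def test_matches_brute_force_dbscan(self, rng):
        frames = rng.normal(size=(12, 6, 3)) * 4
        n = len(frames)
        dist = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                dist[i, j] = dist[j, i] = rmsd_anchors(frames[i], frames[j])
        expected = brute_force_dbscan(dist, eps=4.0, min_samples=2)
        got = cluster_frames(frames, eps=4.0, min_size=2).labels
        # identical partition up to label permutation
        assert (got == -1).sum() == (expected == -1).sum()
        mapping = {}
        for g, e in zip(got, expected):
            if g == -1:
                assert e == -1
                continue
            assert mapping.setdefault(g, e) == e

    def test_empty_trajectory(self):
        report = cluster_frames(np.empty((0, 5, 3)))
        assert report.n_clusters == 0
        assert report.noise_count == 0

    def test_frame_order_invariance(self, rng):
        frames = rng.normal(size=(10, 6, 3)) * 4
        perm = rng.permutation(10)
        a = cluster_frames(frames).labels
        b = cluster_frames(frames[perm]).labels
        # permuting frames permutes labels consistently
        mapping = {}
        for i, pi in enumerate(perm):
            ga, gb = a[pi], b[i]
            assert (ga == -1) == (gb == -1)
            if ga != -1:
                assert mapping.setdefault(ga, gb) == gb


class TestPercentageError:
    def test_exact_match(self):
        pe = percentage_error(60.0, 60.0)
        assert pe.percent == 0.0
        assert pe.direction == "exact"

    def test_slightly_above(self):
        pe = percentage_error(60.12, 60.0)
        assert pe.percent == pytest.approx(0.2)
        assert pe.direction == "above"

    def test_far_below(self):
        pe = percentage_error(14.8, 60.0)
        assert pe.percent == pytest.approx(75.3, abs=0.05)
        assert pe.direction == "below"

    def test_invalid_reference(self):
        with pytest.raises(ParameterError):
            percentage_error(10.0, 0.0)


class TestObservableSeries:
    def test_eed_bounded_by_contour_length(self, params):
        chain = build_chain(8, params)
        traj = run_simulation(
            chain, params, RunConfig(n_steps=20_000, snapshot_stride=200, seed=5)
        )
        obs = compute_observables(traj)
        contours = np.linalg.norm(np.diff(traj.frames, axis=1), axis=2).sum(axis=1)
        assert np.all(obs.eed <= contours + 1e-9)
        assert np.all(obs.rg >= 0)

    def test_equilibration_window_excluded(self, rng):
        frames = rng.normal(size=(20, 5, 3))
        obs = compute_observables(frames, equilibration=0.5)
        assert obs.eed_mean == pytest.approx(obs.eed[10:].mean())

    def test_sites_from_anchors_midpoints(self, rng):
        anchors = rng.normal(size=(6, 3))
        sites = sites_from_anchors(anchors)
        assert np.allclose(sites, 0.5 * (anchors[:-1] + anchors[1:]))


@settings(derandomize=True, max_examples=20, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_rmsd_is_rigid_motion_invariant(seed):
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(seed)
    x = rng.normal(size=(8, 3)) * 4
    y = rng.normal(size=(8, 3)) * 4
    R = Rotation.random(random_state=seed).as_matrix()
    t = rng.normal(size=3) * 10
    assert rmsd_anchors(x @ R.T + t, y) == pytest.approx(rmsd_anchors(x, y), abs=1e-9)
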