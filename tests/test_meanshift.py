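"""Weighted mean shift: literal-summation oracles, equivariances, recovery."""

import math

import numpy as np
import pytest

from trihinge.errors import ConfigError, DimensionError
from trihinge.io import CorticalSurface
from trihinge.meanshift import (
    CentroidSet,
    MeanShiftConfig,
    WeightedMeanShift,
    find_centroids,
    mean_shift_mode,
    shift_vector,
)

from conftest import flat_sheet


def literal_shift(Xm, points, h, s, weight="gaussian_distance"):
    """Independent scalar-loop implementation of the weighted offset formula."""
    num = [0.0, 0.0, 0.0]
    den = 0.0
    for Xi in points:
        d = math.dist(Xi, Xm)
        u = d / h
        g = u / (math.sqrt(2 * math.pi) * s**3) * math.exp(-(u**2) / (2 * s**2))
        w = math.exp(-(d**2) / (2 * h**2)) if weight == "gaussian_distance" else 1.0
        c = g * w
        den += c
        for a in range(3):
            num[a] += c * (Xi[a] - Xm[a])
    return np.array([n / den for n in num])


def test_symmetric_pair_gives_zero_offset():
    cfg = MeanShiftConfig(weight_fn="uniform")
    Xm = np.array([1.0, 2.0, 3.0])
    d = np.array([0.7, -0.4, 1.1])
    offset = shift_vector(Xm, np.vstack([Xm + d, Xm - d]), cfg)
    np.testing.assert_allclose(offset, 0.0, atol=1e-12)


def test_single_point_offset_collapses_to_difference():
    Xm = np.array([0.0, 0.0, 0.0])
    X1 = np.array([3.0, 4.0, 0.0])
    offset = shift_vector(Xm, X1[None], MeanShiftConfig())
    np.testing.assert_allclose(offset, X1 - Xm, atol=1e-12)  # kernel and weight cancel


@pytest.mark.parametrize("weight", ["gaussian_distance", "uniform"])
def test_shift_matches_literal_summation(rng, weight):
    cfg = MeanShiftConfig(h=6.0, weight_fn=weight)
    points = rng.normal(size=(50, 3)) * 4
    Xm = rng.normal(size=3)
    ours = shift_vector(Xm, points, cfg)
    oracle = literal_shift(Xm, points, cfg.h, cfg.s_eff, weight)
    np.testing.assert_allclose(ours, oracle, atol=1e-10)


def test_degenerate_all_points_at_seed():
    Xm = np.array([1.0, 1.0, 1.0])
    offset, degenerate = shift_vector(
        Xm, np.tile(Xm, (5, 1)), MeanShiftConfig(), return_degenerate=True
    )
    assert degenerate
    np.testing.assert_array_equal(offset, 0.0)


def test_flat_kernel_uniform_weights_reproduce_in_sphere_sample_mean(rng):
    """Classical mean shift: offset = mean of points inside the h-sphere - Xm."""
    cfg = MeanShiftConfig(h=4.0, kernel="flat", weight_fn="uniform")
    points = rng.normal(size=(200, 3)) * 5
    Xm = rng.normal(size=3)
    inside = points[np.linalg.norm(points - Xm, axis=1) <= cfg.h]
    oracle = inside.mean(axis=0) - Xm
    np.testing.assert_allclose(shift_vector(Xm, points, cfg), oracle, atol=1e-12)


def test_mode_on_isolated_point_converges_immediately():
    point = np.array([[2.0, -1.0, 0.5]])
    mode, iters, converged = mean_shift_mode(np.array([5.0, 0.0, 0.0]), point, MeanShiftConfig())
    assert converged and iters <= 2
    np.testing.assert_allclose(mode, point[0], atol=1e-9)


def test_large_tol_stops_after_one_iteration(rng):
    points = rng.normal(size=(30, 3))
    _, iters, converged = mean_shift_mode(
        np.array([5.0, 5.0, 5.0]), points, MeanShiftConfig(tol=100.0)
    )
    assert converged and iters == 1


def test_gaussian_cloud_mode_near_sample_mean():
    rng = np.random.default_rng(77)
    cfg = MeanShiftConfig(h=6.0)
    points = rng.normal(scale=cfg.h / 2, size=(500, 3))
    seed = points.mean(axis=0) + np.array([cfg.h, 0, 0])
    mode, _, converged = mean_shift_mode(seed, points, cfg)
    assert converged
    assert np.linalg.norm(mode - points.mean(axis=0)) < 0.5 * cfg.h


def test_translation_equivariance(rng):
    cfg = MeanShiftConfig(h=5.0)
    points = rng.normal(size=(80, 3)) * 3
    seed = rng.normal(size=3)
    t = np.array([12.0, -7.0, 3.0])
    m1, _, _ = mean_shift_mode(seed, points, cfg)
    m2, _, _ = mean_shift_mode(seed + t, points + t, cfg)
    np.testing.assert_allclose(m2, m1 + t, atol=1e-9)


def test_rotation_equivariance(rng):
    from scipy.spatial.transform import Rotation

    cfg = MeanShiftConfig(h=5.0)
    points = rng.normal(size=(80, 3)) * 3
    seed = rng.normal(size=3)
    R = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
    m1, _, _ = mean_shift_mode(seed, points, cfg)
    m2, _, _ = mean_shift_mode(R @ seed, points @ R.T, cfg)
    np.testing.assert_allclose(m2, R @ m1, atol=1e-7)


# ---------------------------------------------------------------------------
# find_centroids
# ---------------------------------------------------------------------------

def disk_labels(surface, centers, radius):
    labels = np.zeros(surface.n_vertices, dtype=np.uint8)
    for c in centers:
        d = np.linalg.norm(surface.vertices - np.asarray(c), axis=1)
        labels[d <= radius] = 1
    return labels


def test_two_distant_blobs_give_two_centroids():
    surf = flat_sheet(40, 80)
    centers = [(15.0, 20.0, 0.0), (65.0, 20.0, 0.0)]
    labels = disk_labels(surf, centers, 6.0)
    cs = find_centroids(labels, surf, MeanShiftConfig())
    assert cs.n_centroids == 2
    d = np.linalg.norm(
        cs.centroids[:, None, :] - np.asarray(centers)[None, :, :], axis=2
    ).min(axis=1)
    assert d.max() < 6.0


def test_single_vertex_region():
    surf = flat_sheet(10, 10)
    labels = np.zeros(100, dtype=np.uint8)
    labels[55] = 1
    cfg = MeanShiftConfig(min_region_size=1, min_occupancy=0.0)
    cs = find_centroids(labels, surf, cfg)
    assert cs.n_centroids == 1
    np.testing.assert_allclose(cs.centroids[0], surf.vertices[55], atol=1e-9)


def test_all_zero_labels_give_empty_set():
    surf = flat_sheet(10, 10)
    cs = find_centroids(np.zeros(100), surf, MeanShiftConfig())
    assert cs.n_centroids == 0
    assert cs.cluster_sizes.size == 0


def test_small_components_discarded():
    surf = flat_sheet(30, 30)
    labels = disk_labels(surf, [(15.0, 15.0, 0.0)], 5.0)
    labels[0] = 1  # isolated single-vertex speck in the corner
    cs = find_centroids(labels, surf, MeanShiftConfig(min_region_size=5))
    assert cs.n_centroids == 1


def test_mode_count_monotone_in_merge_radius(desk_subject, desk_labels):
    counts = []
    for radius in (0.5, 3.0, 12.0, 60.0):
        cfg = MeanShiftConfig(merge_radius=radius)
        cs = find_centroids(desk_labels, desk_subject.surface, cfg)
        counts.append(cs.n_centroids)
    assert all(a >= b for a, b in zip(counts, counts[1:]))
    assert counts[-1] == 1  # merging at sheet scale collapses everything


def test_centroidset_invariants_on_desk_subject(desk_subject, desk_labels):
    cs = find_centroids(desk_labels, desk_subject.surface, MeanShiftConfig())
    pts = desk_subject.surface.vertices[cs.labeled_idx]
    assert cs.memberships.shape == (len(pts),)
    assert cs.cluster_sizes.sum() == len(pts)  # memberships partition the points
    h = 6.0
    for k in range(cs.n_centroids):
        member_pts = pts[cs.memberships == k]
        lo, hi = member_pts.min(axis=0) - h, member_pts.max(axis=0) + h
        assert np.all(cs.centroids[k] >= lo) and np.all(cs.centroids[k] <= hi)


def test_labels_length_mismatch_rejected():
    surf = flat_sheet(5, 5)
    with pytest.raises(DimensionError):
        find_centroids(np.zeros(7), surf, MeanShiftConfig())


def test_config_validation():
    with pytest.raises(ConfigError):
        MeanShiftConfig(h=0.0).validate()
    with pytest.raises(ConfigError):
        MeanShiftConfig(weight_fn="cubic").validate()
    with pytest.raises(ConfigError):
        MeanShiftConfig(kernel="triangular").validate()


def test_weighted_meanshift_estimator_clusters_two_gaussians():
    rng = np.random.default_rng(5)
    a = rng.normal(loc=(0, 0, 0), scale=1.0, size=(150, 3))
    b = rng.normal(loc=(20, 0, 0), scale=1.0, size=(150, 3))
    X = np.vstack([a, b])
    ms = WeightedMeanShift(bandwidth=4.0).fit(X)
    assert len(ms.cluster_centers_) == 2
    assert set(ms.labels_) == {0, 1}
    centers = ms.cluster_centers_[np.argsort(ms.cluster_centers_[:, 0])]
    assert np.linalg.norm(centers[0] - a.mean(axis=0)) < 2.0
    assert np.linalg.norm(centers[1] - b.mean(axis=0)) < 2.0
    # one cluster per side
    assert (ms.labels_[:150] == ms.labels_[0]).all()
    assert (ms.labels_[150:] == ms.labels_[150]).all()
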