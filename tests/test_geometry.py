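import numpy as np
import pytest

from dualscale import geometry as geo
from dualscale.protocol import build_schedule

RNG = np.random.default_rng(2024)


def _series(points):
    return geo.SnapshotSeries(points=np.asarray(points, dtype=float),
                              event_times=np.arange(7.0))


def test_snapshot_times_default_schedule():
    sched = build_schedule()
    times = geo.snapshot_times(sched)
    assert list(times) == [600, 2400, 4200, 6000, 7800, 9600, 13200]


def test_extract_snapshots_constant_and_ramp():
    sched = build_schedule(lead_s=100, n_cycles=3, pert_s=100, wash_s=100,
                           tail_s=100)
    t = np.arange(0.0, sched.total_duration, 1.0)
    const = np.full((t.size, 2), 3.25)
    series = geo.extract_snapshots(t, const, sched)
    assert np.allclose(series.points, 3.25)

    ramp = np.stack([t, 2 * t], axis=1)
    series = geo.extract_snapshots(t, ramp, sched)
    # window [t-30, t-10) over integer samples -> mean at t - 20.5
    expected = series.event_times - 20.5
    assert np.allclose(series.points[:, 0], expected)
    assert np.allclose(series.points[:, 1], 2 * expected)


def test_displacements_simple_sequence():
    pts = np.array([[0.0], [1.0], [3.0], [6.0], [10.0], [15.0], [21.0]])
    disp = geo.displacements(_series(pts))
    assert np.allclose(disp.ravel(), [1, 2, 3, 4, 5, 6])
    assert geo.DISPLACEMENT_LABELS[0] == "After Pert 1"
    assert geo.DISPLACEMENT_LABELS[-1] == "After Wash 3"


def test_identical_points_give_zero_displacements_and_radius():
    pts = np.ones((7, 5))
    disp = geo.displacements(_series(pts))
    assert np.allclose(disp, 0.0)
    sphere = geo.bounding_sphere(pts[1:])
    assert sphere.radius == 0.0


def test_vector_norm_examples_and_oracle():
    assert geo.vector_norm([3.0, 4.0]) == 5.0
    assert geo.vector_norm(np.zeros(11)) == 0.0
    v = RNG.normal(size=11)
    brute = np.sqrt(sum(x * x for x in v))  # elementwise oracle
    assert geo.vector_norm(v) == pytest.approx(brute, rel=1e-15)


def test_bounding_sphere_two_point_example():
    pts = np.array([[0.0], [2.0], [0.0], [2.0], [0.0], [2.0]])
    sphere = geo.bounding_sphere(pts)
    assert sphere.center[0] == pytest.approx(1.0)
    assert sphere.radius == pytest.approx(1.0)


def test_signed_outside_distance_examples():
    sphere = geo.SphereSummary(center=np.zeros(3), radius=1.0,
                               outside_distance=float("nan"))
    assert geo.signed_outside_distance([3.0, 0, 0], sphere) == \
        pytest.approx(2.0)
    assert geo.signed_outside_distance([0.0, 0, 0], sphere) == \
        pytest.approx(-1.0)
    assert geo.signed_outside_distance([0.0, 1.0, 0], sphere) == \
        pytest.approx(0.0)


def test_angle_examples():
    u = RNG.normal(size=11)
    assert geo.angle_between(u, -u) == pytest.approx(180.0)
    assert geo.angle_between([1, 0], [0, 2]) == pytest.approx(90.0)
    with pytest.raises(ValueError):
        geo.angle_between(u, np.zeros(11))


def test_angle_matches_high_precision_oracle():
    for _ in range(200):
        u, v = RNG.normal(size=(2, 7))
        # oracle via atan2 of the rejection, numerically independent of arccos
        nu = np.linalg.norm(u)
        proj = np.dot(u, v) / nu
        perp = np.linalg.norm(v - proj * u / nu)
        oracle = np.degrees(np.arctan2(perp, proj))
        assert geo.angle_between(u, v) == pytest.approx(oracle, abs=1e-9)


def test_geometry_oracles_on_random_instances():
    # norms, spheres, outside distances and angles vs brute force, 1000 cases
    for _ in range(1000):
        d = int(RNG.integers(2, 12))
        pts = RNG.normal(size=(7, d)) * RNG.uniform(0.1, 10)
        series = _series(pts)
        disp = geo.displacements(series)
        for k in range(6):
            assert geo.vector_norm(disp[k]) == pytest.approx(
                np.sqrt(np.sum(disp[k] ** 2)), abs=1e-9)
        sphere = geo.bounding_sphere(pts[1:])
        brute_r = max(np.sqrt(np.sum((p - pts[1:].mean(axis=0)) ** 2))
                      for p in pts[1:])
        assert sphere.radius == pytest.approx(brute_r, abs=1e-9)
        dist = np.sqrt(np.sum((pts[0] - sphere.center) ** 2))
        assert geo.signed_outside_distance(pts[0], sphere) == pytest.approx(
            dist - brute_r, abs=1e-9)
        u, v = disp[4], disp[5]
        c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        assert geo.angle_between(u, v) == pytest.approx(
            np.degrees(np.arccos(np.clip(c, -1, 1))), abs=1e-9)


def test_rotation_invariance_and_scale_equivariance():
    for _ in range(25):
        d = 7
        pts = RNG.normal(size=(7, d))
        q, _ = np.linalg.qr(RNG.normal(size=(d, d)))
        s = float(RNG.uniform(0.5, 3.0))
        base = geo.trajectory_summary(_series(pts))
        rotated = geo.trajectory_summary(_series(pts @ q.T))
        scaled = geo.trajectory_summary(_series(pts * s))
        for label in geo.DISPLACEMENT_LABELS:
            assert rotated["norms"][label] == pytest.approx(
                base["norms"][label], rel=1e-9)
            assert scaled["norms"][label] == pytest.approx(
                base["norms"][label] * s, rel=1e-9)
        assert rotated["radius"] == pytest.approx(base["radius"], rel=1e-9)
        assert scaled["outside_distance"] == pytest.approx(
            base["outside_distance"] * s, rel=1e-9)
        for key in ("angle_pert_wash_pert", "angle_wash_pert_wash"):
            assert rotated[key] == pytest.approx(base[key], abs=1e-6)
            assert scaled[key] == pytest.approx(base[key], abs=1e-9)


def test_angle_threshold_means_negative_dot_product():
    for _ in range(100):
        u, v = RNG.normal(size=(2, 11))
        assert (geo.angle_between(u, v) > 90.0) == (np.dot(u, v) < 0)
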