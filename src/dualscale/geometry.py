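"""Parameter-space trajectory geometry.

Seven event-anchored snapshots of an intrinsic-parameter vector are taken per
run (just before each of the three perturbations, at the end of each, and
after the final wash).  From these we derive the six successive displacement
vectors, their Euclidean norms, a mean-centered bounding sphere over the six
post-adaptation points, the signed distance of the naive state to that
sphere, and tail-to-tail angles between successive displacements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DISPLACEMENT_LABELS", "SnapshotSeries", "SphereSummary",
    "snapshot_times", "extract_snapshots", "displacements", "vector_norm",
    "bounding_sphere", "signed_outside_distance", "angle_between",
    "trajectory_summary",
]

DISPLACEMENT_LABELS = (
    "After Pert 1", "After Wash 1", "After Pert 2",
    "After Wash 2", "After Pert 3", "After Wash 3",
)

#: averaging window relative to the event time: [t-30 s, t-10 s)
WINDOW_BEFORE = 30.0
WINDOW_AFTER = 10.0


@dataclass(frozen=True)
class SnapshotSeries:
    """The seven event-anchored parameter vectors, chronological order."""

    points: np.ndarray  # (7, d)
    event_times: np.ndarray  # (7,) s

    def __post_init__(self):
        if self.points.shape[0] != 7:
            raise ValueError("exactly 7 snapshots required")


@dataclass(frozen=True)
class SphereSummary:
    center: np.ndarray
    radius: float
    outside_distance: float  # ||p1 - center|| - radius; negative = inside


def snapshot_times(schedule) -> np.ndarray:
    """Event times of the seven snapshots for a 3-cycle schedule (s)."""
    perts = schedule.perturbation_epochs
    if len(perts) != 3:
        raise ValueError("snapshot extraction requires a 3-cycle schedule")
    times = []
    for e in perts:
        times.append(e.start)  # just before perturbation k
        times.append(e.end)  # end of perturbation k
    times.append(schedule.total_duration)  # after the final wash
    return np.array(sorted(times))


def extract_snapshots(sample_times, param_samples, schedule) -> SnapshotSeries:
    """Average ``param_samples`` over [t-30 s, t-10 s) at each event time.

    ``param_samples`` has shape (n_samples, d); samples must cover every
    window (parameter recording at >= 1 Hz guarantees >= 19 samples each).
    """
    sample_times = np.asarray(sample_times, dtype=float)
    param_samples = np.asarray(param_samples, dtype=float)
    events = snapshot_times(schedule)
    points = np.empty((7, param_samples.shape[1]))
    for i, t_event in enumerate(events):
        mask = (sample_times >= t_event - WINDOW_BEFORE) & (
            sample_times < t_event - WINDOW_AFTER)
        if not mask.any():
            raise ValueError(
                f"no parameter samples in snapshot window before t={t_event}")
        points[i] = param_samples[mask].mean(axis=0)
    return SnapshotSeries(points=points, event_times=events)


def displacements(series: SnapshotSeries) -> np.ndarray:
    """Six successive displacement vectors p[k+1] - p[k], shape (6, d)."""
    return np.diff(series.points, axis=0)


def vector_norm(v) -> float:
    """Euclidean norm: square each element, sum, square root."""
    v = np.asarray(v, dtype=float)
    return float(np.sqrt(np.sum(v * v)))


def bounding_sphere(points) -> SphereSummary:
    """Mean-centered sphere over the six post-adaptation points (2..7).

    The center is the componentwise mean and the radius the largest distance
    of any of the six points to the center — the smallest sphere centered at
    the mean that encloses all of them.  ``outside_distance`` is filled by
    :func:`signed_outside_distance`; here it is NaN.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] != 6:
        raise ValueError("bounding sphere is defined over the 6 points 2..7")
    center = pts.mean(axis=0)
    radius = float(np.max(np.linalg.norm(pts - center, axis=1)))
    return SphereSummary(center=center, radius=radius,
                         outside_distance=float("nan"))


def signed_outside_distance(point1, sphere: SphereSummary) -> float:
    """||point1 - center|| - radius; positive iff the point lies outside."""
    d = vector_norm(np.asarray(point1, dtype=float) - sphere.center)
    return d - sphere.radius


def angle_between(u, v) -> float:
    """Tail-to-tail angle between two nonzero vectors, degrees in [0, 180]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = vector_norm(u), vector_norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("angle undefined for zero vector")
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def trajectory_summary(series: SnapshotSeries) -> dict:
    """Per-model geometric summary used by the reports.

    Returns displacement norms (labeled), the sphere over points 2..7 with
    the signed outside distance of point 1, and the two angle measurements:
    pert-wash-pert = angle(After Wash 2, After Pert 3) and
    wash-pert-wash = angle(After Pert 3, After Wash 3).
    """
    disp = displacements(series)
    sphere = bounding_sphere(series.points[1:])
    out = signed_outside_distance(series.points[0], sphere)
    summary = {
        "norms": {label: vector_norm(disp[k])
                  for k, label in enumerate(DISPLACEMENT_LABELS)},
        "radius": sphere.radius,
        "outside_distance": out,
        "center_distance": out + sphere.radius,
    }
    try:
        summary["angle_pert_wash_pert"] = angle_between(disp[3], disp[4])
        summary["angle_wash_pert_wash"] = angle_between(disp[4], disp[5])
    except ValueError:
        summary["angle_pert_wash_pert"] = float("nan")
        summary["angle_wash_pert_wash"] = float("nan")
    return summary
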