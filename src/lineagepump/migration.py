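"""Mean migration velocity from centroid tracks.

Velocity is total path length divided by total tracked time, evaluated on
centroid samples at least 2 h apart: for shorter intervals the displacement
is comparable to microscope stage-relocation error, so denser samples would
inflate the path length with positioning noise. The final observed point is
always kept; when it lands closer than one interval after the last retained
grid point, that grid point is dropped so the final interval exceeds the
grid spacing ("last-interval rule").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CentroidPath",
    "ResampledPath",
    "resample_to_grid",
    "migration_velocity",
    "path_from_observations",
]

DEFAULT_INTERVAL_H = 2.0


@dataclass
class CentroidPath:
    """Strictly time-increasing centroid samples (hours, micrometres)."""

    times: np.ndarray
    xs: np.ndarray
    ys: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.xs = np.asarray(self.xs, dtype=float)
        self.ys = np.asarray(self.ys, dtype=float)
        if not (len(self.times) == len(self.xs) == len(self.ys)):
            raise ValueError("times, xs, ys must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class ResampledPath:
    """A centroid path after grid resampling, with quality flags."""

    path: CentroidPath
    short_track: bool = False
    degenerate: bool = False
    dropped_last_grid_point: bool = False


def path_from_observations(observations) -> CentroidPath:
    """Build a path from a cell's observation series (any frame kind)."""
    return CentroidPath(
        times=np.array([o.time for o in observations]),
        xs=np.array([o.centroid_x for o in observations]),
        ys=np.array([o.centroid_y for o in observations]),
    )


def resample_to_grid(
    path: CentroidPath, interval: float = DEFAULT_INTERVAL_H
) -> ResampledPath:
    """Thin a path to samples >= ``interval`` apart, last-interval rule applied.

    The grid is anchored at the cell's own first observation (daughters are
    born off any experiment-wide grid). Points are retained greedily: the
    next point kept is the earliest one at least ``interval`` after the last
    kept point; the final observed point is then appended. If the final gap
    is shorter than ``interval``, the preceding retained point is removed so
    the final interval exceeds ``interval``. Paths spanning less than one
    interval in total are flagged ``short_track`` (and ``degenerate`` when a
    velocity cannot be computed at all).
    """
    eps = 1e-9
    n = len(path)
    if n < 2:
        empty = CentroidPath(path.times[:n], path.xs[:n], path.ys[:n])
        return ResampledPath(path=empty, short_track=True, degenerate=True)

    keep = [0]
    for i in range(1, n - 1):
        if path.times[i] - path.times[keep[-1]] >= interval - eps:
            keep.append(i)
    dropped = False
    final_gap = path.times[-1] - path.times[keep[-1]]
    if final_gap < interval - eps and len(keep) > 1:
        keep.pop()  # drop the preceding grid point -> final interval > interval
        dropped = True
    keep.append(n - 1)

    resampled = CentroidPath(path.times[keep], path.xs[keep], path.ys[keep])
    span = resampled.times[-1] - resampled.times[0]
    return ResampledPath(
        path=resampled,
        short_track=bool(span < interval - eps),
        degenerate=False,
        dropped_last_grid_point=dropped,
    )


def migration_velocity(path: CentroidPath) -> float:
    """Path length divided by elapsed time, in micrometres/day."""
    if len(path) < 2:
        raise ValueError("velocity requires at least 2 points")
    elapsed_h = path.times[-1] - path.times[0]
    if elapsed_h <= 0:
        raise ValueError("zero elapsed time")
    steps = np.hypot(np.diff(path.xs), np.diff(path.ys))
    return float(steps.sum() / elapsed_h * 24.0)
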