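"""Shared fixtures: tiny hand-built lineage forests and brute-force oracles."""

from __future__ import annotations

import math

import numpy as np
import pytest

from lineagepump.model import LineageForest, Observation, TrackedCell


def make_observation(time, x=0.0, y=0.0, fluorescence=None, area=None,
                     circularity=None, kind=None):
    """Observation helper; perimeter derived from area and circularity."""
    perimeter = None
    if area is not None:
        circ = circularity if circularity is not None else 0.6
        perimeter = math.sqrt(4.0 * math.pi * area / circ)
    if kind is None:
        kind = "fluorescence" if fluorescence is not None else "phase"
    return Observation(
        time=time, centroid_x=x, centroid_y=y, area=area,
        perimeter=perimeter, fluorescence=fluorescence, frame_kind=kind,
    )


def make_cell(cell_id, generation=0, parent_id=None, birth=None, end=8.0,
              fate="incomplete", obs=(), cell_type="SAOS-2",
              condition="co-culture", experiment_id="x"):
    return TrackedCell(
        cell_id=cell_id, experiment_id=experiment_id, cell_type=cell_type,
        condition=condition, generation=generation, parent_id=parent_id,
        birth_time=birth, end_time=end, fate=fate, observations=list(obs),
    )


@pytest.fixture
def two_generation_forest():
    """One divided mother (M) with two daughters, plus one bystander."""
    forest = LineageForest(experiment_id="x")
    forest.add(make_cell(
        "M", end=8.0, fate="divided",
        obs=[make_observation(0.0, fluorescence=200.0),
             make_observation(4.0, fluorescence=240.0),
             make_observation(8.0, fluorescence=300.0)],
    ))
    for cid, fl in (("M.1", 150.0), ("M.2", 180.0)):
        forest.add(make_cell(
            cid, generation=1, parent_id="M", birth=8.0, end=20.0,
            obs=[make_observation(8.0, fluorescence=fl),
                 make_observation(12.0, fluorescence=fl + 20.0),
                 make_observation(16.0, fluorescence=fl + 40.0),
                 make_observation(20.0, fluorescence=fl + 60.0)],
        ))
    forest.add(make_cell(
        "B", end=20.0, fate="incomplete",
        obs=[make_observation(0.0, fluorescence=100.0),
             make_observation(4.0, fluorescence=110.0),
             make_observation(20.0, fluorescence=140.0)],
    ))
    return forest


def brute_force_tau_b(x, y):
    """O(n^2) pair enumeration with tau-b tie normalization."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    concordant = discordant = ties_x = ties_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx == 0 and dy == 0:
                ties_x += 1
                ties_y += 1
            elif dx == 0:
                ties_x += 1
            elif dy == 0:
                ties_y += 1
            elif dx * dy > 0:
                concordant += 1
            else:
                discordant += 1
    n0 = n * (n - 1) / 2
    denom = math.sqrt((n0 - ties_x) * (n0 - ties_y))
    if denom == 0:
        return float("nan")
    return (concordant - discordant) / denom


def brute_force_velocity(times_h, xs, ys):
    """Sum of hypotenuses divided by elapsed time, um/day."""
    total = 0.0
    for i in range(1, len(times_h)):
        total += math.hypot(xs[i] - xs[i - 1], ys[i] - ys[i - 1])
    return total / (times_h[-1] - times_h[0]) * 24.0
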