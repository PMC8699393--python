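"""Agent-based simulator of donor/acceptor co-culture with label transfer.

The simulator emulates the structure of a tracked co-culture time-lapse
experiment: an asynchronously dividing acceptor (osteosarcoma-like)
population receiving a lipophilic membrane label from a donor
(fibroblast-like) population over up to 5 days, observed on three
interleaved grids (phase 0.25 h, centroid 2 h, fluorescence 4 h).

Mechanics, per acceptor cell:

* label content follows a gamma process whose per-day mean is the cell's
  uptake *propensity* (log-normal across cells; sisters share a correlated
  random effect). Transfer is propensity-driven, not geometry-driven.
* every cell also carries a baseline red-channel fluorescence
  (bleed-through plus imaging background), so unlabelled cells measure a
  small positive signal — this is what anchors normalization at the first
  frame.
* at division the mother's content is split between the daughters
  (fraction configurable, default exactly half); intermitotic times are
  log-normal, shortened monotonically by uptake propensity when the
  division coupling is on.
* each phenotype (area, circularity, velocity) is a noisy monotone
  function of a *driver*. With the persistence switch ``"reset"`` the
  driver is the cell's current label content; with ``"inherit"`` a
  daughter starts from her mother's final driver value (undiluted) and
  adds her own uptake — the mechanism whose footprint the
  mother-compensated fluorescence (Fmc) analysis is designed to detect.

Couplings encode the study system's qualitative behaviour with invented
magnitudes chosen to land on realistic scales (all-generation area tau
around 0.5, uptake rates of tens of normalized units/day, roughly a 3:1
ratio of tracked to starting cells over 4 days); they are synthetic ground
truth, not measurements.
"""

from __future__ import annotations

import math
import warnings
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .model import (
    CENTROID_INTERVAL_H,
    FLUORESCENCE_INTERVAL_H,
    PHASE_INTERVAL_H,
    LineageForest,
    Observation,
    TrackedCell,
)

__all__ = [
    "SimulationConfig",
    "simulate_experiment",
    "simulate_batch",
    "render_image_fixture",
    "STUDY_DURATIONS_DAYS",
    "EXPERIMENT_LABELS",
]

#: Per-experiment co-culture durations (days) of the seven-experiment design.
STUDY_DURATIONS_DAYS = (4.0, 2.0, 3.6, 4.0, 4.0, 5.0, 4.0)
EXPERIMENT_LABELS = ("a", "b", "c", "d", "e", "f", "g")

_POPULATION_GUARD = 1e5


@dataclass(frozen=True)
class SimulationConfig:
    """All parameters of one simulated co-culture experiment."""

    seed: int = 0
    experiment_id: str = "sim"
    n_start_acceptors: int = 100
    n_start_donors: int = 75
    duration_days: float = 4.0

    # acquisition grids (hours)
    phase_dt_h: float = PHASE_INTERVAL_H
    fluorescence_dt_h: float = FLUORESCENCE_INTERVAL_H
    centroid_dt_h: float = CENTROID_INTERVAL_H

    # division / fate
    intermitotic_median_h: float = 76.0
    intermitotic_log_sd: float = 0.35
    donor_intermitotic_median_h: float = 72.0
    division_uptake_coef: float = 0.5  # proportional shortening per unit relative propensity
    apoptosis_rate_per_day: float = 0.02
    loss_rate_per_day: float = 0.15
    incomplete_division_p: float = 0.02

    # label transfer (raw fluorescence units)
    uptake_median: float = 20.0  # units/day, log-normal across cells
    uptake_log_sd: float = 0.8
    uptake_shape_per_frame: float = 2.0  # gamma-process shape per 4-h frame
    baseline_fluorescence_median: float = 50.0
    baseline_fluorescence_log_sd: float = 0.3
    donor_fluorescence_median: float = 5000.0
    donor_fluorescence_log_sd: float = 0.3
    sister_propensity_corr: float = 0.7
    split_fraction: float = 0.5  # to daughter 1

    # phenotype couplings (phenotype = baseline +/- coef * driver + noise)
    area_baseline_um2: float = 700.0
    area_coef: float = 4.0
    area_noise_sd: float = 100.0
    area_floor_um2: float = 100.0
    circularity_baseline: float = 0.65
    circularity_coef: float = 0.0015
    circularity_noise_sd: float = 0.06
    velocity_baseline_um_day: float = 250.0
    velocity_coef: float = 0.6
    velocity_noise_sd: float = 60.0
    donor_area_um2: float = 1800.0
    donor_circularity: float = 0.25
    donor_velocity_um_day: float = 500.0

    # persistence switches: "reset" or "inherit", per phenotype driver
    persistence_area: str = "reset"
    persistence_circularity: str = "inherit"
    persistence_velocity: str = "reset"

    # field geometry (micrometres)
    field_width_um: float = 1920.0
    field_height_um: float = 1440.0

    def validate(self) -> None:
        if self.duration_days <= 0 or self.duration_days > 5.0:
            raise ValueError("duration_days must be in (0, 5]")
        if not (0.0 < self.split_fraction < 1.0):
            raise ValueError("split_fraction must be in (0, 1)")
        for name in ("persistence_area", "persistence_circularity",
                     "persistence_velocity"):
            if getattr(self, name) not in ("reset", "inherit"):
                raise ValueError(f"{name} must be 'reset' or 'inherit'")
        nonneg = (
            "intermitotic_median_h", "intermitotic_log_sd",
            "division_uptake_coef", "apoptosis_rate_per_day",
            "loss_rate_per_day", "uptake_median", "uptake_log_sd",
            "baseline_fluorescence_median", "area_noise_sd",
            "circularity_noise_sd", "velocity_noise_sd",
        )
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        expected = (self.n_start_acceptors + self.n_start_donors) * 2.0 ** (
            self.duration_days * 24.0 / self.intermitotic_median_h
        )
        if expected > _POPULATION_GUARD:
            raise ValueError(
                f"expected population {expected:.0f} exceeds the "
                f"{_POPULATION_GUARD:.0f}-cell guard; reduce duration or "
                "starting counts"
            )


def _cell_rng(seed: int, cell_id: str) -> np.random.Generator:
    # deterministic sub-stream per (seed, cell_id), independent of the
    # order in which cells are processed
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(cell_id.encode())])


def _quantize(t: float, dt: float) -> float:
    return round(t / dt) * dt


def _grid_times(start: float, stop: float, dt: float) -> np.ndarray:
    """Multiples of dt (experiment-wide grid) within [start, stop]."""
    first = math.ceil(start / dt - 1e-9) * dt
    if first > stop + 1e-9:
        return np.empty(0)
    return np.round(np.arange(first, stop + 1e-9, dt), 9)


@dataclass
class _CellState:
    cell_id: str
    cell_type: str
    generation: int
    parent_id: Optional[str]
    birth_time: Optional[float]  # None for starting generation
    start_time: float
    content: float  # label content at start
    propensity: float  # raw units/day (0 for donors)
    driver_inherit_base: float  # mother's final driver (inherit mode)
    position: tuple[float, float]


def _simulate_cell(
    state: _CellState, cfg: SimulationConfig
) -> tuple[TrackedCell, dict, list[_CellState]]:
    rng = _cell_rng(cfg.seed, state.cell_id)
    duration_h = cfg.duration_days * 24.0
    is_donor = state.cell_type == "HDF"

    # --- fate draws (fixed order for reproducibility) ---
    z_T = rng.standard_normal()
    if is_donor:
        T0 = cfg.donor_intermitotic_median_h * math.exp(cfg.intermitotic_log_sd * z_T)
        T_div = T0
    else:
        T0 = cfg.intermitotic_median_h * math.exp(cfg.intermitotic_log_sd * z_T)
        link = 1.0 + cfg.division_uptake_coef * (state.propensity / cfg.uptake_median
                                                 if cfg.uptake_median > 0 else 0.0)
        T_div = T0 / link
    t_div = state.start_time + T_div
    t_apo = (
        state.start_time + rng.exponential(24.0 / cfg.apoptosis_rate_per_day)
        if cfg.apoptosis_rate_per_day > 0
        else math.inf
    )
    t_loss = (
        state.start_time + rng.exponential(24.0 / cfg.loss_rate_per_day)
        if cfg.loss_rate_per_day > 0
        else math.inf
    )
    u_incomplete = rng.uniform()

    events = [(t_div, "divided"), (t_apo, "apoptosis"), (t_loss, "incomplete")]
    t_event, fate = min(events, key=lambda e: e[0])
    if t_event > duration_h + 1e-9:
        t_event, fate = duration_h, "incomplete"
    end_time = max(_quantize(t_event, cfg.phase_dt_h), state.start_time)
    end_time = min(end_time, duration_h)
    if end_time <= state.start_time and state.start_time < duration_h:
        end_time = min(state.start_time + cfg.phase_dt_h, duration_h)
    if fate == "divided" and u_incomplete < cfg.incomplete_division_p:
        fate = "incomplete-division"

    # --- observation times ---
    fluor_times = _grid_times(state.start_time, end_time, cfg.fluorescence_dt_h)
    centroid_times = _grid_times(state.start_time, end_time, cfg.centroid_dt_h)
    times = set(np.round(fluor_times, 9)) | set(np.round(centroid_times, 9))
    times.add(round(state.start_time, 9))
    times.add(round(end_time, 9))
    obs_times = np.array(sorted(times))
    fluor_set = set(np.round(fluor_times, 9))
    centroid_set = set(np.round(centroid_times, 9))

    # --- label content along the observation series (gamma process) ---
    dts = np.diff(obs_times, prepend=obs_times[0])
    if state.propensity > 0:
        shape_per_h = cfg.uptake_shape_per_frame / cfg.fluorescence_dt_h
        theta = state.propensity / 24.0 / shape_per_h
        increments = np.where(
            dts > 0, rng.gamma(np.maximum(shape_per_h * dts, 1e-12), theta), 0.0
        )
        increments[dts <= 0] = 0.0
    else:
        increments = np.zeros_like(dts)
    content = state.content + np.cumsum(increments)
    uptake = content - state.content  # own uptake since birth

    # --- phenotype drivers ---
    def driver(switch: str) -> np.ndarray:
        if switch == "inherit":
            return state.driver_inherit_base + uptake
        return content

    d_area = driver(cfg.persistence_area)
    d_circ = driver(cfg.persistence_circularity)
    d_vel = driver(cfg.persistence_velocity)

    # --- movement (random heading per interval, speed linked to driver) ---
    n = len(obs_times)
    headings = rng.uniform(0.0, 2.0 * math.pi, n)
    vel_cell_noise = rng.standard_normal() * cfg.velocity_noise_sd
    xs = np.empty(n)
    ys = np.empty(n)
    x, y = state.position
    for i in range(n):
        if i > 0:
            if is_donor:
                speed = cfg.donor_velocity_um_day
            else:
                speed = max(10.0, cfg.velocity_baseline_um_day
                            + cfg.velocity_coef * d_vel[i - 1] + vel_cell_noise)
            step = speed * dts[i] / 24.0
            x += step * math.cos(headings[i])
            y += step * math.sin(headings[i])
            # reflect into the field
            x = abs(x)
            y = abs(y)
            if x > cfg.field_width_um:
                x = 2 * cfg.field_width_um - x
            if y > cfg.field_height_um:
                y = 2 * cfg.field_height_um - y
            x = min(max(x, 0.0), cfg.field_width_um)
            y = min(max(y, 0.0), cfg.field_height_um)
        xs[i] = x
        ys[i] = y

    # --- shape measures at fluorescence frames ---
    area_noise = rng.standard_normal(n) * cfg.area_noise_sd
    circ_noise = rng.standard_normal(n) * cfg.circularity_noise_sd

    observations = []
    for i, t in enumerate(obs_times):
        tr = round(float(t), 9)
        if tr in fluor_set:
            kind = "fluorescence"
            if is_donor:
                area = cfg.donor_area_um2
                circ = cfg.donor_circularity
            else:
                area = max(cfg.area_floor_um2,
                           cfg.area_baseline_um2 + cfg.area_coef * d_area[i]
                           + area_noise[i])
                circ = float(np.clip(
                    cfg.circularity_baseline - cfg.circularity_coef * d_circ[i]
                    + circ_noise[i],
                    0.05, 1.0,
                ))
            perimeter = math.sqrt(4.0 * math.pi * area / circ)
            fluor = float(content[i])
        else:
            kind = "centroid-only" if tr in centroid_set else "phase"
            area = perimeter = fluor = None
        observations.append(
            Observation(
                time=float(t),
                centroid_x=float(xs[i]),
                centroid_y=float(ys[i]),
                area=area,
                perimeter=perimeter,
                fluorescence=fluor,
                frame_kind=kind,
            )
        )

    cell = TrackedCell(
        cell_id=state.cell_id,
        experiment_id="",  # filled by caller
        cell_type=state.cell_type,
        condition="co-culture",
        generation=state.generation,
        parent_id=state.parent_id,
        birth_time=state.birth_time,
        end_time=float(end_time),
        fate=fate,
        observations=observations,
    )

    final_content = float(content[-1])
    truth = {
        "cell_id": state.cell_id,
        "cell_type": state.cell_type,
        "generation": state.generation,
        "fate": fate,
        "propensity": state.propensity,
        "content_birth": state.content,
        "content_end": final_content,
        "driver_area_end": float(d_area[-1]),
        "driver_circularity_end": float(d_circ[-1]),
        "driver_velocity_end": float(d_vel[-1]),
    }

    daughters: list[_CellState] = []
    if fate == "divided":
        # division-level draws still come from the mother's stream
        z_shared = rng.standard_normal()
        z_ind = rng.standard_normal(2)
        rho = cfg.sister_propensity_corr
        shares = (cfg.split_fraction, 1.0 - cfg.split_fraction)
        for j in (0, 1):
            if is_donor:
                prop = 0.0
            else:
                z = math.sqrt(rho) * z_shared + math.sqrt(1.0 - rho) * z_ind[j]
                prop = cfg.uptake_median * math.exp(cfg.uptake_log_sd * z)
            daughters.append(
                _CellState(
                    cell_id=f"{state.cell_id}.{j + 1}",
                    cell_type=state.cell_type,
                    generation=state.generation + 1,
                    parent_id=state.cell_id,
                    birth_time=float(end_time),
                    start_time=float(end_time),
                    content=final_content * shares[j],
                    propensity=prop,
                    # inherit mode: daughters start from the mother's final
                    # driver value (per phenotype this base is only used
                    # when that phenotype's switch is "inherit")
                    driver_inherit_base=state.driver_inherit_base
                    + float(uptake[-1]),
                    position=(xs[-1], ys[-1]),
                )
            )
    return cell, truth, daughters


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[LineageForest, pd.DataFrame]:
    """Run one experiment; returns the lineage forest and per-cell truth.

    Identical configs (including seed) produce identical output.
    """
    config.validate()
    forest = LineageForest(
        experiment_id=config.experiment_id,
        experiment_duration=config.duration_days,
    )
    rng0 = np.random.default_rng([config.seed & 0x7FFFFFFF, 0xC0FFEE])
    queue: list[_CellState] = []
    for i in range(config.n_start_acceptors):
        cid = f"SA{i:03d}"
        crng = _cell_rng(config.seed, cid + "#init")
        baseline = config.baseline_fluorescence_median * math.exp(
            config.baseline_fluorescence_log_sd * crng.standard_normal()
        ) if config.baseline_fluorescence_median > 0 else 0.0
        prop = config.uptake_median * math.exp(
            config.uptake_log_sd * crng.standard_normal()
        ) if config.uptake_median > 0 else 0.0
        queue.append(
            _CellState(
                cell_id=cid, cell_type="SAOS-2", generation=0, parent_id=None,
                birth_time=None, start_time=0.0, content=baseline,
                propensity=prop, driver_inherit_base=baseline,
                position=(
                    crng.uniform(0, config.field_width_um),
                    crng.uniform(0, config.field_height_um),
                ),
            )
        )
    for i in range(config.n_start_donors):
        cid = f"HD{i:03d}"
        crng = _cell_rng(config.seed, cid + "#init")
        bright = config.donor_fluorescence_median * math.exp(
            config.donor_fluorescence_log_sd * crng.standard_normal()
        )
        queue.append(
            _CellState(
                cell_id=cid, cell_type="HDF", generation=0, parent_id=None,
                birth_time=None, start_time=0.0, content=bright,
                propensity=0.0, driver_inherit_base=bright,
                position=(
                    crng.uniform(0, config.field_width_um),
                    crng.uniform(0, config.field_height_um),
                ),
            )
        )
    del rng0

    truth_rows = []
    while queue:
        state = queue.pop()
        cell, truth, daughters = _simulate_cell(state, config)
        cell.experiment_id = config.experiment_id
        forest.add(cell)
        truth_rows.append(truth)
        queue.extend(daughters)
        if len(forest) > _POPULATION_GUARD:
            raise RuntimeError("population guard tripped during simulation")

    truth_df = (
        pd.DataFrame(truth_rows).sort_values("cell_id").reset_index(drop=True)
    )
    return forest, truth_df


def simulate_batch(
    seed: int,
    n_experiments: int = 7,
    durations_days: Optional[tuple[float, ...]] = None,
    workdir: Optional[Path] = None,
    **overrides,
) -> dict[str, LineageForest]:
    """Simulate a batch of experiments (default: the 7-experiment design).

    Every forest is written to the track-table schema and read back, so
    the file round-trip is exercised end to end rather than short-cutting
    through memory. ``overrides`` are applied to every experiment's
    :class:`SimulationConfig`.
    """
    from . import io as _io  # deferred: io imports model only

    if durations_days is None:
        durations_days = STUDY_DURATIONS_DAYS
    labels = [
        EXPERIMENT_LABELS[i] if i < len(EXPERIMENT_LABELS) else f"x{i}"
        for i in range(n_experiments)
    ]
    import tempfile

    forests: dict[str, LineageForest] = {}
    with tempfile.TemporaryDirectory() as tmp:
        base = Path(workdir) if workdir is not None else Path(tmp)
        base.mkdir(parents=True, exist_ok=True)
        for i, label in enumerate(labels):
            kwargs = {
                "seed": (seed * 1009 + i * 101) % (2**31 - 1),
                "experiment_id": label,
                "duration_days": durations_days[i % len(durations_days)],
            }
            kwargs.update(overrides)  # explicit overrides win
            cfg = SimulationConfig(**kwargs)
            forest, _ = simulate_experiment(cfg)
            path = _io.write_track_table(forest, base / f"tracks_{label}.csv")
            forests[label] = _io.read_track_table(path)[label]
    return forests


def render_image_fixture(
    cells: list[dict],
    field_shape: tuple[int, int],
    pixel_size: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render cells as filled ellipses into a label mask and red image.

    Each cell dict needs ``cy, cx`` (pixels), ``a, b`` (semi-axes,
    pixels), optional ``angle`` (radians) and ``fluorescence`` (total
    intensity, distributed uniformly over the cell's pixels before
    noise). Overlapping ellipses are resolved deterministically by list
    order (later cells overwrite) with a warning.
    """
    from skimage.draw import ellipse as _ellipse

    mask = np.zeros(field_shape, dtype=np.int32)
    rng = np.random.default_rng(seed)
    overlapped = False
    for label, cell in enumerate(cells, start=1):
        rr, cc = _ellipse(
            cell["cy"], cell["cx"], cell["a"], cell["b"],
            shape=field_shape, rotation=cell.get("angle", 0.0),
        )
        if np.any(mask[rr, cc] != 0):
            overlapped = True
        mask[rr, cc] = label
    if overlapped:
        warnings.warn(
            "overlapping ellipses resolved by z-order (later cells on top)",
            stacklevel=2,
        )
    image = np.zeros(field_shape, dtype=float)
    for label, cell in enumerate(cells, start=1):
        sel = mask == label
        n_px = int(sel.sum())
        if n_px:
            image[sel] = cell.get("fluorescence", 0.0) / n_px
    if noise_sd > 0:
        image = image + rng.normal(0.0, noise_sd, field_shape)
    return mask, image
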