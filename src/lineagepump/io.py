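"""Reading and writing track tables, raster fixtures and run configuration.

Track tables are long ("tidy") CSV/TSV files with one row per
(cell, observation); cell-level columns are repeated on every row of that
cell. Times are stored in hours, coordinates in micrometres, with empty
cells (never sentinel numbers) for absent values. This layout is a semantic
mirror of the per-cell spreadsheets produced by manual tracking tools: each
spreadsheet row corresponds to one segmented/sampled time point of one cell.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .model import (
    LineageForest,
    Observation,
    TrackedCell,
    validate_lineage_forest,
)

__all__ = [
    "TRACK_TABLE_COLUMNS",
    "TrackTableError",
    "SchemaError",
    "LinkError",
    "OrderError",
    "read_track_table",
    "write_track_table",
    "read_mask_and_image",
    "load_config",
]

#: Fixed column order of the track-table schema.
TRACK_TABLE_COLUMNS = (
    "experiment_id",
    "cell_id",
    "cell_type",
    "condition",
    "generation",
    "parent_id",
    "fate",
    "birth_time_h",
    "end_time_h",
    "time_h",
    "x_um",
    "y_um",
    "area_um2",
    "perimeter_um",
    "fluor_raw",
    "frame_kind",
)

_CELL_LEVEL = TRACK_TABLE_COLUMNS[:9]
_FLOAT_FMT = "%.9g"


class TrackTableError(ValueError):
    """Base class for track-table I/O failures."""


class SchemaError(TrackTableError):
    pass


class LinkError(TrackTableError):
    pass


class OrderError(TrackTableError):
    pass


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)


def read_track_table(
    path: Union[str, Path],
    dialect: str = "csv",
    validate: bool = True,
) -> dict[str, LineageForest]:
    """Read a track table into one :class:`LineageForest` per experiment.

    Raises :class:`SchemaError` for missing columns, :class:`LinkError` for
    unresolvable parent links, :class:`OrderError` for non-monotone
    observation times, and :class:`TrackTableError` listing every violated
    invariant when ``validate`` is true.
    """
    sep = {"csv": ",", "tsv": "\t"}[dialect]
    df = pd.read_csv(path, sep=sep, dtype={"cell_id": str, "parent_id": str,
                                           "experiment_id": str})
    missing = [c for c in TRACK_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    forests: dict[str, LineageForest] = {}
    for (exp_id, cell_id), rows in df.groupby(["experiment_id", "cell_id"], sort=True):
        forest = forests.setdefault(exp_id, LineageForest(experiment_id=exp_id))
        first = rows.iloc[0]
        parent_id = first["parent_id"]
        if isinstance(parent_id, float) and math.isnan(parent_id):
            parent_id = None
        cell = TrackedCell(
            cell_id=str(cell_id),
            experiment_id=str(exp_id),
            cell_type=str(first["cell_type"]),
            condition=str(first["condition"]),
            generation=int(first["generation"]),
            parent_id=parent_id,
            fate=str(first["fate"]),
            birth_time=_opt_float(first["birth_time_h"]),
            end_time=float(first["end_time_h"]),
        )
        times = rows["time_h"].to_numpy(dtype=float)
        if np.any(np.diff(times) <= 0):
            raise OrderError(
                f"cell {cell_id!r} in experiment {exp_id!r}: "
                "observation times are not strictly increasing"
            )
        for _, row in rows.iterrows():
            cell.observations.append(
                Observation(
                    time=float(row["time_h"]),
                    centroid_x=float(row["x_um"]),
                    centroid_y=float(row["y_um"]),
                    area=_opt_float(row["area_um2"]),
                    perimeter=_opt_float(row["perimeter_um"]),
                    fluorescence=_opt_float(row["fluor_raw"]),
                    frame_kind=str(row["frame_kind"]),
                )
            )
        forest.add(cell)

    for forest in forests.values():
        for cell in forest:
            if cell.parent_id is not None and cell.parent_id not in forest.cells:
                raise LinkError(
                    f"cell {cell.cell_id!r} in experiment "
                    f"{forest.experiment_id!r} references unknown parent "
                    f"{cell.parent_id!r}"
                )
        forest.experiment_duration = (
            max(c.end_time for c in forest) / 24.0 if len(forest) else None
        )

    if validate:
        problems = []
        for forest in forests.values():
            for issue in validate_lineage_forest(forest):
                if issue.severity == "error":
                    problems.append(f"{forest.experiment_id}/{issue.cell_id}: "
                                    f"[{issue.rule}] {issue.message}")
        if problems:
            raise TrackTableError(
                "track table violates lineage invariants:\n  " + "\n  ".join(problems)
            )
    return forests


def _fmt(value: Optional[float]) -> str:
    if value is None:
        return ""
    return _FLOAT_FMT % value


def write_track_table(
    forests: Union[LineageForest, dict[str, LineageForest]],
    path: Union[str, Path],
    dialect: str = "csv",
) -> Path:
    """Write forests as a track table with deterministic row order.

    Rows are sorted by (experiment_id, cell_id, time_h); floats are printed
    with 9 significant digits so that write -> read -> write is
    byte-identical.
    """
    if isinstance(forests, LineageForest):
        forests = {forests.experiment_id: forests}
    sep = {"csv": ",", "tsv": "\t"}[dialect]
    path = Path(path)
    lines = [sep.join(TRACK_TABLE_COLUMNS)]
    for exp_id in sorted(forests):
        forest = forests[exp_id]
        for cell_id in sorted(forest.cells):
            cell = forest.cells[cell_id]
            prefix = [
                exp_id,
                cell.cell_id,
                cell.cell_type,
                cell.condition,
                str(cell.generation),
                cell.parent_id or "",
                cell.fate,
                _fmt(cell.birth_time),
                _fmt(cell.end_time),
            ]
            for obs in cell.observations:
                lines.append(sep.join(prefix + [
                    _fmt(obs.time),
                    _fmt(obs.centroid_x),
                    _fmt(obs.centroid_y),
                    _fmt(obs.area),
                    _fmt(obs.perimeter),
                    _fmt(obs.fluorescence),
                    obs.frame_kind,
                ]))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def read_mask_and_image(
    mask_path: Union[str, Path],
    image_path: Union[str, Path],
    pixel_size: float,
) -> tuple[list[np.ndarray], np.ndarray, float]:
    """Load a segmentation mask and its fluorescence image.

    Labelled masks are split into one binary mask per label (sorted by
    label). Returns ``(masks, intensity, pixel_size)``.
    """
    if pixel_size <= 0:
        raise ValueError(f"pixel_size must be positive, got {pixel_size}")
    import imageio.v3 as iio

    mask = np.asarray(iio.imread(mask_path))
    image = np.asarray(iio.imread(image_path))
    if mask.shape != image.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match image shape {image.shape}"
        )
    labels = np.unique(mask)
    labels = labels[labels > 0]
    masks = [(mask == lab) for lab in labels]
    return masks, image.astype(float), float(pixel_size)


def load_config(path: Union[str, Path]) -> dict:
    """Load a YAML run configuration as a plain dict."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}
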