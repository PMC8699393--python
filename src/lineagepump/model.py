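"""Domain model for single-cell lineage tracking of co-cultured populations.

A tracked experiment is represented as a :class:`LineageForest`: a set of
:class:`TrackedCell` objects linked mother -> daughters across generations.
Cells present at the first frame form the *starting generation* (generation 0);
each observed mitosis produces exactly two daughters of the next generation.
Every cell carries a time-ordered series of :class:`Observation` records taken
on three interleaved acquisition grids (phase contrast every 0.25 h, centroid
sampling every 2 h, fluorescence every 4 h).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Optional

__all__ = [
    "Observation",
    "TrackedCell",
    "LineageForest",
    "ValidationIssue",
    "validate_lineage_forest",
    "sister_pairs",
    "FATES",
    "FRAME_KINDS",
    "PHASE_INTERVAL_H",
    "CENTROID_INTERVAL_H",
    "FLUORESCENCE_INTERVAL_H",
    "generation_label",
]

#: Acquisition grid spacings, in hours.
PHASE_INTERVAL_H = 0.25
CENTROID_INTERVAL_H = 2.0
FLUORESCENCE_INTERVAL_H = 4.0

FATES = ("divided", "incomplete-division", "apoptosis", "incomplete")
FRAME_KINDS = ("phase", "fluorescence", "centroid-only")

#: Tolerance for daughters' birth time vs mother's end time: one phase frame.
BIRTH_TIME_TOL_H = PHASE_INTERVAL_H

_GENERATION_LABELS = ("starting", "first", "second", "third", "fourth", "fifth")


def generation_label(generation: int) -> str:
    """Display name for an internal generation number (0 -> 'starting')."""
    if 0 <= generation < len(_GENERATION_LABELS):
        return _GENERATION_LABELS[generation]
    return f"generation-{generation}"


@dataclass
class Observation:
    """A single time-stamped measurement of one cell.

    Parameters
    ----------
    time : float
        Hours since the start of the experiment (>= 0).
    centroid_x, centroid_y : float
        Cell centroid in micrometres, image convention (origin top-left,
        y increasing downward).
    area : float, optional
        Cell-profile area in um^2 (fluorescence frames only).
    perimeter : float, optional
        Cell peripheral circumference in um.
    fluorescence : float, optional
        Summed donor-label pixel intensity over the segmented profile;
        raw (arbitrary) units until the forest is normalized.
    frame_kind : str
        One of ``phase``, ``fluorescence``, ``centroid-only``.
    """

    time: float
    centroid_x: float
    centroid_y: float
    area: Optional[float] = None
    perimeter: Optional[float] = None
    fluorescence: Optional[float] = None
    frame_kind: str = "phase"

    @property
    def circularity(self) -> Optional[float]:
        """4*pi*area / perimeter**2, when both measures are present."""
        if self.area is None or self.perimeter is None:
            return None
        return 4.0 * math.pi * self.area / self.perimeter**2


@dataclass
class TrackedCell:
    """One tracked cell with its lineage links, fate and observation series."""

    cell_id: str
    experiment_id: str
    cell_type: str  # "SAOS-2" (acceptor) or "HDF" (donor)
    condition: str  # "co-culture" or "control"
    generation: int
    fate: str
    end_time: float
    parent_id: Optional[str] = None
    birth_time: Optional[float] = None
    observations: list[Observation] = field(default_factory=list)

    @property
    def first_time(self) -> Optional[float]:
        return self.observations[0].time if self.observations else None

    @property
    def last_time(self) -> Optional[float]:
        return self.observations[-1].time if self.observations else None

    @property
    def observation_days(self) -> Optional[float]:
        """Span from first to last observation, in days."""
        if len(self.observations) < 2:
            return None
        return (self.observations[-1].time - self.observations[0].time) / 24.0

    def fluorescence_observations(self) -> list[Observation]:
        return [o for o in self.observations if o.frame_kind == "fluorescence"]


@dataclass
class LineageForest:
    """All tracked cells of one experiment, keyed by ``cell_id``."""

    experiment_id: str
    cells: dict[str, TrackedCell] = field(default_factory=dict)
    experiment_duration: Optional[float] = None  # days
    normalized: bool = False
    normalization_factor: Optional[float] = None

    def __iter__(self) -> Iterator[TrackedCell]:
        return iter(self.cells.values())

    def __len__(self) -> int:
        return len(self.cells)

    def add(self, cell: TrackedCell) -> None:
        if cell.cell_id in self.cells:
            raise ValueError(f"duplicate cell_id {cell.cell_id!r}")
        self.cells[cell.cell_id] = cell

    def daughters_of(self, cell_id: str) -> list[TrackedCell]:
        return sorted(
            (c for c in self.cells.values() if c.parent_id == cell_id),
            key=lambda c: c.cell_id,
        )

    def mother_of(self, cell: TrackedCell) -> Optional[TrackedCell]:
        if cell.parent_id is None:
            return None
        return self.cells.get(cell.parent_id)

    def sister_of(self, cell: TrackedCell) -> Optional[TrackedCell]:
        if cell.parent_id is None:
            return None
        for other in self.daughters_of(cell.parent_id):
            if other.cell_id != cell.cell_id:
                return other
        return None


@dataclass(frozen=True)
class ValidationIssue:
    cell_id: str
    rule: str
    severity: str  # "error" or "warning"
    message: str


def _check_cell(cell: TrackedCell, issues: list[ValidationIssue]) -> None:
    if cell.fate not in FATES:
        issues.append(
            ValidationIssue(cell.cell_id, "fate", "error", f"unknown fate {cell.fate!r}")
        )
    has_parent = cell.parent_id is not None
    has_birth = cell.birth_time is not None
    if (cell.generation == 0) != (not has_parent):
        issues.append(
            ValidationIssue(
                cell.cell_id,
                "generation-parent",
                "error",
                "generation 0 iff parent_id absent is violated",
            )
        )
    if has_parent != has_birth:
        issues.append(
            ValidationIssue(
                cell.cell_id,
                "birth-parent",
                "error",
                "birth_time must be present exactly when parent_id is",
            )
        )
    if has_birth and cell.end_time < cell.birth_time - 1e-9:
        issues.append(
            ValidationIssue(
                cell.cell_id, "end-before-birth", "error",
                f"end_time {cell.end_time} < birth_time {cell.birth_time}",
            )
        )
    times = [o.time for o in cell.observations]
    if any(t < 0 for t in times):
        issues.append(
            ValidationIssue(cell.cell_id, "negative-time", "error", "observation before t=0")
        )
    if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
        issues.append(
            ValidationIssue(
                cell.cell_id, "time-order", "error",
                "observations are not strictly time-increasing",
            )
        )
    for obs in cell.observations:
        if obs.frame_kind not in FRAME_KINDS:
            issues.append(
                ValidationIssue(
                    cell.cell_id, "frame-kind", "error",
                    f"unknown frame_kind {obs.frame_kind!r}",
                )
            )
        if obs.fluorescence is not None and obs.frame_kind != "fluorescence":
            issues.append(
                ValidationIssue(
                    cell.cell_id, "fluorescence-frame", "error",
                    f"fluorescence value on a {obs.frame_kind!r} frame at t={obs.time}",
                )
            )
        if obs.area is not None and obs.perimeter is not None:
            circ = 4.0 * math.pi * obs.area / obs.perimeter**2
            # stored circularity is derived, so only sanity-check positivity
            if obs.area <= 0 or obs.perimeter <= 0 or circ <= 0:
                issues.append(
                    ValidationIssue(
                        cell.cell_id, "shape-positive", "error",
                        f"non-positive shape measure at t={obs.time}",
                    )
                )


def validate_lineage_forest(forest: LineageForest) -> list[ValidationIssue]:
    """Check every forest invariant; return a report of violations.

    The forest is never mutated and violations never raise: an empty report
    means all invariants hold.
    """
    issues: list[ValidationIssue] = []
    for cell in forest:
        _check_cell(cell, issues)
        if cell.parent_id is not None:
            mother = forest.cells.get(cell.parent_id)
            if mother is None:
                issues.append(
                    ValidationIssue(
                        cell.cell_id, "parent-link", "error",
                        f"parent_id {cell.parent_id!r} not in forest",
                    )
                )
            else:
                if cell.generation != mother.generation + 1:
                    issues.append(
                        ValidationIssue(
                            cell.cell_id, "generation-increment", "error",
                            f"generation {cell.generation} but mother is "
                            f"generation {mother.generation}",
                        )
                    )
                if (
                    cell.birth_time is not None
                    and abs(cell.birth_time - mother.end_time) > BIRTH_TIME_TOL_H + 1e-9
                ):
                    issues.append(
                        ValidationIssue(
                            cell.cell_id, "birth-time", "error",
                            f"birth_time {cell.birth_time} differs from mother end_time "
                            f"{mother.end_time} by more than one phase frame",
                        )
                    )
    for cell in forest:
        daughters = forest.daughters_of(cell.cell_id)
        if cell.fate == "divided" and len(daughters) != 2:
            issues.append(
                ValidationIssue(
                    cell.cell_id, "two-daughters", "error",
                    f"fate=divided but {len(daughters)} daughter(s) found",
                )
            )
        if cell.fate != "divided" and daughters:
            issues.append(
                ValidationIssue(
                    cell.cell_id, "daughters-without-division", "error",
                    f"fate={cell.fate} but {len(daughters)} daughter(s) found",
                )
            )
    return issues


def sister_pairs(forest: LineageForest) -> list[tuple[str, str]]:
    """All sister-cell pairs, one per divided mother.

    Pairs are ordered lexicographically by ``cell_id`` within each pair, and
    the list itself is sorted by the first member. Starting-generation cells
    never appear (sisters only exist from the first generation on).
    """
    pairs: list[tuple[str, str]] = []
    for cell in forest:
        if cell.fate == "divided":
            daughters = forest.daughters_of(cell.cell_id)
            if len(daughters) == 2:
                a, b = sorted(d.cell_id for d in daughters)
                pairs.append((a, b))
    return sorted(pairs)
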