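"""Lineage-aware fluorescence accounting.

Two per-cell summaries of donor-label receipt are computed:

* ``Fa`` — absolute fluorescence: the cell's normalized fluorescence at its
  final fluorescence frame (the frame at or immediately before its end
  event).
* ``Fmc`` — mother-compensated fluorescence: ``Fa`` plus half of the
  immediate mother's ``Fa``, restoring the share of the mother's label that
  went to the sister at division. Starting-generation cells have
  ``Fmc = Fa``. Compensation deliberately stops at one generation:
  measurement variance swamps deeper corrections.

Because mitosis is asynchronous and cells are observed for very different
spans, comparisons between dividing and non-dividing cells use uptake
*rates* (``Fa/day``, ``Fmc/day``) over each cell's observation span.

All values are expressed in normalized fluorescence units: the median
first-frame fluorescence of co-cultured acceptor cells in the starting
generation defines 100 units.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .model import LineageForest, TrackedCell

__all__ = [
    "FluorescenceAccount",
    "NormalizationError",
    "normalize_fluorescence",
    "compute_Fa",
    "compute_Fmc",
    "compute_rates",
    "build_accounts",
    "NORMALIZED_REFERENCE_MEDIAN",
]

logger = logging.getLogger(__name__)

NORMALIZED_REFERENCE_MEDIAN = 100.0


class NormalizationError(ValueError):
    pass


@dataclass
class FluorescenceAccount:
    """Per-cell fluorescence summary in normalized units."""

    cell_id: str
    Fa: float
    Fmc: Optional[float] = None
    observation_days: Optional[float] = None
    Fa_rate: Optional[float] = None
    Fmc_rate: Optional[float] = None


def _reference_value(cell: TrackedCell, reference: str) -> Optional[float]:
    frames = cell.fluorescence_observations()
    if not frames:
        return None
    obs = frames[0] if reference == "first" else frames[-1]
    return obs.fluorescence


def normalize_fluorescence(
    forest: LineageForest,
    reference: str = "first",
    acceptor_type: str = "SAOS-2",
) -> LineageForest:
    """Rescale all fluorescence values to normalized units.

    The reference set is the co-cultured acceptor cells of the starting
    generation; each contributes one value (its first fluorescence-frame
    value by default, or its final one with ``reference="final"``). The
    scale factor is ``100 / median(reference values)``, so the reference
    median is exactly 100 after scaling. Normalization is idempotent and
    scale-invariant; the input forest is not mutated.
    """
    if reference not in ("first", "final"):
        raise ValueError(f"reference must be 'first' or 'final', got {reference!r}")
    ref_values = [
        v
        for cell in forest
        if cell.generation == 0
        and cell.cell_type == acceptor_type
        and cell.condition == "co-culture"
        and (v := _reference_value(cell, reference)) is not None
    ]
    if not ref_values:
        raise NormalizationError(
            "no starting-generation co-cultured acceptor cell with a "
            "fluorescence observation"
        )
    median = float(np.median(ref_values))
    if median <= 0:
        raise NormalizationError(
            f"degenerate reference median {median}; cannot normalize"
        )
    factor = NORMALIZED_REFERENCE_MEDIAN / median
    out = copy.deepcopy(forest)
    for cell in out:
        for obs in cell.observations:
            if obs.fluorescence is not None:
                obs.fluorescence *= factor
    out.normalized = True
    out.normalization_factor = (forest.normalization_factor or 1.0) * factor
    return out


def compute_Fa(cell: TrackedCell) -> Optional[float]:
    """Fluorescence at the cell's final fluorescence frame, or None.

    None marks a cell with no fluorescence frame inside its lifetime (born
    and ended between two frames of the 4-h grid); such cells are excluded
    downstream and logged.
    """
    frames = cell.fluorescence_observations()
    if not frames:
        logger.debug("cell %s has no fluorescence frame; Fa undefined", cell.cell_id)
        return None
    return frames[-1].fluorescence


def compute_Fmc(cell: TrackedCell, mother_Fa: Optional[float]) -> float:
    """``Fa + mother_Fa/2`` for daughters, ``Fa`` for the starting generation."""
    fa = compute_Fa(cell)
    if fa is None:
        raise ValueError(f"cell {cell.cell_id}: Fa undefined, cannot compute Fmc")
    if cell.generation == 0:
        return fa
    if mother_Fa is None:
        raise ValueError(
            f"cell {cell.cell_id}: generation {cell.generation} requires the "
            "mother's Fa"
        )
    return fa + mother_Fa / 2.0


def compute_rates(
    account: FluorescenceAccount, observation_days: float
) -> FluorescenceAccount:
    """Fill in Fa/day (and Fmc/day) over the cell's observation span."""
    if observation_days <= 0:
        raise ValueError(
            f"observation_days must be positive, got {observation_days}"
        )
    account.observation_days = observation_days
    account.Fa_rate = account.Fa / observation_days
    if account.Fmc is not None:
        account.Fmc_rate = account.Fmc / observation_days
    return account


def build_accounts(
    forest: LineageForest,
    acceptor_type: str = "SAOS-2",
    condition: str = "co-culture",
) -> dict[str, FluorescenceAccount]:
    """Fa, Fmc and uptake rates for every eligible acceptor cell.

    Cells without a fluorescence frame, or whose mother lacks one, are
    skipped (logged); rates are left unset for cells observed at a single
    time point.
    """
    accounts: dict[str, FluorescenceAccount] = {}
    n_skipped = 0
    for cell in forest:
        if cell.cell_type != acceptor_type or cell.condition != condition:
            continue
        fa = compute_Fa(cell)
        if fa is None:
            n_skipped += 1
            continue
        mother = forest.mother_of(cell)
        mother_fa = compute_Fa(mother) if mother is not None else None
        if cell.generation > 0 and mother_fa is None:
            logger.info(
                "cell %s: mother has no usable fluorescence frame; Fmc undefined",
                cell.cell_id,
            )
            fmc = None
        else:
            fmc = compute_Fmc(cell, mother_fa)
        account = FluorescenceAccount(cell_id=cell.cell_id, Fa=fa, Fmc=fmc)
        days = cell.observation_days
        if days is not None and days > 0:
            compute_rates(account, days)
        accounts[cell.cell_id] = account
    if n_skipped:
        logger.info(
            "experiment %s: %d acceptor cell(s) without a fluorescence frame "
            "excluded from accounting",
            forest.experiment_id,
            n_skipped,
        )
    return accounts


def accounts_table(accounts: dict[str, FluorescenceAccount]) -> pd.DataFrame:
    """Accounts as a tidy DataFrame sorted by cell_id."""
    rows = [
        {
            "cell_id": a.cell_id,
            "Fa": a.Fa,
            "Fmc": a.Fmc,
            "observation_days": a.observation_days,
            "Fa_rate": a.Fa_rate,
            "Fmc_rate": a.Fmc_rate,
        }
        for a in accounts.values()
    ]
    return pd.DataFrame(rows).sort_values("cell_id").reset_index(drop=True)
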