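"""Association statistics for phenotype vs fluorescence receipt.

All correlations use Kendall's tau-b (tie corrected — areas, circularities
and fluorescence values contain ties after measurement rounding), with a
two-sided p-value from the normal approximation with tie-adjusted variance
and continuity correction. Group comparisons use the two-sided
Mann-Whitney U test; cross-experiment summaries use one-sample or paired
Wilcoxon tests. Significance is read at p < 0.05, two-sided; no
multiple-testing correction is applied.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .fluorescence import FluorescenceAccount
from .migration import migration_velocity, path_from_observations, resample_to_grid
from .model import LineageForest, sister_pairs

__all__ = [
    "KendallTauResult",
    "CorrelationResult",
    "MitosisComparison",
    "kendall_tau",
    "cell_feature_table",
    "correlate_by_generations",
    "sister_pair_differences",
    "compare_dividing_vs_nondividing",
    "cross_experiment_summary",
    "LOW_N_THRESHOLD",
]

logger = logging.getLogger(__name__)

LOW_N_THRESHOLD = 5
PHENOTYPES = ("area", "circularity", "velocity")
FLUOR_KINDS = ("Fa", "Fmc")


@dataclass(frozen=True)
class KendallTauResult:
    tau: float
    p_value: float
    n: int

    @property
    def is_defined(self) -> bool:
        return not math.isnan(self.tau)


@dataclass(frozen=True)
class CorrelationResult:
    experiment_id: str
    phenotype: str
    fluorescence_kind: str
    grouping: tuple[int, ...]
    grouping_label: str
    n: int
    tau: float
    p_value: float
    low_n: bool


@dataclass(frozen=True)
class MitosisComparison:
    experiment_id: str
    n_dividing: int
    n_nondividing: int
    median_Fa_rate_dividing: float
    median_Fa_rate_nondividing: float
    pFa: float
    p_value_Fa: float
    median_Fmc_rate_dividing: Optional[float]
    median_Fmc_rate_nondividing: Optional[float]
    pFmc: Optional[float]
    p_value_Fmc: Optional[float]


def _tie_sums(values: np.ndarray) -> tuple[float, float, float]:
    _, counts = np.unique(values, return_counts=True)
    t = counts[counts > 1].astype(float)
    return (
        float(np.sum(t * (t - 1) / 2.0)),
        float(np.sum(t * (t - 1) * (2 * t + 5))),
        float(np.sum(t * (t - 1) * (t - 2))),
    )


def kendall_tau(x: Sequence[float], y: Sequence[float]) -> KendallTauResult:
    """Kendall's tau-b with a tie-adjusted, continuity-corrected p-value.

    Returns ``tau = nan`` (undefined-correlation marker) when either input
    is constant. The point estimate matches a brute-force enumeration of
    all pairs with tau-b tie normalization.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    n = len(x)
    if n < 2:
        raise ValueError("kendall_tau requires at least 2 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return KendallTauResult(tau=float("nan"), p_value=float("nan"), n=n)

    tau = float(sps.kendalltau(x, y).statistic)

    # S statistic recovered from tau-b and the tie structure; p-value from
    # the normal approximation with tie-adjusted variance (Kendall's
    # variance formula) and a +-1 continuity correction on S.
    n0 = n * (n - 1) / 2.0
    n1, vx, tx3 = _tie_sums(x)
    n2, vy, ty3 = _tie_sums(y)
    denom = math.sqrt((n0 - n1) * (n0 - n2))
    s = round(tau * denom)
    var_s = (n * (n - 1) * (2 * n + 5) - vx - vy) / 18.0
    if n > 2:
        var_s += tx3 * ty3 / (9.0 * n * (n - 1) * (n - 2))
    var_s += (n1 * 2.0) * (n2 * 2.0) / (2.0 * n * (n - 1))
    if var_s <= 0:
        return KendallTauResult(tau=tau, p_value=float("nan"), n=n)
    z = (abs(s) - 1.0) / math.sqrt(var_s) if s != 0 else 0.0
    z = max(z, 0.0)
    p = 2.0 * sps.norm.sf(z)
    return KendallTauResult(tau=tau, p_value=min(p, 1.0), n=n)


def cell_feature_table(
    forest: LineageForest,
    accounts: dict[str, FluorescenceAccount],
    acceptor_type: str = "SAOS-2",
    condition: str = "co-culture",
    velocity_interval_h: float = 2.0,
    include_short_tracks: bool = True,
) -> pd.DataFrame:
    """One row per eligible acceptor cell with its phenotype measures.

    ``area`` and ``circularity`` are taken at the cell's final fluorescence
    frame, the same frame that defines Fa, mirroring the one-row-per-cell
    analysis; ``velocity`` is the mean migration velocity over the
    resampled centroid path.
    """
    rows = []
    for cell_id in sorted(forest.cells):
        cell = forest.cells[cell_id]
        if cell.cell_type != acceptor_type or cell.condition != condition:
            continue
        account = accounts.get(cell_id)
        frames = cell.fluorescence_observations()
        final = frames[-1] if frames else None
        velocity = None
        short = False
        if len(cell.observations) >= 2:
            res = resample_to_grid(
                path_from_observations(cell.observations), velocity_interval_h
            )
            if not res.degenerate and len(res.path) >= 2:
                short = res.short_track
                if include_short_tracks or not res.short_track:
                    velocity = migration_velocity(res.path)
        rows.append(
            {
                "cell_id": cell_id,
                "generation": cell.generation,
                "fate": cell.fate,
                "Fa": account.Fa if account else None,
                "Fmc": account.Fmc if account else None,
                "Fa_rate": account.Fa_rate if account else None,
                "Fmc_rate": account.Fmc_rate if account else None,
                "observation_days": cell.observation_days,
                "area": final.area if final else None,
                "circularity": final.circularity if final else None,
                "velocity": velocity,
                "short_track": short,
            }
        )
    return pd.DataFrame(rows)


def _groupings(generations: Sequence[int]) -> list[tuple[str, tuple[int, ...]]]:
    gens = sorted(set(generations))
    out: list[tuple[str, tuple[int, ...]]] = []
    for g in gens:
        out.append((f"generation-{g}", (g,)))
    for k in range(2, len(gens) + 1):
        out.append(("generations-" + "+".join(map(str, gens[:k])), tuple(gens[:k])))
    out.append(("all", tuple(gens)))
    return out


def correlate_by_generations(
    features: pd.DataFrame,
    phenotype: str,
    fluorescence_kind: str,
    experiment_id: str = "",
) -> list[CorrelationResult]:
    """Kendall correlations for each generation, cumulative groups, and all.

    Cells missing either measure are excluded (and counted in the log).
    Groupings with fewer than 5 usable cells are flagged ``low_n`` but
    still reported.
    """
    usable = features.dropna(subset=[phenotype, fluorescence_kind])
    n_excluded = len(features) - len(usable)
    if n_excluded:
        logger.info(
            "%s/%s vs %s: %d cell(s) with missing values excluded",
            experiment_id, phenotype, fluorescence_kind, n_excluded,
        )
    results: list[CorrelationResult] = []
    if usable.empty:
        logger.info("%s: no eligible cells for %s vs %s",
                    experiment_id, phenotype, fluorescence_kind)
        return results
    for label, gens in _groupings(usable["generation"].tolist()):
        sub = usable[usable["generation"].isin(gens)]
        if len(sub) < 2:
            continue
        kt = kendall_tau(sub[phenotype].to_numpy(), sub[fluorescence_kind].to_numpy())
        results.append(
            CorrelationResult(
                experiment_id=experiment_id,
                phenotype=phenotype,
                fluorescence_kind=fluorescence_kind,
                grouping=gens,
                grouping_label=label,
                n=kt.n,
                tau=kt.tau,
                p_value=kt.p_value,
                low_n=kt.n < LOW_N_THRESHOLD,
            )
        )
    return results


def sister_pair_differences(
    forest: LineageForest,
    features: pd.DataFrame,
    phenotype: str,
    fluorescence_kind: str = "Fa",
) -> tuple[pd.DataFrame, list[CorrelationResult]]:
    """Per-pair (dFa, dPhenotype) differences and their correlations.

    Within each pair, sisters are ordered so the fluorescence difference is
    non-negative (ties broken by cell_id), and the phenotype difference
    carries its sign relative to that ordering. Requires >= 3 usable pairs
    for a correlation.
    """
    feat = features.set_index("cell_id")
    rows = []
    for a, b in sister_pairs(forest):
        if a not in feat.index or b not in feat.index:
            continue
        ra, rb = feat.loc[a], feat.loc[b]
        vals = [ra[fluorescence_kind], rb[fluorescence_kind], ra[phenotype], rb[phenotype]]
        if any(pd.isna(v) for v in vals):
            continue
        hi, lo = (a, b)
        if (rb[fluorescence_kind] > ra[fluorescence_kind]) or (
            rb[fluorescence_kind] == ra[fluorescence_kind] and b < a
        ):
            hi, lo = (b, a)
        d_fluor = feat.loc[hi, fluorescence_kind] - feat.loc[lo, fluorescence_kind]
        d_pheno = feat.loc[hi, phenotype] - feat.loc[lo, phenotype]
        rows.append(
            {
                "cell_id_high": hi,
                "cell_id_low": lo,
                "generation": int(feat.loc[hi, "generation"]),
                f"d_{fluorescence_kind}": d_fluor,
                f"d_{phenotype}": d_pheno,
            }
        )
    pairs = pd.DataFrame(rows)
    if len(pairs) < 3:
        logger.info(
            "%s: only %d sister pair(s) with complete measures; "
            "differences correlation not computed",
            forest.experiment_id, len(pairs),
        )
        return pairs, []
    pseudo = pairs.rename(
        columns={f"d_{fluorescence_kind}": fluorescence_kind, f"d_{phenotype}": phenotype}
    )
    results = correlate_by_generations(
        pseudo, phenotype, fluorescence_kind, experiment_id=forest.experiment_id
    )
    return pairs, results


def median_intermitotic_time_h(forest: LineageForest) -> Optional[float]:
    """Median birth-to-division time over divided cells born in-experiment."""
    spans = [
        c.end_time - c.birth_time
        for c in forest
        if c.fate == "divided" and c.birth_time is not None
    ]
    return float(np.median(spans)) if spans else None


def compare_dividing_vs_nondividing(
    forest: LineageForest,
    features: pd.DataFrame,
    exclude_generations: Sequence[int] = (),
    min_observation_h: Optional[float] = None,
) -> MitosisComparison:
    """Median uptake rates of dividing vs non-dividing cells, with pFa/pFmc.

    ``pFa`` (``pFmc``) is the median Fa/day (Fmc/day) of dividing cells
    divided by that of non-dividing cells. Cells of
    ``exclude_generations`` are dropped (late generations with too little
    remaining experimental time); non-dividing cells observed for less than
    ``min_observation_h`` (default: the experiment's median intermitotic
    time) are excluded since they had insufficient time to demonstrate a
    division. Incomplete divisions count as non-dividing.
    """
    if min_observation_h is None:
        min_observation_h = median_intermitotic_time_h(forest) or 0.0
    usable = features.dropna(subset=["Fa_rate"])
    usable = usable[~usable["generation"].isin(set(exclude_generations))]
    dividing = usable[usable["fate"] == "divided"]
    nondiv = usable[
        (usable["fate"] != "divided")
        & (usable["observation_days"] * 24.0 >= min_observation_h - 1e-9)
    ]
    if dividing.empty or nondiv.empty:
        empty = "dividing" if dividing.empty else "non-dividing"
        raise ValueError(
            f"experiment {forest.experiment_id}: no eligible {empty} cells; "
            "comparison undefined"
        )

    def _mw(a: pd.Series, b: pd.Series) -> float:
        return float(sps.mannwhitneyu(a, b, alternative="two-sided").pvalue)

    med_fa_div = float(dividing["Fa_rate"].median())
    med_fa_non = float(nondiv["Fa_rate"].median())
    div_fmc = dividing.dropna(subset=["Fmc_rate"])
    non_fmc = nondiv.dropna(subset=["Fmc_rate"])
    have_fmc = len(div_fmc) > 0 and len(non_fmc) > 0
    med_fmc_div = float(div_fmc["Fmc_rate"].median()) if have_fmc else None
    med_fmc_non = float(non_fmc["Fmc_rate"].median()) if have_fmc else None
    return MitosisComparison(
        experiment_id=forest.experiment_id,
        n_dividing=len(dividing),
        n_nondividing=len(nondiv),
        median_Fa_rate_dividing=med_fa_div,
        median_Fa_rate_nondividing=med_fa_non,
        pFa=med_fa_div / med_fa_non if med_fa_non != 0 else float("inf"),
        p_value_Fa=_mw(dividing["Fa_rate"], nondiv["Fa_rate"]),
        median_Fmc_rate_dividing=med_fmc_div,
        median_Fmc_rate_nondividing=med_fmc_non,
        pFmc=(med_fmc_div / med_fmc_non)
        if have_fmc and med_fmc_non not in (None, 0)
        else None,
        p_value_Fmc=_mw(div_fmc["Fmc_rate"], non_fmc["Fmc_rate"]) if have_fmc else None,
    )


def cross_experiment_summary(
    values: Sequence[float],
    test: str = "one-sample-wilcoxon-vs-0",
    other: Optional[Sequence[float]] = None,
) -> tuple[float, float]:
    """Median of per-experiment statistics and a two-sided test p-value.

    Tests: ``one-sample-wilcoxon-vs-0`` (divergence of per-experiment
    values from 0), ``wilcoxon-signed-rank-paired`` (paired difference vs
    ``other``), ``mann-whitney`` (unpaired vs ``other``). Exact
    distributions are used for n <= 25 where ties permit, the normal
    approximation otherwise. All-zero differences yield ``p = nan``.
    """
    values = np.asarray(values, dtype=float)
    if test in ("wilcoxon-signed-rank-paired", "mann-whitney") and other is None:
        raise ValueError(f"test {test!r} requires a second sample")
    if len(values) < 3:
        raise ValueError("need at least 3 values")
    median = float(np.median(values))
    method = "exact" if len(values) <= 25 else "approx"
    try:
        if test == "one-sample-wilcoxon-vs-0":
            p = float(sps.wilcoxon(values, method="auto").pvalue)
        elif test == "wilcoxon-signed-rank-paired":
            p = float(sps.wilcoxon(values, np.asarray(other, dtype=float),
                                   method="auto").pvalue)
        elif test == "mann-whitney":
            p = float(
                sps.mannwhitneyu(
                    values, np.asarray(other, dtype=float),
                    alternative="two-sided",
                    method=method if method == "exact" else "asymptotic",
                ).pvalue
            )
        else:
            raise ValueError(f"unknown test {test!r}")
    except ValueError as exc:
        if "zero" in str(exc).lower():
            logger.warning("signed-rank test undefined (all differences zero)")
            p = float("nan")
        else:
            raise
    return median, p
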