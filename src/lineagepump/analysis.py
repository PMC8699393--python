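"""End-to-end analysis: a model object over tracked experiments.

:class:`LineageTransferModel` bundles one or more lineage forests
(typically the seven experiments of a co-culture study, or simulated
batches) and :meth:`~LineageTransferModel.fit` runs the full pipeline —
normalize fluorescence, build Fa/Fmc accounts, measure migration
velocity, correlate each phenotype with Fa and Fmc by generation
grouping, compare dividing with non-dividing cells, and score persistence
across experiments. The returned :class:`LineageTransferResults` carries
every table plus ``summary()``.

:func:`summarize_tau_table` and :func:`summarize_mitosis_table` run only
the cross-experiment summary machinery on per-experiment statistics that
are already computed (e.g., the printed values reproduced in
``lineagepump.data``), recomputing medians, Wilcoxon tests and
persistence indices from them.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import io as _io
from .fluorescence import accounts_table, build_accounts, normalize_fluorescence
from .model import LineageForest, validate_lineage_forest
from .persistence import (
    PersistenceResult,
    persistence_index,
    score_experiment_mitosis,
    score_experiment_ordinal,
)
from .stats import (
    MitosisComparison,
    cell_feature_table,
    compare_dividing_vs_nondividing,
    correlate_by_generations,
    cross_experiment_summary,
    sister_pair_differences,
)

__all__ = [
    "AnalysisConfig",
    "LineageTransferModel",
    "LineageTransferResults",
    "summarize_tau_table",
    "summarize_mitosis_table",
    "load_study_table",
]

logger = logging.getLogger(__name__)

PHENOTYPES = ("area", "circularity", "velocity")

#: Default generation grouping used for the cross-experiment persistence
#: scoring of each phenotype: all generations for area and velocity,
#: starting+first for circularity (late generations are confounded by
#: crowding for shape measures).
DEFAULT_PERSISTENCE_GROUPING = {
    "area": "all",
    "circularity": "generations-0+1",
    "velocity": "all",
}


@dataclass(frozen=True)
class AnalysisConfig:
    normalize: bool = True
    normalization_reference: str = "first"
    acceptor_type: str = "SAOS-2"
    condition: str = "co-culture"
    velocity_interval_h: float = 2.0
    include_short_tracks: bool = False
    mitosis_exclude_generations: tuple[int, ...] = ()
    mitosis_min_observation_h: Optional[float] = None
    persistence_grouping: Optional[dict] = None


class LineageTransferModel:
    """Pipeline model over one or more tracked co-culture experiments."""

    def __init__(
        self,
        forests: Union[LineageForest, dict[str, LineageForest]],
        config: AnalysisConfig = AnalysisConfig(),
    ) -> None:
        if isinstance(forests, LineageForest):
            forests = {forests.experiment_id: forests}
        self.forests = dict(sorted(forests.items()))
        self.config = config
        for label, forest in self.forests.items():
            issues = [
                i for i in validate_lineage_forest(forest) if i.severity == "error"
            ]
            if issues:
                details = "; ".join(
                    f"{i.cell_id}[{i.rule}]" for i in issues[:5]
                )
                raise ValueError(
                    f"experiment {label!r}: {len(issues)} lineage invariant "
                    f"violation(s): {details}"
                )

    @classmethod
    def from_track_table(
        cls,
        path: Union[str, Path],
        dialect: str = "csv",
        config: AnalysisConfig = AnalysisConfig(),
    ) -> "LineageTransferModel":
        return cls(_io.read_track_table(path, dialect=dialect), config=config)

    def fit(self) -> "LineageTransferResults":
        cfg = self.config
        corr_rows = []
        sister_rows = []
        mitosis: dict[str, MitosisComparison] = {}
        features: dict[str, pd.DataFrame] = {}
        for label, forest in self.forests.items():
            f = normalize_fluorescence(
                forest, reference=cfg.normalization_reference,
                acceptor_type=cfg.acceptor_type,
            ) if cfg.normalize else forest
            accounts = build_accounts(
                f, acceptor_type=cfg.acceptor_type, condition=cfg.condition
            )
            feats = cell_feature_table(
                f, accounts,
                acceptor_type=cfg.acceptor_type, condition=cfg.condition,
                velocity_interval_h=cfg.velocity_interval_h,
                include_short_tracks=cfg.include_short_tracks,
            )
            features[label] = feats
            for phenotype in PHENOTYPES:
                for kind in ("Fa", "Fmc"):
                    for res in correlate_by_generations(
                        feats, phenotype, kind, experiment_id=label
                    ):
                        corr_rows.append(res.__dict__ | {})
            for phenotype in PHENOTYPES:
                pairs, pair_corr = sister_pair_differences(f, feats, phenotype)
                for res in pair_corr:
                    sister_rows.append(res.__dict__ | {"kind": "sister-diff"})
            try:
                mitosis[label] = compare_dividing_vs_nondividing(
                    f, feats,
                    exclude_generations=cfg.mitosis_exclude_generations,
                    min_observation_h=cfg.mitosis_min_observation_h,
                )
            except ValueError as exc:
                logger.warning("mitosis comparison skipped: %s", exc)

        correlations = pd.DataFrame(corr_rows)
        sister = pd.DataFrame(sister_rows)
        grouping_map = dict(DEFAULT_PERSISTENCE_GROUPING)
        if cfg.persistence_grouping:
            grouping_map.update(cfg.persistence_grouping)

        persistence: dict[str, PersistenceResult] = {}
        summaries: dict[str, dict] = {}
        for phenotype in PHENOTYPES:
            table = _phenotype_tau_table(correlations, phenotype,
                                         grouping_map[phenotype])
            if len(table) >= 1:
                scores = [
                    score_experiment_ordinal(r.tau_fa, r.tau_fmc)
                    for r in table.itertuples()
                ]
                persistence[phenotype] = persistence_index(
                    scores, phenotype=phenotype,
                    experiments=table["experiment"].tolist(),
                )
            if len(table) >= 3:
                summaries[phenotype] = {
                    "median_tau_fa": cross_experiment_summary(table["tau_fa"])[0],
                    "median_tau_fmc": cross_experiment_summary(table["tau_fmc"])[0],
                    "p_tau_fa_vs_0": cross_experiment_summary(table["tau_fa"])[1],
                    "p_tau_fmc_vs_0": cross_experiment_summary(table["tau_fmc"])[1],
                    "p_fa_vs_fmc_paired": cross_experiment_summary(
                        table["tau_fa"], "wilcoxon-signed-rank-paired",
                        table["tau_fmc"],
                    )[1],
                }
        if mitosis:
            usable = {
                k: m for k, m in mitosis.items()
                if m.pFa is not None and m.pFmc is not None
            }
            if usable:
                scores = [
                    score_experiment_mitosis(m.pFa, m.pFmc)
                    for m in usable.values()
                ]
                persistence["mitosis"] = persistence_index(
                    scores, phenotype="mitosis", experiments=list(usable)
                )

        return LineageTransferResults(
            model=self,
            features=features,
            correlations=correlations,
            sister_correlations=sister,
            mitosis=mitosis,
            persistence=persistence,
            phenotype_summaries=summaries,
            persistence_grouping=grouping_map,
        )


def _phenotype_tau_table(
    correlations: pd.DataFrame, phenotype: str, grouping_label: str
) -> pd.DataFrame:
    """Per-experiment (tau_fa, tau_fmc) pairs for one phenotype/grouping."""
    if correlations.empty:
        return pd.DataFrame(columns=["experiment", "tau_fa", "tau_fmc"])
    sub = correlations[
        (correlations["phenotype"] == phenotype)
        & (correlations["grouping_label"] == grouping_label)
    ]
    rows = []
    for exp, grp in sub.groupby("experiment_id"):
        fa = grp[grp["fluorescence_kind"] == "Fa"]["tau"]
        fmc = grp[grp["fluorescence_kind"] == "Fmc"]["tau"]
        if len(fa) == 1 and len(fmc) == 1:
            tau_fa, tau_fmc = float(fa.iloc[0]), float(fmc.iloc[0])
            if not (np.isnan(tau_fa) or np.isnan(tau_fmc)):
                rows.append(
                    {"experiment": exp, "tau_fa": tau_fa, "tau_fmc": tau_fmc}
                )
    return pd.DataFrame(rows)


@dataclass
class LineageTransferResults:
    """Fitted tables, comparisons and persistence indices."""

    model: LineageTransferModel
    features: dict[str, pd.DataFrame]
    correlations: pd.DataFrame
    sister_correlations: pd.DataFrame
    mitosis: dict[str, MitosisComparison]
    persistence: dict[str, PersistenceResult]
    phenotype_summaries: dict[str, dict]
    persistence_grouping: dict[str, str]

    def mitosis_table(self) -> pd.DataFrame:
        rows = []
        for label, m in self.mitosis.items():
            rows.append(
                {
                    "experiment": label,
                    "n_dividing": m.n_dividing,
                    "n_nondividing": m.n_nondividing,
                    "fa_rate_dividing": m.median_Fa_rate_dividing,
                    "fa_rate_nondividing": m.median_Fa_rate_nondividing,
                    "pfa": m.pFa,
                    "p_value_fa": m.p_value_Fa,
                    "fmc_rate_dividing": m.median_Fmc_rate_dividing,
                    "fmc_rate_nondividing": m.median_Fmc_rate_nondividing,
                    "pfmc": m.pFmc,
                    "p_value_fmc": m.p_value_Fmc,
                }
            )
        return pd.DataFrame(rows)

    def phenotype_tau_table(self, phenotype: str) -> pd.DataFrame:
        return _phenotype_tau_table(
            self.correlations, phenotype, self.persistence_grouping[phenotype]
        )

    def summary(self) -> str:
        lines = [
            "Lineage fluorescence-transfer analysis",
            "=" * 44,
            f"experiments: {', '.join(self.model.forests)}",
            "",
        ]
        for phenotype in PHENOTYPES:
            s = self.phenotype_summaries.get(phenotype)
            p = self.persistence.get(phenotype)
            if s is None and p is None:
                continue
            lines.append(f"{phenotype} (grouping: "
                         f"{self.persistence_grouping[phenotype]})")
            if s:
                lines.append(
                    f"  median tau Fa {s['median_tau_fa']:+.2f} "
                    f"(p vs 0: {s['p_tau_fa_vs_0']:.3g}), "
                    f"Fmc {s['median_tau_fmc']:+.2f} "
                    f"(p vs 0: {s['p_tau_fmc_vs_0']:.3g})"
                )
            if p:
                lines.append(
                    f"  persistence index {p.index_2dp:.2f} "
                    f"(scores {list(p.scores)})"
                )
        if "mitosis" in self.persistence:
            p = self.persistence["mitosis"]
            lines.append("mitosis (pFa vs pFmc)")
            lines.append(
                f"  persistence index {p.index_2dp:.2f} (scores {list(p.scores)})"
            )
        return "\n".join(lines)

    def save(self, out_dir: Union[str, Path]) -> dict[str, Path]:
        """Write deterministic machine-readable outputs (CSV + JSON)."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        fmt = lambda df: df.to_csv(index=False, float_format="%.9g")
        paths["correlations"] = out_dir / "correlations.csv"
        paths["correlations"].write_text(fmt(self.correlations))
        paths["mitosis"] = out_dir / "mitosis.csv"
        paths["mitosis"].write_text(fmt(self.mitosis_table()))
        for label, feats in self.features.items():
            p = out_dir / f"cells_{label}.csv"
            p.write_text(fmt(feats))
            paths[f"cells_{label}"] = p
        report = {
            "persistence": {
                k: {
                    "scores": list(v.scores),
                    "experiments": list(v.experiments),
                    "final_score": v.final_score,
                    "index": v.index,
                    "index_2dp": v.index_2dp,
                }
                for k, v in sorted(self.persistence.items())
            },
            "phenotype_summaries": self.phenotype_summaries,
            "persistence_grouping": self.persistence_grouping,
        }
        paths["report"] = out_dir / "report.json"
        paths["report"].write_text(json.dumps(report, indent=2, sort_keys=True))
        return paths


# ---------------------------------------------------------------------------
# summary machinery over already-computed per-experiment statistics
# ---------------------------------------------------------------------------

def load_study_table(name: str) -> pd.DataFrame:
    """Load one of the packaged per-experiment statistic tables.

    Available: ``area``, ``circularity``, ``velocity`` (per-experiment
    Kendall tau pairs for Fa and Fmc) and ``mitosis`` (median uptake rates
    and pFa/pFmc ratios), as reported by the co-culture study at 2-decimal
    (taus) / 1-decimal (rates) precision.
    """
    fname = f"study_{'tau_' + name if name != 'mitosis' else name}.csv"
    with resources.files("lineagepump.data").joinpath(fname).open() as fh:
        return pd.read_csv(fh)


def summarize_tau_table(
    table: pd.DataFrame,
    phenotype: str = "",
    decimals: Optional[int] = 2,
) -> dict:
    """Recompute summary statistics from per-experiment (tau_fa, tau_fmc).

    Returns medians of both tau columns, one-sample Wilcoxon p-values for
    divergence from 0, the paired Fa-vs-Fmc Wilcoxon p-value, and the
    persistence result. ``decimals`` is the precision at which tau
    equality is judged for the 0-score (use the reporting precision for
    printed tables).
    """
    required = {"experiment", "tau_fa", "tau_fmc"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    scores = [
        score_experiment_ordinal(r.tau_fa, r.tau_fmc, decimals=decimals)
        for r in table.itertuples()
    ]
    result = persistence_index(
        scores, phenotype=phenotype, experiments=table["experiment"].tolist()
    )
    return {
        "median_tau_fa": cross_experiment_summary(table["tau_fa"])[0],
        "median_tau_fmc": cross_experiment_summary(table["tau_fmc"])[0],
        "p_tau_fa_vs_0": cross_experiment_summary(table["tau_fa"])[1],
        "p_tau_fmc_vs_0": cross_experiment_summary(table["tau_fmc"])[1],
        "p_fa_vs_fmc_paired": cross_experiment_summary(
            table["tau_fa"], "wilcoxon-signed-rank-paired", table["tau_fmc"]
        )[1],
        "persistence": result,
    }


def summarize_mitosis_table(
    table: pd.DataFrame,
    persistence_exclude: Sequence[str] = ("a", "a*"),
    ratio_warn_tol: float = 0.05,
) -> dict:
    """Recompute mitosis summaries from per-experiment rates and ratios.

    Cross-experiment medians of the dividing and non-dividing Fa/day rates
    are computed both including the reduced ``a*`` row (and excluding the
    full ``a`` row) and excluding experiment ``a`` entirely; the paired
    Wilcoxon test compares dividing vs non-dividing rates. The mitosis
    persistence index scores pFmc > pFa as +1 over the experiments not in
    ``persistence_exclude``. Reported ratios inconsistent with their own
    rate columns beyond ``ratio_warn_tol`` (relative) are flagged with a
    warning, not corrected.
    """
    df = table.copy()
    for r in df.itertuples():
        recomputed = r.fa_rate_dividing / r.fa_rate_nondividing
        if np.isfinite(r.pfa) and abs(recomputed - r.pfa) > ratio_warn_tol * max(
            abs(r.pfa), 1.0
        ):
            warnings.warn(
                f"experiment {r.experiment}: reported pFa {r.pfa} "
                f"inconsistent with rates ({recomputed:.2f}); "
                "using reported value",
                stacklevel=2,
            )
    star = df[df["experiment"].str.endswith("*")]
    plain = df[~df["experiment"].str.endswith("*")]
    # "including a*": reduced a* row replaces the full a row
    with_star = pd.concat(
        [plain[~plain["experiment"].isin(star["experiment"].str.rstrip("*"))], star]
    )
    no_a = plain[~plain["experiment"].isin(star["experiment"].str.rstrip("*"))]

    def _summ(sub: pd.DataFrame) -> dict:
        med_div, p = cross_experiment_summary(
            sub["fa_rate_dividing"], "wilcoxon-signed-rank-paired",
            sub["fa_rate_nondividing"],
        )
        return {
            "median_fa_rate_dividing": float(sub["fa_rate_dividing"].median()),
            "median_fa_rate_nondividing": float(
                sub["fa_rate_nondividing"].median()
            ),
            "p_dividing_vs_nondividing": p,
            "n": len(sub),
        }

    pers_rows = df[
        ~df["experiment"].isin(set(persistence_exclude))
    ].dropna(subset=["pfa", "pfmc"])
    scores = [
        score_experiment_mitosis(r.pfa, r.pfmc) for r in pers_rows.itertuples()
    ]
    result = persistence_index(
        scores, phenotype="mitosis", experiments=pers_rows["experiment"].tolist()
    )
    return {
        "including_reduced_a": _summ(with_star),
        "excluding_a": _summ(no_a),
        "persistence": result,
    }
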