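"""Persistence index: does a phenotype effect of label receipt survive mitosis?

If an effect induced in a mother persists in her daughters, the daughters'
phenotype is ordered by the lineage's fluorescence receipt rather than by
their own measured label, so compensating each daughter with half the
mother's fluorescence (Fmc) *increases* the phenotype correlation relative
to Fa; without persistence the compensation adds disorder and *decreases*
it. Each experiment is therefore scored +1 (Fmc correlation stronger), 0
(equal) or -1 (weaker); the scores are averaged into a final score in
[-1, 1] and mapped to an index ``(1 + final_score)/2`` in [0, 1] — the
proportionate weight of experiments showing persistence, not its strength.

For the (nominal) mitosis outcome the same logic applies to the
proportionate rate ratios pFa and pFmc, with ties counting against
persistence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

__all__ = [
    "PersistenceResult",
    "score_experiment_ordinal",
    "score_experiment_mitosis",
    "persistence_index",
]


@dataclass(frozen=True)
class PersistenceResult:
    """Per-experiment scores and the derived persistence index."""

    phenotype: str
    scores: tuple[int, ...]
    experiments: tuple[str, ...]
    final_score: float
    index: float

    @property
    def index_2dp(self) -> float:
        return round(self.index, 2)


def score_experiment_ordinal(
    tau_fa: float,
    tau_fmc: float,
    decimals: Optional[int] = None,
) -> int:
    """Score one experiment from its (tau_Fa, tau_Fmc) pair.

    When the Fa correlation is negative both taus are sign-flipped first,
    so the comparison is always on correlation *strength* in the direction
    set by Fa. Returns +1 if the (adjusted) Fa tau is weaker than the Fmc
    tau, 0 if equal, -1 otherwise. ``decimals`` rounds both taus before
    comparison — use the reporting precision (2) when scoring printed
    tables so that printed ties score 0; leave None for full-precision
    pipeline values.
    """
    if decimals is not None:
        tau_fa = round(tau_fa, decimals)
        tau_fmc = round(tau_fmc, decimals)
    if tau_fa < 0:
        tau_fa, tau_fmc = -tau_fa, -tau_fmc
    if tau_fa < tau_fmc:
        return 1
    if tau_fa == tau_fmc:
        return 0
    return -1


def score_experiment_mitosis(pFa: float, pFmc: float) -> int:
    """+1 iff pFmc exceeds pFa; ties count against persistence (-1)."""
    if not (pFa > 0 and pFmc > 0):
        raise ValueError(f"pFa and pFmc must be positive, got {pFa}, {pFmc}")
    return 1 if pFmc > pFa else -1


def persistence_index(
    scores: Sequence[int],
    phenotype: str = "",
    experiments: Optional[Sequence[str]] = None,
) -> PersistenceResult:
    """Average per-experiment scores into the [0, 1] persistence index."""
    scores = tuple(int(s) for s in scores)
    if not scores:
        raise ValueError("at least one experiment score is required")
    if any(s not in (-1, 0, 1) for s in scores):
        raise ValueError(f"scores must be -1, 0 or +1, got {scores}")
    if experiments is None:
        experiments = tuple(str(i) for i in range(len(scores)))
    final = sum(scores) / len(scores)
    return PersistenceResult(
        phenotype=phenotype,
        scores=scores,
        experiments=tuple(experiments),
        final_score=final,
        index=(1.0 + final) / 2.0,
    )
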