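"""Important-regulator ranking by total influence value (TIV).

A candidate regulator's TIV is the sum of its influence over a set of
gene-expression-signature (GES) genes, TIV(Xi) = sum_t D(Xi -> X_st).  TIV is
computed from the full influence matrix rather than the pruned network so
that indirect influence (through transitive genes) counts toward a
regulator's importance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "RegulatorRanking",
    "total_influence",
    "rank_regulators",
    "regulator_recovery_proportion",
]


@dataclass
class RegulatorRanking:
    """TIV scores and the descending ranking they induce.

    ``ties`` lists groups of genes with exactly equal TIV (ordered
    lexicographically within the ranking and flagged here).
    """

    tiv: dict[str, float]
    ges: list[str]
    ranking: list[str]
    ties: list[list[str]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": range(1, len(self.ranking) + 1),
                "gene": self.ranking,
                "tiv": [self.tiv[g] for g in self.ranking],
            }
        )


def total_influence(gene: str, ges: Iterable[str], influence_df: pd.DataFrame) -> float:
    """Total influence value of ``gene`` over the GES set.

    The sum (not average) of D(gene -> s) over s in ``ges``; ``gene`` itself
    is excluded if present in the set.
    """
    targets = [g for g in ges if g != gene]
    unknown = [g for g in [gene, *targets] if g not in influence_df.index]
    if unknown:
        raise KeyError(f"gene id(s) not in influence matrix: {unknown}")
    if not targets:
        return 0.0
    return float(influence_df.loc[gene, targets].sum())


def rank_regulators(
    candidates: Sequence[str], ges: Iterable[str], influence_df: pd.DataFrame
) -> RegulatorRanking:
    """Score and rank candidate regulators by TIV over the GES set.

    When a candidate is scored it is removed from its own GES target set, so
    a gene appearing both as candidate and signature gene never scores
    against itself.  Ranking is by TIV descending with lexicographic
    tie-break; tied groups are flagged.
    """
    if not candidates:
        raise ValueError("candidate set is empty")
    ges = list(ges)
    tiv = {g: total_influence(g, ges, influence_df) for g in candidates}
    ranking = sorted(tiv, key=lambda g: (-tiv[g], g))
    ties: list[list[str]] = []
    by_value: dict[float, list[str]] = {}
    for g in ranking:
        by_value.setdefault(tiv[g], []).append(g)
    ties = [group for group in by_value.values() if len(group) > 1]
    return RegulatorRanking(tiv=tiv, ges=ges, ranking=ranking, ties=ties)


def regulator_recovery_proportion(influence_df: pd.DataFrame, true_root: str) -> float:
    """Fraction of non-root genes whose TIV is strictly below the root's.

    Every gene is treated as a candidate regulator with all genes as the GES
    pool (each candidate scored against the others), matching the protocol
    used to confirm a known master regulator: a proportion of 1.0 means the
    root out-influences every other node.
    """
    genes = list(influence_df.index)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    ranking = rank_regulators(genes, genes, influence_df)
    root_tiv = ranking.tiv[true_root]
    others = [g for g in genes if g != true_root]
    return sum(ranking.tiv[g] < root_tiv for g in others) / len(others)
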