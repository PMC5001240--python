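"""Model/Results façade over the inference pipeline.

``CBDN(expr).fit()`` runs the three stages — influence computation, edge
orientation, DDPI pruning — and returns a :class:`CBDNResults` carrying the
correlation and influence matrices, the oriented pair set, the pruned
network and regulator-ranking helpers, statsmodels-style.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .influence import (
    OrientedPairSet,
    correlation_matrix,
    influence_matrix_from_correlation,
    orient,
)
from .pruning import DirectedNetwork, prune_transitive
from .ranking import RegulatorRanking, rank_regulators, regulator_recovery_proportion

__all__ = ["CBDN", "CBDNResults"]


class CBDN:
    """Context-based dependency network model for an expression matrix.

    Parameters
    ----------
    endog
        Samples x genes expression data; array-like or DataFrame.  With an
        array, ``gene_ids`` names the columns (defaults to G1..Gn).
    tau
        DDPI noise tolerance (>= 0).  Larger values assume noisier data and
        remove fewer direct edges in favour of shortcuts.
    """

    def __init__(self, endog, gene_ids: Sequence[str] | None = None, tau: float = 0.0):
        if tau < 0:
            raise ValueError("tau must be >= 0")
        if isinstance(endog, pd.DataFrame):
            expr = endog.copy()
        else:
            arr = np.asarray(endog, dtype=float)
            if arr.ndim != 2:
                raise ValueError("expression data must be 2-dimensional")
            if gene_ids is None:
                gene_ids = [f"G{i + 1}" for i in range(arr.shape[1])]
            expr = pd.DataFrame(
                arr,
                columns=list(gene_ids),
                index=[f"S{i + 1}" for i in range(arr.shape[0])],
            )
        if expr.shape[0] < 3 or expr.shape[1] < 2:
            raise ValueError("need at least 3 samples and 2 genes")
        if expr.columns.duplicated().any():
            raise ValueError("gene ids are not unique")
        self.data = expr
        self.tau = float(tau)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, tau: float = 0.0) -> "CBDN":
        return cls(df, tau=tau)

    @property
    def nobs(self) -> int:
        return self.data.shape[0]

    @property
    def n_genes(self) -> int:
        return self.data.shape[1]

    def fit(self) -> "CBDNResults":
        """Run the full inference pipeline; deterministic for fixed input."""
        corr = correlation_matrix(self.data)
        D = influence_matrix_from_correlation(corr)
        oriented = orient(D)
        network = prune_transitive(oriented, D, tau=self.tau)
        return CBDNResults(self, corr, D, oriented, network)


class CBDNResults:
    """Fitted results: correlation/influence matrices and the pruned network."""

    def __init__(
        self,
        model: CBDN,
        correlation: pd.DataFrame,
        influence: pd.DataFrame,
        oriented: OrientedPairSet,
        network: DirectedNetwork,
    ):
        self.model = model
        self.correlation = correlation
        self.influence = influence
        self.oriented = oriented
        self.network = network
        self.tau = model.tau

    def rank_regulators(
        self,
        ges: Sequence[str] | None = None,
        candidates: Sequence[str] | None = None,
    ) -> RegulatorRanking:
        """TIV ranking over a GES set (defaults: all genes both roles)."""
        genes = list(self.influence.index)
        return rank_regulators(
            list(candidates) if candidates is not None else genes,
            list(ges) if ges is not None else genes,
            self.influence,
        )

    def regulator_recovery(self, true_root: str) -> float:
        return regulator_recovery_proportion(self.influence, true_root)

    def summary(self, top: int = 5) -> str:
        """Plain-text fit summary with the top TIV-ranked regulators."""
        ranking = self.rank_regulators()
        n_pruned = len({tuple(p["edge"]) for p in self.network.provenance})
        lines = [
            "Context-Based Dependency Network Results",
            "=" * 54,
            f"{'No. samples:':<28}{self.model.nobs}",
            f"{'No. genes:':<28}{self.model.n_genes}",
            f"{'DDPI tolerance (tau):':<28}{self.tau:g}",
            f"{'Oriented pairs:':<28}{len(self.oriented.edges)}",
            f"{'Orientation ties dropped:':<28}{len(self.oriented.ties)}",
            f"{'Edges pruned by DDPI:':<28}{n_pruned}",
            f"{'Edges in final network:':<28}{len(self.network.edges)}",
            "-" * 54,
            f"{'Top regulators by TIV':<28}",
        ]
        for rank, gene in enumerate(ranking.ranking[:top], start=1):
            lines.append(f"  {rank:>2}. {gene:<16}TIV = {ranking.tiv[gene]:.4f}")
        lines.append("=" * 54)
        return "\n".join(lines)
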