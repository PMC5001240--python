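"""Asymmetric influence function over a partial correlation network.

The influence of a candidate regulator :math:`X_j` on a target :math:`X_i` is
measured as the average absolute change in the target's Pearson correlations
with every other gene when the regulator is conditioned away:

.. math::

    D(X_j \\to X_i) = \\frac{1}{n-1} \\sum_{k \\ne j}
        \\left| \\mathrm{Corr}(X_i, X_k) - \\mathrm{PC}(X_i, X_k \\mid X_j) \\right|

where :math:`\\mathrm{PC}` is the first-order partial correlation.  Because a
regulator perturbs the correlation structure of its targets more than the
reverse, :math:`D` is asymmetric and the larger direction is taken as the
regulatory (parent-to-child) direction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DegenerateConditioningError",
    "OrientedPairSet",
    "correlation_matrix",
    "partial_correlation",
    "influence_d",
    "influence",
    "influence_matrix",
    "influence_matrix_from_correlation",
    "orient",
    "write_influence_tsv",
]

logger = logging.getLogger(__name__)

# |Corr| this close to 1 makes the partial-correlation denominator vanish.
DEGENERACY_ATOL = 1e-12


class DegenerateConditioningError(ValueError):
    """Conditioning variable is perfectly correlated with one of the pair."""


def correlation_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """Sample Pearson correlation matrix of a samples x genes expression frame.

    Parameters
    ----------
    expr
        Samples x genes matrix; every column must have positive variance.

    Returns
    -------
    pandas.DataFrame
        Symmetric n x n correlation matrix with unit diagonal, indexed by
        gene identifier on both axes.
    """
    if expr.isna().any().any():
        raise ValueError("expression matrix contains missing values; impute first")
    variances = expr.var(axis=0, ddof=1)
    dead = variances.index[variances.values == 0.0].tolist()
    if dead:
        raise ValueError(f"zero-variance gene column(s): {dead}")
    corr = expr.corr(method="pearson")
    # exact unit diagonal, symmetry to fp noise
    values = np.asarray(corr.values)
    np.fill_diagonal(values, 1.0)
    return pd.DataFrame(values, index=expr.columns, columns=expr.columns)


def _as_index(corr: pd.DataFrame, gene) -> int:
    if isinstance(gene, (int, np.integer)):
        return int(gene)
    return int(corr.index.get_loc(gene))


def partial_correlation(i, k, j, corr: pd.DataFrame) -> float:
    """First-order partial correlation PC(Xi, Xk | Xj).

    ``i``, ``k``, ``j`` may be integer positions or gene labels of ``corr``.
    Symmetric in ``(i, k)``.  Raises :class:`DegenerateConditioningError` when
    the conditioning gene is perfectly correlated with either endpoint.
    """
    C = corr.values
    ii, kk, jj = (_as_index(corr, g) for g in (i, k, j))
    cij, ckj = C[ii, jj], C[kk, jj]
    if abs(cij) >= 1.0 - DEGENERACY_ATOL or abs(ckj) >= 1.0 - DEGENERACY_ATOL:
        raise DegenerateConditioningError(
            f"|Corr| with conditioning gene {j!r} is 1 within tolerance"
        )
    num = C[ii, kk] - cij * ckj
    den = np.sqrt((1.0 - cij**2) * (1.0 - ckj**2))
    return float(num / den)


def influence_d(i, k, j, corr: pd.DataFrame) -> float:
    """Change in Corr(Xi, Xk) caused by conditioning on Xj.

    d(Xi, Xk | Xj) = Corr(Xi, Xk) - PC(Xi, Xk | Xj).  The self case i == k is
    identically zero and is excluded from influence averages.
    """
    ii, kk = _as_index(corr, i), _as_index(corr, k)
    if ii == kk:
        return 0.0
    return float(corr.values[ii, kk]) - partial_correlation(ii, kk, j, corr)


def influence(j, i, corr: pd.DataFrame) -> float:
    """Influence D(Xj -> Xi): mean |d(Xi, Xk | Xj)| over all genes k != j.

    The k == i self term is identically zero but still counted in the n - 1
    denominator.  Terms whose conditioning is degenerate (|Corr(., Xj)| = 1)
    are skipped with a warning.
    """
    n = corr.shape[0]
    if n < 3:
        raise ValueError("influence needs at least 3 genes to condition on")
    jj, ii = _as_index(corr, j), _as_index(corr, i)
    if jj == ii:
        raise ValueError("influence of a gene on itself is undefined")
    total = 0.0
    skipped = 0
    for kk in range(n):
        if kk == jj or kk == ii:
            continue
        try:
            total += abs(influence_d(ii, kk, jj, corr))
        except DegenerateConditioningError:
            skipped += 1
    if skipped:
        warnings.warn(
            f"skipped {skipped} degenerate conditioning term(s) for D({j!r}->{i!r})",
            RuntimeWarning,
            stacklevel=2,
        )
    return total / (n - 1)


def influence_matrix_from_correlation(corr: pd.DataFrame) -> pd.DataFrame:
    """All pairwise influences from a correlation matrix.

    Returns an n x n frame with entry (row=j, col=i) = D(Xj -> Xi); the
    diagonal is defined as zero.  O(n^3) arithmetic, vectorised per
    conditioning gene.
    """
    C = np.asarray(corr.values, dtype=float)
    n = C.shape[0]
    if n < 3:
        raise ValueError("influence matrix needs at least 3 genes")
    D = np.zeros((n, n))
    idx = np.arange(n)
    degenerate_total = 0
    for j in range(n):
        c = C[:, j]
        ok = np.abs(c) < 1.0 - DEGENERACY_ATOL
        degenerate_total += int(n - 1 - ok[idx != j].sum())
        ok[j] = False  # k = j excluded from the sum; row j is the diagonal
        s = np.sqrt(np.clip(1.0 - c * c, 0.0, None))
        with np.errstate(divide="ignore", invalid="ignore"):
            pc = (C - np.outer(c, c)) / np.outer(s, s)
        d = np.abs(C - pc)
        d[~ok, :] = 0.0
        d[:, ~ok] = 0.0
        d[idx, idx] = 0.0  # k = i self terms are identically zero
        D[j, :] = d.sum(axis=1) / (n - 1)
    D[idx, idx] = 0.0
    if degenerate_total:
        warnings.warn(
            f"skipped {degenerate_total} degenerate conditioning term(s) "
            "(|Corr| = 1 within tolerance)",
            RuntimeWarning,
            stacklevel=2,
        )
    return pd.DataFrame(D, index=corr.index, columns=corr.columns)


def influence_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """Influence matrix straight from a samples x genes expression frame."""
    return influence_matrix_from_correlation(correlation_matrix(expr))


@dataclass
class OrientedPairSet:
    """Every unordered gene pair resolved into a directed edge or a tie.

    ``edges`` holds (source, target, weight) with weight = D(source->target)
    and D(source->target) > D(target->source); ``ties`` holds the unordered
    pairs with exactly equal influence both ways (dropped from the network,
    conservative treatment of an event that is measure-zero in practice).
    """

    edges: list[tuple[str, str, float]]
    ties: list[tuple[str, str]] = field(default_factory=list)

    def edge_dict(self) -> dict[tuple[str, str], float]:
        return {(s, t): w for s, t, w in self.edges}


def orient(influence_df: pd.DataFrame) -> OrientedPairSet:
    """Orient every gene pair by influence comparison.

    Keeps i -> j iff D(i->j) > D(j->i); exact ties are recorded separately
    and excluded.  Two-gene cycles are impossible by construction.
    """
    genes = list(influence_df.index)
    D = influence_df.values
    edges: list[tuple[str, str, float]] = []
    ties: list[tuple[str, str]] = []
    n = len(genes)
    for a in range(n):
        for b in range(a + 1, n):
            dab, dba = D[a, b], D[b, a]
            if dab > dba:
                edges.append((genes[a], genes[b], float(dab)))
            elif dba > dab:
                edges.append((genes[b], genes[a], float(dba)))
            else:
                ties.append((genes[a], genes[b]))
    if ties:
        logger.info("orientation ties dropped: %d pair(s)", len(ties))
    return OrientedPairSet(edges=edges, ties=ties)


def write_influence_tsv(influence_df: pd.DataFrame, path) -> None:
    """Write the influence matrix as TSV (source rows, target columns)."""
    influence_df.to_csv(path, sep="\t", float_format="%.17g")
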