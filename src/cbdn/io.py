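"""Reading, preprocessing and writing of expression matrices and networks.

Expression matrices are plain delimited text with a header row and an index
column; the in-memory convention is always samples x genes (a pandas
DataFrame), whatever the on-disk orientation.  Microarray conventions are
supported: negative intensities are treated as missing (indistinguishable
from background) and imputed with the per-gene mean of strictly positive
values, and multiple probes per gene are collapsed by averaging.
"""

from __future__ import annotations

import logging
import warnings
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .pruning import DirectedNetwork

__all__ = [
    "ExpressionParseError",
    "read_expression",
    "validate_expression",
    "impute_negative_as_missing",
    "collapse_probes",
    "write_expression",
    "write_network",
    "read_network",
    "write_ranking",
]

logger = logging.getLogger(__name__)

Orientation = Literal["samples_x_genes", "genes_x_samples"]


class ExpressionParseError(ValueError):
    """A cell of the expression file could not be parsed as a number."""


def read_expression(
    path,
    orientation: Orientation,
    delimiter: str = "\t",
) -> pd.DataFrame:
    """Read a delimited expression matrix into samples x genes form.

    The orientation flag is required — square-ish matrices make
    auto-detection ambiguous.  Empty cells become missing values (NaN), not
    zeros; any other non-numeric cell raises :class:`ExpressionParseError`
    naming its row and column.
    """
    if orientation not in ("samples_x_genes", "genes_x_samples"):
        raise ValueError(f"unknown orientation {orientation!r}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(delimiter)[1:]
    if orientation == "samples_x_genes" and len(set(header)) != len(header):
        dups = sorted({g for g in header if header.count(g) > 1})
        raise ValueError(f"duplicate gene id(s): {dups}")
    raw = pd.read_csv(path, sep=delimiter, index_col=0)
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.any().any():
        rows, cols = np.where(bad.values)
        r, c = raw.index[rows[0]], raw.columns[cols[0]]
        raise ExpressionParseError(
            f"non-numeric cell {raw.iloc[rows[0], cols[0]]!r} at row {r!r}, "
            f"column {c!r} in {path}"
        )
    if orientation == "genes_x_samples":
        numeric = numeric.T
    if numeric.columns.duplicated().any():
        dups = numeric.columns[numeric.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene id(s): {dups}")
    logger.info(
        "read expression matrix %s: %d samples x %d genes",
        path,
        numeric.shape[0],
        numeric.shape[1],
    )
    return numeric


def validate_expression(expr: pd.DataFrame, allow_missing: bool = False) -> None:
    """Check the invariants required before inference."""
    m, n = expr.shape
    if m < 3:
        raise ValueError(f"need at least 3 samples, got {m}")
    if n < 2:
        raise ValueError(f"need at least 2 genes, got {n}")
    if expr.columns.duplicated().any():
        raise ValueError("gene ids are not unique")
    if not allow_missing and expr.isna().any().any():
        raise ValueError("expression matrix contains missing values")
    if not allow_missing:
        dead = expr.columns[expr.var(axis=0, ddof=1).values == 0.0].tolist()
        if dead:
            raise ValueError(f"zero-variance gene column(s): {dead}")


def impute_negative_as_missing(
    expr: pd.DataFrame, drop_unimputable: bool = False
) -> pd.DataFrame:
    """Replace negative and missing entries by the gene's positive mean.

    Negative intensities are below background and treated as missing; each
    such entry of gene g becomes the mean of g's strictly positive values
    across samples.  Idempotent.  A gene with no positive value at all has no
    defined replacement and is an error unless ``drop_unimputable`` drops it
    with a warning.
    """
    out = expr.copy()
    values = out.values.astype(float, copy=False)
    mask = np.isnan(values) | (values < 0)
    needs = mask.any(axis=0)
    positive = np.where(values > 0, values, np.nan)
    with warnings.catch_warnings():
        # all-NaN columns (no positive value) are handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        pos_mean = np.nanmean(positive, axis=0)
    unimputable = needs & np.isnan(pos_mean)
    if unimputable.any():
        genes = out.columns[unimputable].tolist()
        if not drop_unimputable:
            raise ValueError(
                f"gene(s) with no positive expression value cannot be imputed: {genes}"
            )
        logger.warning("dropping %d unimputable gene(s): %s", len(genes), genes)
        keep = ~unimputable
        out = out.loc[:, keep]
        values, mask, pos_mean = values[:, keep], mask[:, keep], pos_mean[keep]
    filled = np.where(mask, pos_mean, values)
    n_imputed = int(mask.sum())
    if n_imputed:
        logger.info("imputed %d negative/missing cell(s)", n_imputed)
    return pd.DataFrame(filled, index=out.index, columns=out.columns)


def collapse_probes(
    probe_values: pd.DataFrame, probe_to_gene: Mapping[str, str]
) -> pd.DataFrame:
    """Collapse a probes x samples table to a samples x genes matrix.

    Probes mapping to the same gene are combined by averaging their
    expression values per sample; probes with no gene mapping are dropped
    (count logged).
    """
    if not probe_to_gene:
        raise ValueError("probe-to-gene mapping is empty")
    if probe_values.index.duplicated().any():
        raise ValueError("probe ids are not unique")
    mapped = probe_values.index[probe_values.index.isin(probe_to_gene)]
    dropped = probe_values.shape[0] - len(mapped)
    if dropped:
        logger.info("dropped %d unmapped probe(s)", dropped)
    if len(mapped) == 0:
        raise ValueError("no probe maps to a gene")
    sub = probe_values.loc[mapped]
    genes = pd.Index([probe_to_gene[p] for p in mapped], name="gene")
    collapsed = sub.groupby(genes).mean()  # genes x samples
    return collapsed.T  # samples x genes


def write_expression(expr: pd.DataFrame, path, delimiter: str = "\t") -> None:
    """Write a samples x genes matrix at full precision."""
    expr.to_csv(path, sep=delimiter, float_format="%.17g")


def write_network(
    network: DirectedNetwork, path, format: Literal["tsv", "sif"] = "tsv"
) -> None:
    """Write the final network as a TSV edge list or SIF.

    Rows are deterministically ordered: descending influence weight, then
    lexicographic source, then target — equal inputs give byte-identical
    files.
    """
    rows = sorted(network.edges, key=lambda e: (-e[2], e[0], e[1]))
    with open(path, "w") as fh:
        if format == "tsv":
            fh.write("source\ttarget\tinfluence_weight\n")
            for s, t, w in rows:
                fh.write(f"{s}\t{t}\t{w:.17g}\n")
        elif format == "sif":
            for s, t, _ in rows:
                fh.write(f"{s} regulates {t}\n")
        else:
            raise ValueError(f"unknown format {format!r}")


def read_network(path) -> DirectedNetwork:
    """Read a TSV edge list written by :func:`write_network`."""
    df = pd.read_csv(path, sep="\t")
    edges = [
        (str(r.source), str(r.target), float(r.influence_weight))
        for r in df.itertuples()
    ]
    nodes = sorted({g for s, t, _ in edges for g in (s, t)})
    return DirectedNetwork(nodes=nodes, edges=edges)


def write_ranking(ranking, path) -> None:
    """Write a regulator ranking as TSV (rank, gene, tiv)."""
    ranking.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")
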