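"""Per-cell gene set Z-score (GSZ) signature activity.

For a cell with gene-level scores x_g (per-gene z-scores of
log2-expression, see :func:`ptdyn.preprocessing.log_standardize`), the
activity of a gene set of size m among N scored genes is

    GSZ = (S - m * mu) / sqrt(m * sigma^2 * (N - m)/(N - 1) + lambda)

where S is the sum of the set members' scores in that cell, and mu and
sigma^2 are the mean and population variance of *all* gene scores in
that cell. The variance term is the exact variance of a sum of m scores
drawn without replacement, so GSZ is the z-statistic of the observed
set sum against random same-size sets; lambda >= 0 optionally
regularizes the denominator for tiny or near-degenerate sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GeneSetCollection

logger = logging.getLogger(__name__)


@dataclass
class GszVector:
    """GSZ values of one gene set across all cells."""

    set_name: str
    values: pd.Series
    n_used: int
    lam: float
    unmatched: list[str]


def gsz_score(standardized: pd.DataFrame, gene_set: list[str],
              lam: float = 0.0, set_name: str = "") -> GszVector:
    """Score one gene set in every cell.

    Parameters
    ----------
    standardized
        Genes x cells table of gene-level scores (typically per-gene
        z-scores of log2 expression).
    gene_set
        Member gene symbols; members absent from the matrix are dropped
        with a logged warning (case-sensitive matching).
    lam
        Additive variance regularizer, >= 0.

    Raises
    ------
    ValueError
        If no member is present in the matrix, or if the set covers the
        whole matrix with ``lam == 0`` (the null variance is then zero).
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    members = pd.Index(gene_set)
    present = members[members.isin(standardized.index)]
    unmatched = [g for g in gene_set if g not in standardized.index]
    if unmatched:
        logger.warning("gene set %s: %d/%d members absent from matrix",
                       set_name or "<unnamed>", len(unmatched), len(gene_set))
    m = len(present)
    N = standardized.shape[0]
    if m == 0:
        raise ValueError(f"gene set {set_name or '<unnamed>'} has no member in the matrix")
    if m == N and lam == 0:
        raise ValueError("gene set covers every scored gene: null variance is zero "
                         "(set lambda > 0 to define GSZ = 0)")

    x = standardized.to_numpy(dtype=float)
    set_sum = standardized.loc[present].to_numpy(dtype=float).sum(axis=0)
    mu = x.mean(axis=0)
    var = x.var(axis=0, ddof=0)
    expected = m * mu
    null_var = m * var * (N - m) / (N - 1)
    gsz = (set_sum - expected) / np.sqrt(null_var + lam)
    return GszVector(
        set_name=set_name,
        values=pd.Series(gsz, index=standardized.columns, name=set_name or "gsz"),
        n_used=m,
        lam=lam,
        unmatched=unmatched,
    )


def score_collection(standardized: pd.DataFrame, collection: GeneSetCollection,
                     lam: float = 0.0) -> pd.DataFrame:
    """GSZ for every set in a collection; returns a cells x sets table."""
    columns = {}
    for name in collection:
        columns[name] = gsz_score(standardized, collection[name],
                                  lam=lam, set_name=name).values
    return pd.DataFrame(columns)
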