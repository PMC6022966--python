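"""Cell filtering, quantile normalization and gene-level standardization.

The pipeline's preprocessing mirrors standard FPKM-scale practice for
small single-cell plates: cells expressing neither housekeeping gene
(ACTB, GAPDH by default) are discarded as failed libraries, the
surviving columns are quantile-normalized so every cell shares one
value distribution, and gene-level scores for signature analysis are
per-gene z-scores of log2(FPKM + 1) across cells.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_HOUSEKEEPING = ("ACTB", "GAPDH")


def filter_cells(matrix: pd.DataFrame,
                 housekeeping=DEFAULT_HOUSEKEEPING) -> tuple[pd.DataFrame, list[str]]:
    """Drop cells in which *every* listed housekeeping gene is unexpressed.

    "Unexpressed" means FPKM <= 0 — zero is the only unambiguous absence
    on the FPKM scale. A cell expressing at least one housekeeping gene
    is kept; column order of survivors is preserved.

    Returns
    -------
    (filtered matrix, list of removed cell ids)

    Raises
    ------
    KeyError
        If a housekeeping gene is missing from the matrix.
    ValueError
        If filtering would remove every cell.
    """
    housekeeping = list(housekeeping)
    if not housekeeping:
        raise ValueError("housekeeping gene list must be non-empty")
    for gene in housekeeping:
        if gene not in matrix.index:
            raise KeyError(f"housekeeping gene {gene!r} absent from matrix")
    expressed = (matrix.loc[housekeeping] > 0).any(axis=0)
    removed = [c for c, keep in expressed.items() if not keep]
    if len(removed) == matrix.shape[1]:
        raise ValueError("housekeeping filter removed every cell")
    if removed:
        logger.info("filter_cells removed %d/%d cells: %s",
                    len(removed), matrix.shape[1], ", ".join(removed))
    return matrix.loc[:, expressed], removed


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force an identical value distribution on every cell (column).

    The reference distribution is the across-column mean of sorted
    columns; each entry is replaced by the reference value at its
    within-column rank. Ties within a column receive the mean of the
    reference values over their rank span, so the map is well defined
    and idempotent.
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 cells")
    values = matrix.to_numpy(dtype=float)
    n_genes, n_cells = values.shape
    reference = np.sort(values, axis=0).mean(axis=1)
    ref_cumsum = np.concatenate([[0.0], np.cumsum(reference)])

    out = np.empty_like(values)
    for j in range(n_cells):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        sorted_col = col[order]
        # runs of tied values share the mean of the reference over the run
        boundaries = np.flatnonzero(np.diff(sorted_col) != 0) + 1
        starts = np.concatenate([[0], boundaries])
        stops = np.concatenate([boundaries, [n_genes]])
        normalized_sorted = np.empty(n_genes)
        for lo, hi in zip(starts, stops):
            normalized_sorted[lo:hi] = (ref_cumsum[hi] - ref_cumsum[lo]) / (hi - lo)
        out[order, j] = normalized_sorted
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def log_standardize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-scores of log2(value + 1) across cells.

    Genes with zero variance on the log scale carry no ranking
    information and are dropped with a logged warning. Uses the
    population standard deviation (ddof = 0).
    """
    if matrix.shape[1] < 2:
        raise ValueError("standardization needs >= 2 cells")
    log_values = np.log2(matrix.to_numpy(dtype=float) + 1.0)
    sd = log_values.std(axis=1, ddof=0)
    keep = sd > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("log_standardize dropped %d zero-variance genes", n_dropped)
    log_values = log_values[keep]
    mean = log_values.mean(axis=1, keepdims=True)
    z = (log_values - mean) / sd[keep][:, None]
    return pd.DataFrame(z, index=matrix.index[keep], columns=matrix.columns)
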