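"""Probe-set summarization: log2, quantile normalization, median polish.

This is the RMA-style summarization path (between-array quantile
normalization followed by per-probe-set median polish of the log2 probe
intensities).  The convolution background-correction step of literal RMA is
deliberately not performed: the statistics downstream (bias contrasts,
cross-protocol regressions, fold ratios) operate on relative structure and
the synthetic generator produces no optical background.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, ProbeLevelDataset

logger = logging.getLogger(__name__)

__all__ = [
    "log2_transform",
    "quantile_normalize",
    "median_polish",
    "median_polish_summarize",
    "rma_summarize",
]


def log2_transform(data: ProbeLevelDataset) -> pd.DataFrame:
    """Log2 of every probe intensity; shape preserved.

    Raises ``ValueError`` identifying the first offending cell if any
    intensity is non-positive.
    """
    values = data.intensities
    arr = values.to_numpy()
    if (arr <= 0).any():
        r, c = np.argwhere(arr <= 0)[0]
        raise ValueError(
            f"non-positive intensity at probe {values.index[r]}, "
            f"array {values.columns[c]}: {arr[r, c]}"
        )
    return np.log2(values)


def quantile_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Force every array (column) onto the mean empirical distribution.

    For each rank r the reference value is the across-array mean of the r-th
    order statistics; each column is replaced by the reference values taken
    in its own rank order.  Ties within a column all receive the mean of the
    reference values at their tied ranks, so the result is invariant to how
    the sort permutes equal values.
    """
    arr = table.to_numpy(dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 1:
        raise ValueError("expected a dense 2-D table with at least one array")
    if not np.isfinite(arr).all():
        raise ValueError("table contains non-finite values (ragged input?)")
    n, k = arr.shape
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(k):
        order = np.argsort(arr[:, j], kind="mergesort")
        col_sorted = arr[order, j]
        # average reference over runs of tied input values
        starts = np.flatnonzero(np.r_[True, col_sorted[1:] != col_sorted[:-1]])
        run_sums = np.add.reduceat(reference, starts)
        run_lens = np.diff(np.r_[starts, n])
        assigned = np.repeat(run_sums / run_lens, run_lens)
        out[order, j] = assigned
    return pd.DataFrame(out, index=table.index, columns=table.columns)


def median_polish(
    x: np.ndarray, max_iter: int = 10, tol: float = 0.01
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Tukey's median polish of a rows x columns table.

    Alternates row- and column-median sweeps until every row and column
    median of the residuals is within ``tol`` of zero, or ``max_iter``
    full sweeps have run.  Returns (overall, row_effects, col_effects,
    residuals) with the row effects constrained to median 0 (the column
    effects likewise), so ``overall + row + col + residual`` reconstructs
    the input exactly.
    """
    r = np.asarray(x, dtype=float).copy()
    overall = 0.0
    row = np.zeros(r.shape[0])
    col = np.zeros(r.shape[1])
    for _ in range(max_iter):
        rmed = np.median(r, axis=1)
        r -= rmed[:, None]
        row += rmed
        d = np.median(col)
        col -= d
        overall += d
        cmed = np.median(r, axis=0)
        r -= cmed[None, :]
        col += cmed
        d = np.median(row)
        row -= d
        overall += d
        if (
            np.abs(np.median(r, axis=1)).max() <= tol
            and np.abs(np.median(r, axis=0)).max() <= tol
        ):
            break
    return overall, row, col, r


def _polish_stack(
    stack: np.ndarray, max_iter: int, tol: float
) -> np.ndarray:
    """Vectorized median polish over a (sets, probes, arrays) stack.

    Sweeps all probe sets simultaneously; a set whose residual medians are
    already within ``tol`` is unaffected by further sweeps.  Returns the
    per-set array summaries ``overall + col_effects`` of shape
    (sets, arrays).
    """
    r = stack.copy()
    n_sets = r.shape[0]
    overall = np.zeros(n_sets)
    row = np.zeros(r.shape[:2])
    col = np.zeros((n_sets, r.shape[2]))
    active = np.ones(n_sets, dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        ra = r[idx]
        rmed = np.median(ra, axis=2)
        ra -= rmed[:, :, None]
        row[idx] += rmed
        d = np.median(col[idx], axis=1)
        col[idx] -= d[:, None]
        overall[idx] += d
        cmed = np.median(ra, axis=1)
        ra -= cmed[:, None, :]
        col[idx] += cmed
        d = np.median(row[idx], axis=1)
        row[idx] -= d[:, None]
        overall[idx] += d
        r[idx] = ra
        # freeze probe sets whose residual medians are within tolerance so
        # the stacked sweep matches per-matrix polish exactly
        done = (np.abs(np.median(ra, axis=2)).max(axis=1) <= tol) & (
            np.abs(np.median(ra, axis=1)).max(axis=1) <= tol
        )
        active[idx[done]] = False
    return overall[:, None] + col


def median_polish_summarize(
    table: pd.DataFrame,
    arrays: pd.DataFrame,
    max_iter: int = 10,
    tol: float = 0.01,
) -> ExpressionMatrix:
    """Summarize a probe-level log2 table to probe-set expression.

    Fits overall + probe effect + array effect per probe set by median
    polish; a probe set's expression on an array is overall + that array's
    effect.  Probe sets with a single probe are passed through unchanged
    (with a logged notice — there is nothing to polish).
    """
    counts = table.groupby(level=0, sort=False).size()
    n_arrays = table.shape[1]
    gene_order = counts.index

    if counts.nunique() == 1 and counts.iloc[0] > 1:
        stack = table.to_numpy(dtype=float).reshape(
            len(counts), counts.iloc[0], n_arrays
        )
        values = _polish_stack(stack, max_iter, tol)
        out = pd.DataFrame(values, index=gene_order, columns=table.columns)
    else:
        rows = {}
        n_single = 0
        for gene, sub in table.groupby(level=0, sort=False):
            mat = sub.to_numpy(dtype=float)
            if mat.shape[0] == 1:
                rows[gene] = mat[0]
                n_single += 1
                continue
            overall, _, coleff, _ = median_polish(mat, max_iter=max_iter, tol=tol)
            rows[gene] = overall + coleff
        if n_single:
            logger.info("passed through %d single-probe probe sets unpolished",
                        n_single)
        out = pd.DataFrame.from_dict(rows, orient="index", columns=table.columns)
        out = out.loc[gene_order]
    out.index.name = "probe_set_id"
    return ExpressionMatrix(values=out, arrays=arrays)


def rma_summarize(
    data: ProbeLevelDataset,
    max_iter: int = 10,
    tol: float = 0.01,
    quantile: bool = True,
) -> ExpressionMatrix:
    """Full summarization chain: log2 -> quantile normalize -> median polish."""
    table = log2_transform(data)
    if quantile:
        table = quantile_normalize(table)
    return median_polish_summarize(table, data.arrays, max_iter=max_iter, tol=tol)
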