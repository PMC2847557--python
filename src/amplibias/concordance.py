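"""Replicate/protocol agreement: R², PCA, relative expression, fold ratios.

Cross-dataset comparisons work on median-normalized natural-scale
expression: each gene's value on an array is divided by that array's median
expression, removing global hybridization-level differences, so folds
between experiments are comparable.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "pairwise_r2",
    "r2_matrix",
    "pca_scores",
    "median_normalize",
    "relative_expression",
    "fold_summary",
]


def pairwise_r2(a, b) -> float:
    """Squared Pearson correlation between two matched log2 vectors."""
    av = np.asarray(a, dtype=float)
    bv = np.asarray(b, dtype=float)
    if av.shape != bv.shape or av.size < 3:
        raise ValueError("vectors must be matched and of length >= 3")
    if av.std() == 0 or bv.std() == 0:
        raise ValueError("undefined correlation: zero variance")
    r = np.corrcoef(av, bv)[0, 1]
    return float(r ** 2)


def r2_matrix(expr: ExpressionMatrix) -> pd.DataFrame:
    """Symmetric matrix of pairwise R² over all arrays."""
    cols = list(expr.values.columns)
    corr = np.corrcoef(expr.values.to_numpy().T)
    return pd.DataFrame(corr ** 2, index=cols, columns=cols)


def pca_scores(
    expr: ExpressionMatrix, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Array coordinates on the leading principal components.

    Gene-centered (each gene's mean across arrays removed), unscaled SVD of
    the arrays x genes matrix.  Returns (scores, explained variance
    fractions); fractions are non-increasing and sum to <= 1.
    """
    mat = expr.values.to_numpy(dtype=float).T  # arrays x genes
    if mat.shape[0] < 2:
        raise ValueError("PCA needs at least 2 arrays")
    centered = mat - mat.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    k = min(n_components, len(s))
    scores = u[:, :k] * s[:k]
    var = s ** 2
    explained = var[:k] / var.sum() if var.sum() > 0 else np.zeros(k)
    frame = pd.DataFrame(
        scores,
        index=expr.values.columns,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return frame, explained


def median_normalize(values) -> pd.Series:
    """Divide a natural-scale array column by its median (output median 1)."""
    v = pd.Series(values, dtype=float)
    if v.empty:
        raise ValueError("empty expression vector")
    if (v <= 0).any():
        raise ValueError("median normalization needs positive values")
    med = v.median()
    if med <= 0:
        raise ValueError("non-positive median")
    return v / med


def relative_expression(expr: ExpressionMatrix) -> pd.DataFrame:
    """Per-array median-normalized natural-scale expression.

    Antilogs the matrix (2**value) and divides each column by its median;
    the median over genes of every output column is 1.
    """
    nat = expr.natural_scale()
    return nat.apply(median_normalize, axis=0)


def fold_summary(
    gene_set,
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
) -> tuple[float, float, pd.Series]:
    """Mean fold (group_a over group_b) across a gene set, with SE.

    Inputs are relative-expression matrices (genes x arrays).  Per gene the
    fold is mean relative expression across group_a arrays divided by the
    mean across group_b arrays; the summary is the arithmetic mean of the
    per-gene folds and its standard error SD/sqrt(n).  SE is NaN for a
    single gene.  Genes absent from either group are excluded (logged).
    """
    genes = [g for g in gene_set if g in group_a.index and g in group_b.index]
    dropped = len(list(gene_set)) - len(genes)
    if dropped:
        logger.info("excluded %d genes absent from one of the groups", dropped)
    if not genes:
        raise ValueError("no genes from the set present in both groups")
    a_mean = group_a.loc[genes].mean(axis=1)
    b_mean = group_b.loc[genes].mean(axis=1)
    folds = a_mean / b_mean
    mean_fold = float(folds.mean())
    se = float(folds.std(ddof=1) / np.sqrt(len(folds))) if len(folds) > 1 else float("nan")
    return mean_fold, se, folds
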