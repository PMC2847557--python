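"""Differential expression between tissues and protocol-list overlap.

A gene is differentially expressed (DE) between the two tissue groups if
its fold change exceeds the threshold (|log2 FC| > log2(fc_threshold),
strict) AND its Benjamini-Hochberg adjusted p-value is at or below the FDR
level.  P-values come from a per-gene Welch two-sample t-test on log2
expression (an equal-variance test is available); the fold change is the
difference of group means on the log2 scale, i.e. a ratio of geometric
means on the natural scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = ["DEResult", "VennCounts", "call_de", "bh_adjust", "venn", "de_by_protocol"]


@dataclass
class DEResult:
    """Per-gene DE table plus the thresholds that produced it."""

    table: pd.DataFrame  # columns: log2_fc, p_value, p_adjusted, de
    fc_threshold: float
    fdr_level: float

    @property
    def de_genes(self) -> frozenset:
        return frozenset(self.table.index[self.table["de"]])


@dataclass
class VennCounts:
    """All region counts of a three-set Venn plus triple percentages."""

    sizes: dict
    regions: dict  # keys like "a_only", "ab_only", "abc"
    triple_pct: dict  # name -> round(100 * triple / size)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def call_de(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    fc_threshold: float = 2.0,
    fdr_level: float = 0.05,
    equal_var: bool = False,
) -> DEResult:
    """DE calls between two replicate groups of log2 expression columns.

    ``group_a`` and ``group_b`` are genes x replicate-array frames with
    matched gene indexes and >= 2 replicates each.  Genes with zero
    variance in both groups get p = 0 if the means differ and p = 1 if
    equal (logged degenerate case).
    """
    if not group_a.index.equals(group_b.index):
        raise ValueError("gene indexes must match")
    if group_a.shape[1] < 2 or group_b.shape[1] < 2:
        raise ValueError("need >= 2 replicates per group")
    a = group_a.to_numpy(dtype=float)
    b = group_b.to_numpy(dtype=float)
    log2_fc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    # zero within-group variance up to float rounding of identical values
    scale = np.maximum(np.abs(a).max(axis=1), np.abs(b).max(axis=1))
    var_floor = (np.maximum(scale, 1.0) * 1e-12) ** 2
    zero_var = (a.var(axis=1, ddof=1) <= var_floor) & (
        b.var(axis=1, ddof=1) <= var_floor
    )
    degenerate = ~np.isfinite(p) | zero_var
    if degenerate.any():
        logger.info("%d genes with zero within-group variance", int(degenerate.sum()))
        p = np.where(degenerate, np.where(log2_fc != 0, 0.0, 1.0), p)
    p_adj = bh_adjust(p)
    de = (np.abs(log2_fc) > np.log2(fc_threshold)) & (p_adj <= fdr_level)
    table = pd.DataFrame(
        {"log2_fc": log2_fc, "p_value": p, "p_adjusted": p_adj, "de": de},
        index=group_a.index,
    )
    return DEResult(table=table, fc_threshold=fc_threshold, fdr_level=fdr_level)


def de_by_protocol(
    expr,
    tissue_a: str = "MS",
    tissue_b: str = "EZ",
    fc_threshold: float = 2.0,
    fdr_level: float = 0.05,
) -> dict[str, DEResult]:
    """One DE analysis (tissue_a vs tissue_b) per protocol."""
    meta = expr.arrays
    out = {}
    for protocol in meta["protocol"].unique():
        cols_a = meta.index[(meta["protocol"] == protocol) & (meta["tissue"] == tissue_a)]
        cols_b = meta.index[(meta["protocol"] == protocol) & (meta["tissue"] == tissue_b)]
        out[protocol] = call_de(
            expr.values[cols_a], expr.values[cols_b],
            fc_threshold=fc_threshold, fdr_level=fdr_level,
        )
    return out


def venn(de_sets: dict) -> VennCounts:
    """Three-set Venn region counts and triple-overlap percentages.

    ``de_sets`` maps three names to gene sets.  Percentages are the triple
    intersection as a share of each single set, rounded to the nearest
    integer.
    """
    if len(de_sets) != 3:
        raise ValueError("venn needs exactly three named sets")
    (na, sa), (nb, sb), (nc, sc) = [(k, set(v)) for k, v in de_sets.items()]
    abc = sa & sb & sc
    regions = {
        f"{na}_only": len(sa - sb - sc),
        f"{nb}_only": len(sb - sa - sc),
        f"{nc}_only": len(sc - sa - sb),
        f"{na}_{nb}_only": len((sa & sb) - sc),
        f"{na}_{nc}_only": len((sa & sc) - sb),
        f"{nb}_{nc}_only": len((sb & sc) - sa),
        "triple": len(abc),
    }
    sizes = {na: len(sa), nb: len(sb), nc: len(sc)}
    triple_pct = {
        name: int(round(100.0 * len(abc) / size)) if size else 0
        for name, size in sizes.items()
    }
    return VennCounts(sizes=sizes, regions=regions, triple_pct=triple_pct)
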