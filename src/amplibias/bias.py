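"""5'/3' probe-position bias statistics.

For each probe set on each array the bias statistic is

    median(log2 values at the 5' probe block) - median(at the 3' block)

with blocks 1-5 and 7-11 for eleven probes (the middle probe is unused).
Positive values indicate 5' bias, negative values 3' bias; incomplete in
vitro transcription pushes signal toward the 3' end and hence the statistic
below zero.  For ``n != 11`` probes the blocks generalize to the first and
last ``(n - 1) // 2`` positions with the middle excluded, which degenerates
to 1-5 / 7-11 at ``n = 11``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "probe_position_bias",
    "mean_bias",
    "trimmed_quantile_curve",
    "compute_bias",
]

Q_TRIM_LOW, Q_TRIM_HIGH = 0.05, 0.95


def _blocks(n_probes: int) -> tuple[np.ndarray, np.ndarray]:
    k = (n_probes - 1) // 2
    if k < 1:
        raise ValueError(f"need at least 3 probes for a bias contrast, got {n_probes}")
    positions = np.arange(1, n_probes + 1)
    return positions[:k], positions[-k:]


def probe_position_bias(table: pd.DataFrame) -> pd.DataFrame:
    """Per-(probe set, array) bias from a probe-level log2 table.

    Probe sets lacking the full position complement are excluded (count
    logged).  Returns a probe_set x array DataFrame of bias values in log2
    units.
    """
    counts = table.groupby(level=0, sort=False).size()
    n_full = counts.max()
    complete = counts[counts == n_full].index
    n_dropped = len(counts) - len(complete)
    if n_dropped:
        logger.info("excluded %d probe sets lacking %d positions", n_dropped, n_full)
        table = table.loc[table.index.get_level_values(0).isin(complete)]

    five_block, three_block = _blocks(int(n_full))
    pos = table.index.get_level_values("probe_position")
    arr = table.to_numpy(dtype=float).reshape(len(complete), int(n_full), -1)
    # positions are sorted within each probe set (dense invariant)
    pos_within = pos[: int(n_full)].to_numpy()
    five_idx = np.isin(pos_within, five_block)
    three_idx = np.isin(pos_within, three_block)
    bias = np.median(arr[:, five_idx, :], axis=1) - np.median(
        arr[:, three_idx, :], axis=1
    )
    out = pd.DataFrame(bias, index=complete, columns=table.columns)
    out.index.name = "probe_set_id"
    return out


def mean_bias(
    bias: pd.DataFrame, arrays: pd.DataFrame, by: str = "protocol"
) -> pd.Series:
    """Arithmetic mean bias per group of arrays.

    ``by`` is a metadata column ("protocol", "tissue") or "array" for
    per-array means.  Gene x array values are pooled within each group;
    more negative means more 3' bias.  Groups with no arrays are reported
    as NaN (missing), never as zero.
    """
    if by == "array":
        return bias.mean(axis=0)
    if by not in arrays.columns:
        raise KeyError(f"unknown grouping column {by!r}")
    groups = {}
    for level in arrays[by].unique():
        cols = arrays.index[arrays[by] == level]
        vals = bias[cols].to_numpy().ravel()
        groups[level] = float(np.mean(vals)) if vals.size else np.nan
    return pd.Series(groups, name=f"mean_bias_by_{by}")


def trimmed_quantile_curve(
    bias: pd.DataFrame,
    arrays: pd.DataFrame,
    q_grid: np.ndarray,
    by: str = "protocol",
) -> pd.DataFrame:
    """Empirical bias quantiles per group at the probabilities in q_grid.

    The grid must lie within [0.05, 0.95]: extreme biases are deliberately
    trimmed out of the comparison.  Quantiles use linear interpolation
    between order statistics.  Returns a DataFrame indexed by q with one
    column per group.
    """
    q = np.asarray(q_grid, dtype=float)
    if q.size == 0:
        raise ValueError("q_grid is empty")
    if (q < Q_TRIM_LOW - 1e-9).any() or (q > Q_TRIM_HIGH + 1e-9).any():
        raise ValueError(
            f"q_grid must lie within [{Q_TRIM_LOW}, {Q_TRIM_HIGH}] (trimmed tails)"
        )
    if not (np.diff(q) > 0).all():
        raise ValueError("q_grid must be strictly increasing")
    cols = {}
    for level in arrays[by].unique():
        members = arrays.index[arrays[by] == level]
        pooled = bias[members].to_numpy().ravel()
        cols[level] = np.quantile(pooled, q, method="linear")
    out = pd.DataFrame(cols, index=pd.Index(q, name="q"))
    return out


def compute_bias(
    data, quantile: bool = True
) -> pd.DataFrame:
    """Bias table straight from a :class:`ProbeLevelDataset`.

    ``quantile=True`` (default) computes bias on quantile-normalized log2
    values for cross-array comparability; ``quantile=False`` uses raw log2
    intensities.
    """
    from .normalize import log2_transform, quantile_normalize

    table = log2_transform(data)
    if quantile:
        table = quantile_normalize(table)
    return probe_position_bias(table)
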