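"""Mis-amplification detection via cross-protocol regression outliers.

For every (tissue, replicate) pair of arrays, the two-cycle log2 expression
vector is regressed on the matched reference-protocol vector (one-cycle or
IVT-E) by ordinary least squares.  Externally studentised residuals — each
residual scaled by the leave-one-out residual standard deviation and its
leverage — follow t(n-3) under the null, effectively standard Normal at
array scale (n in the tens of thousands), so a fixed cut of |t| > 3.5
(99.95% two-sided coverage) flags candidate loci: t > 3.5 means the locus
sits above the regression line, i.e. is over-amplified by the two-cycle
protocol; t < -3.5 means under-amplified.

A locus is called mis-amplified by consensus only if it is flagged with a
consistent direction in at least ``min_replicates`` of the replicates within
EACH of the two comparisons (one-cycle vs two-cycle AND IVT-E vs two-cycle).
A laxer pooled reading (>= min_replicates calls pooled across both
comparisons, with at least one in each) is available via ``pooled=True``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import TWO_CYCLE, ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PairwiseFit",
    "AmplificationCallSet",
    "fit_pairwise",
    "studentize",
    "expected_exceedances",
    "classify",
    "consensus",
    "call_misamplified",
    "DEFAULT_THRESHOLD",
    "COMPARISONS",
]

DEFAULT_THRESHOLD = 3.5

#: (reference protocol, test protocol) pairs; the test protocol is always
#: the regression response so that positive residuals mean "higher under
#: two-cycle".
COMPARISONS = (("one_cycle", TWO_CYCLE), ("ivt_e", TWO_CYCLE))


@dataclass
class PairwiseFit:
    """OLS fit of test-protocol on reference-protocol log2 expression."""

    comparison: tuple[str, str]
    replicate: int
    tissue: str
    slope: float
    intercept: float
    residuals: pd.Series
    studentised: pd.Series = field(default=None)
    n: int = 0
    _x: np.ndarray = field(default=None, repr=False)

    @property
    def label(self) -> str:
        return f"{self.comparison[0]}_vs_{self.comparison[1]}"


@dataclass
class AmplificationCallSet:
    """Per-(comparison, replicate) calls plus the consensus gene sets."""

    calls: pd.DataFrame  # columns: probe_set_id, comparison, tissue, replicate, call
    threshold: float
    consensus_over: frozenset = frozenset()
    consensus_under: frozenset = frozenset()
    discordant: frozenset = frozenset()


def fit_pairwise(
    x: pd.Series,
    y: pd.Series,
    comparison: tuple[str, str] = ("reference", "test"),
    replicate: int = 0,
    tissue: str = "",
) -> PairwiseFit:
    """Least-squares line y = a + b*x over matched loci.

    ``x`` and ``y`` must share length (>= 3) and locus order.  Raises on
    zero variance in x (degenerate design).
    """
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 loci to fit, got {n}")
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    sxx = np.sum((xv - xv.mean()) ** 2)
    if sxx == 0:
        raise ValueError("degenerate fit: zero variance in the reference vector")
    b = np.sum((xv - xv.mean()) * (yv - yv.mean())) / sxx
    a = yv.mean() - b * xv.mean()
    resid = yv - a - b * xv
    index = y.index if isinstance(y, pd.Series) else pd.RangeIndex(n)
    fit = PairwiseFit(
        comparison=comparison,
        replicate=replicate,
        tissue=tissue,
        slope=float(b),
        intercept=float(a),
        residuals=pd.Series(resid, index=index),
        n=n,
        _x=xv,
    )
    fit.studentised = studentize(fit)
    return fit


def studentize(fit: PairwiseFit) -> pd.Series:
    """Externally studentised residuals of a simple-regression fit.

    t_i = e_i / (s_(i) * sqrt(1 - h_ii)) with h_ii the hat diagonal and
    s_(i) the residual scale of the fit with observation i deleted
    (closed form, no refitting).  Under the null t_i ~ t(n-3).  If every
    residual is zero (exact fit) all studentised residuals are defined as
    zero, with a logged notice.
    """
    if fit.n < 4:
        raise ValueError("external studentisation needs n >= 4")
    e = fit.residuals.to_numpy()
    x = fit._x
    n = fit.n
    sxx = np.sum((x - x.mean()) ** 2)
    h = 1.0 / n + (x - x.mean()) ** 2 / sxx
    sse = np.sum(e ** 2)
    if sse == 0:
        logger.info("exact fit: studentised residuals defined as 0")
        return pd.Series(np.zeros(n), index=fit.residuals.index)
    s2_loo = (sse - e ** 2 / (1.0 - h)) / (n - 3)
    s2_loo = np.maximum(s2_loo, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = e / (np.sqrt(s2_loo) * np.sqrt(1.0 - h))
    t = np.where(np.isfinite(t), t, 0.0)
    return pd.Series(t, index=fit.residuals.index)


def expected_exceedances(
    n: int, threshold: float
) -> tuple[float, int, float]:
    """Null expectation of |studentised residual| > threshold among n loci.

    Uses the standard-Normal approximation appropriate for large n.
    Returns (expected count, rounded count, two-sided coverage in percent).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    tail = 2.0 * stats.norm.sf(threshold)
    expected = n * tail
    coverage = 100.0 * (1.0 - tail)
    return expected, int(round(expected)), coverage


def classify(fit: PairwiseFit, threshold: float = DEFAULT_THRESHOLD) -> pd.Series:
    """Per-locus class from studentised residuals.

    Strictly greater than +threshold -> "over", strictly less than
    -threshold -> "under", otherwise "none" (|t| exactly at the threshold
    is "none").
    """
    t = fit.studentised
    out = pd.Series("none", index=t.index, dtype=object)
    out[t > threshold] = "over"
    out[t < -threshold] = "under"
    return out


def _pool_tissues(calls: pd.DataFrame) -> pd.DataFrame:
    """Resolve per-(gene, comparison, replicate) calls across tissue fits.

    A gene is over in a (comparison, replicate) if any tissue fit calls it
    over and none calls it under; symmetrically for under; tissue-level
    conflicts become "none" (logged).
    """
    flags = (
        calls.assign(
            over=calls["call"] == "over", under=calls["call"] == "under"
        )
        .groupby(["probe_set_id", "comparison", "replicate"], sort=False)[
            ["over", "under"]
        ]
        .any()
        .reset_index()
    )
    conflict = flags["over"] & flags["under"]
    n_conflict = int(conflict.sum())
    if n_conflict:
        logger.info(
            "%d (gene, comparison, replicate) calls conflicted across tissues",
            n_conflict,
        )
    call = np.select(
        [conflict, flags["over"], flags["under"]],
        ["none", "over", "under"],
        default="none",
    )
    return flags.assign(call=call)[["probe_set_id", "comparison", "replicate", "call"]]


def consensus(
    callset: AmplificationCallSet,
    min_replicates: int = 2,
    pooled: bool = False,
) -> tuple[frozenset, frozenset, frozenset]:
    """Consensus mis-amplified sets from the full call table.

    Strict reading (default): a gene is consensus-over iff it is called
    over in >= min_replicates replicates within EACH comparison;
    symmetrically for under.  ``pooled=True`` uses the laxer reading:
    >= min_replicates over-calls pooled across both comparisons with at
    least one in each.  Genes qualifying in opposite directions are
    excluded from both sets and returned as discordant.
    """
    calls = _pool_tissues(callset.calls)
    comparisons = sorted(callset.calls["comparison"].unique())
    over_sets, under_sets = {}, {}
    for comp in comparisons:
        sub = calls[calls["comparison"] == comp]
        counts = (
            sub[sub["call"] != "none"]
            .groupby(["probe_set_id", "call"], sort=False)
            .size()
            .unstack(fill_value=0)
        )
        over_sets[comp] = counts["over"] if "over" in counts else pd.Series(dtype=int)
        under_sets[comp] = (
            counts["under"] if "under" in counts else pd.Series(dtype=int)
        )

    def qualifies(per_comp: dict) -> set:
        if pooled:
            all_genes = set().union(*(set(s.index) for s in per_comp.values()))
            out = set()
            for g in all_genes:
                counts = [int(per_comp[c].get(g, 0)) for c in comparisons]
                if sum(counts) >= min_replicates and all(c >= 1 for c in counts):
                    out.add(g)
            return out
        sets = [
            set(s.index[s >= min_replicates]) for s in per_comp.values()
        ]
        return set.intersection(*sets) if sets else set()

    over = qualifies(over_sets)
    under = qualifies(under_sets)
    discordant = over & under
    if discordant:
        logger.warning(
            "%d genes qualified in both directions; excluded as discordant",
            len(discordant),
        )
    return (
        frozenset(over - discordant),
        frozenset(under - discordant),
        frozenset(discordant),
    )


def call_misamplified(
    expr: ExpressionMatrix,
    threshold: float = DEFAULT_THRESHOLD,
    min_replicates: int = 2,
    pooled: bool = False,
    comparisons: tuple = COMPARISONS,
) -> tuple[AmplificationCallSet, list[PairwiseFit]]:
    """Run the full classifier on a summarized expression matrix.

    Fits one regression per (comparison, tissue, replicate) on matched
    array pairs, classifies at ``threshold``, pools tissues, and applies
    the consensus rule.  Returns the call set (with consensus sets filled
    in) and the individual fits for diagnostics.
    """
    meta = expr.arrays
    fits: list[PairwiseFit] = []
    records = []
    for ref_proto, test_proto in comparisons:
        comp_label = f"{ref_proto}_vs_{test_proto}"
        for tissue in meta["tissue"].unique():
            for rep in sorted(meta["replicate"].unique()):
                sel_ref = meta[
                    (meta["tissue"] == tissue)
                    & (meta["protocol"] == ref_proto)
                    & (meta["replicate"] == rep)
                ]
                sel_test = meta[
                    (meta["tissue"] == tissue)
                    & (meta["protocol"] == test_proto)
                    & (meta["replicate"] == rep)
                ]
                if len(sel_ref) != 1 or len(sel_test) != 1:
                    raise ValueError(
                        f"need exactly one array for {tissue}/{ref_proto} and "
                        f"{tissue}/{test_proto} replicate {rep}"
                    )
                x = expr.values[sel_ref.index[0]]
                y = expr.values[sel_test.index[0]]
                fit = fit_pairwise(
                    x, y, comparison=(ref_proto, test_proto),
                    replicate=int(rep), tissue=tissue,
                )
                fits.append(fit)
                cls = classify(fit, threshold)
                records.append(
                    pd.DataFrame(
                        {
                            "probe_set_id": cls.index,
                            "comparison": comp_label,
                            "tissue": tissue,
                            "replicate": int(rep),
                            "call": cls.to_numpy(),
                        }
                    )
                )
    calls = pd.concat(records, ignore_index=True)
    callset = AmplificationCallSet(calls=calls, threshold=threshold)
    over, under, disc = consensus(callset, min_replicates=min_replicates,
                                  pooled=pooled)
    callset.consensus_over = over
    callset.consensus_under = under
    callset.discordant = disc
    return callset, fits


def fit_summary(fits: list[PairwiseFit], threshold: float = DEFAULT_THRESHOLD) -> pd.DataFrame:
    """Per-fit diagnostics: slope, intercept, n, over/under counts."""
    rows = []
    for f in fits:
        t = f.studentised
        rows.append(
            {
                "comparison": f.label,
                "tissue": f.tissue,
                "replicate": f.replicate,
                "slope": f.slope,
                "intercept": f.intercept,
                "n": f.n,
                "n_over": int((t > threshold).sum()),
                "n_under": int((t < -threshold).sum()),
            }
        )
    return pd.DataFrame(rows)
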