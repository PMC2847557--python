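"""End-to-end orchestration: simulate -> normalize -> bias -> misamp ->
concordance -> de, with every intermediate written as TSV and a
machine-readable JSON summary at the end."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bias as bias_mod
from . import concordance as conc
from . import de as de_mod
from . import io
from . import misamp
from .datatypes import TWO_CYCLE, ExpressionMatrix, SimConfig, SimTruth
from .normalize import log2_transform, quantile_normalize, median_polish_summarize
from .simulate import generate_probe_data

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """Parameters of a full pipeline run."""

    sim: SimConfig = field(default_factory=SimConfig)
    out_dir: str = "amplibias_run"
    threshold: float = misamp.DEFAULT_THRESHOLD
    min_replicates: int = 2
    pooled_consensus: bool = False
    fc_threshold: float = 2.0
    fdr_level: float = 0.05
    max_iter: int = 10
    tol: float = 0.01
    bias_on_normalized: bool = True

    def validate(self) -> None:
        self.sim.validate()
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.min_replicates < 1:
            raise ValueError("min_replicates must be >= 1")
        if self.fc_threshold <= 0 or not (0 < self.fdr_level <= 1):
            raise ValueError("invalid DE thresholds")
        if self.max_iter < 1 or self.tol <= 0:
            raise ValueError("invalid median-polish settings")


def _recovery_confusion(callset, truth: SimTruth) -> dict:
    over, under = set(callset.consensus_over), set(callset.consensus_under)
    true_over, true_under = set(truth.over_genes), set(truth.under_genes)
    planted = true_over | true_under
    recovered = (over & true_over) | (under & true_under)
    sign_errors = (over & true_under) | (under & true_over)
    false_pos = (over | under) - planted
    return {
        "n_planted": len(planted),
        "n_recovered": len(recovered),
        "recovery_pct": 100.0 * len(recovered) / len(planted) if planted else float("nan"),
        "n_sign_errors": len(sign_errors),
        "n_false_positives": len(false_pos),
    }


def run_all(config: RunConfig) -> dict:
    """Run every stage on a fresh simulation and write all outputs.

    Returns the summary dictionary (also written as summary.json in
    ``out_dir``).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # simulate
    data, truth = generate_probe_data(config.sim)
    io.write_probe_table(data, out / "probe_intensities.tsv")
    io.write_array_metadata(data.arrays, out / "arrays.tsv")
    io.write_truth(truth, out / "truth.tsv")
    io.write_sim_config(config.sim, out / "sim_config.yaml")

    # normalize
    log2_table = log2_transform(data)
    normed = quantile_normalize(log2_table)
    expr = median_polish_summarize(
        normed, data.arrays, max_iter=config.max_iter, tol=config.tol
    )
    io.write_expression(expr, out / "expression.tsv")

    # bias
    bias_table = bias_mod.probe_position_bias(
        normed if config.bias_on_normalized else log2_table
    )
    bias_table.rename_axis("probe_set_id").reset_index().to_csv(
        out / "bias.tsv", sep="\t", index=False
    )
    group_bias = bias_mod.mean_bias(bias_table, data.arrays, by="protocol")
    group_bias.rename_axis("protocol").to_frame().to_csv(
        out / "bias_by_protocol.tsv", sep="\t"
    )

    # mis-amplification
    callset, fits = misamp.call_misamplified(
        expr,
        threshold=config.threshold,
        min_replicates=config.min_replicates,
        pooled=config.pooled_consensus,
    )
    diag = misamp.fit_summary(fits, config.threshold)
    diag.to_csv(out / "fit_summary.tsv", sep="\t", index=False)
    callset.calls.to_csv(out / "calls.tsv", sep="\t", index=False)
    io.write_gene_list(callset.consensus_over, out / "consensus_over.txt")
    io.write_gene_list(callset.consensus_under, out / "consensus_under.txt")

    # concordance
    r2 = conc.r2_matrix(expr)
    r2.rename_axis("array_id").to_csv(out / "r2_matrix.tsv", sep="\t")
    scores, explained = conc.pca_scores(expr, n_components=3)
    scores.rename_axis("array_id").to_csv(out / "pca_scores.tsv", sep="\t")

    # relative-expression folds of the consensus sets, two-cycle vs others
    rel = conc.relative_expression(expr)
    meta = expr.arrays
    two_cols = meta.index[meta["protocol"] == TWO_CYCLE]
    other_cols = meta.index[meta["protocol"] != TWO_CYCLE]
    folds = {}
    for name, genes in (("over", callset.consensus_over),
                        ("under", callset.consensus_under)):
        if genes:
            mean_fold, se, _ = conc.fold_summary(genes, rel[two_cols], rel[other_cols])
            folds[name] = {"mean_fold": mean_fold, "se": se, "n_genes": len(genes)}
        else:
            folds[name] = {"mean_fold": None, "se": None, "n_genes": 0}

    # differential expression MS vs EZ per protocol + Venn
    de_results = de_mod.de_by_protocol(
        expr, fc_threshold=config.fc_threshold, fdr_level=config.fdr_level
    )
    for protocol, result in de_results.items():
        result.table.rename_axis("probe_set_id").to_csv(
            out / f"de_{protocol}.tsv", sep="\t"
        )
    venn = de_mod.venn({p: r.de_genes for p, r in de_results.items()})

    n_loci = config.sim.n_probe_sets
    expected, expected_rounded, coverage = misamp.expected_exceedances(
        n_loci, config.threshold
    )
    observed_exceed = int((diag["n_over"] + diag["n_under"]).sum())

    summary = {
        "seed": config.sim.seed,
        "n_probe_sets": n_loci,
        "consensus_over": sorted(callset.consensus_over),
        "consensus_under": sorted(callset.consensus_under),
        "n_consensus_over": len(callset.consensus_over),
        "n_consensus_under": len(callset.consensus_under),
        "expected_exceedances_per_fit": expected,
        "expected_exceedances_rounded": expected_rounded,
        "threshold_coverage_pct": coverage,
        "observed_exceedances_total": observed_exceed,
        "n_fits": len(fits),
        "mean_bias_by_protocol": {k: float(v) for k, v in group_bias.items()},
        "pca_explained": [float(x) for x in explained],
        "fold_summary": folds,
        "de_set_sizes": venn.sizes,
        "venn_regions": venn.regions,
        "venn_triple_pct": venn.triple_pct,
        "recovery": _recovery_confusion(callset, truth),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
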