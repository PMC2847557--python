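# amplibias

Small-sample transcriptomics on 3'-biased expression arrays routinely relies
on two-cycle RNA amplification: the in vitro transcription (IVT) labelling
step is run twice so that nanogram amounts of RNA — micro-dissected root
zones, sorted cells — yield enough labelled cRNA to hybridise. The second
cycle is not free. It steepens the 3' probe-position bias and, for a small
set of loci, systematically inflates or deflates the summarized signal
relative to one-cycle or IVT-Express labelling, so that gene lists built
from two-cycle data quietly disagree with everything else.

`amplibias` is a pipeline for detecting such mis-amplified probe sets from
probe-level intensity data, aimed at analysts comparing amplification
protocols or auditing two-cycle datasets. It bundles:

- a **synthetic probe-level generator** with planted ground truth (tissue
  effects, probe affinities, protocol-specific 3' gradients, planted
  log2 shifts under two-cycle), so every stage is testable end to end;
- **RMA-style summarization**: log2, quantile normalization, per-probe-set
  Tukey median polish;
- the **5'/3' bias statistic** per probe set and array:
  `median(log2 PM₁..₅) − median(log2 PM₇..₁₁)` (negative = 3' bias), with
  protocol means and trimmed quantile curves over q ∈ [0.05, 0.95];
- the **mis-amplification classifier**: per (tissue, replicate), OLS of
  two-cycle log2 expression on the matched reference protocol, externally
  studentised residuals `tᵢ = eᵢ / (s₍ᵢ₎√(1−hᵢᵢ))` (≈ standard Normal at
  array scale), calls at |t| > 3.5 (99.95% coverage; the null expectation
  among 22543 loci is ~10 exceedances), and a consensus rule: flagged with
  consistent direction in ≥ 2 of 3 replicates within *each* of the
  one-cycle-vs-two-cycle and IVT-E-vs-two-cycle comparisons;
- **concordance** measures: pairwise R² of log2 expression, gene-centered
  PCA of arrays, median-of-array relative expression and cross-dataset
  fold summaries (arithmetic mean ± SE over a gene set);
- **differential expression** between tissues per protocol (Welch t on
  log2, Benjamini–Hochberg FDR ≤ 0.05, fold change > 2) and the three-way
  Venn overlap of the resulting gene lists.

## Worked example

```bash
amplibias run-all --out-dir demo --seed 1
```

runs the whole chain on the default simulation (2000 probe sets × 11 PM
probes, 2 tissues × 3 protocols × 3 replicates, 20 over- and 20
under-amplified genes planted with |log2 shift| ∈ [2, 6]) and prints

```
consensus over 20, under 20; recovery 100.0%
```

`demo/summary.json` holds the machine-readable results of that run,
including (seed 1):

- `mean_bias_by_protocol`: one_cycle −0.24, ivt_e −0.36, two_cycle −0.96
  log2 units — all protocols 3'-biased, two-cycle most strongly, matching
  the planted gradient ordering;
- `expected_exceedances_per_fit` ≈ 0.93 for 2000 loci at |t| > 3.5 versus
  the observed per-fit counts in `fit_summary.tsv`;
- `recovery`: all 40 planted genes in the correct consensus list, no sign
  errors, no false positives;
- `fold_summary`: the consensus over-amplified genes run ~15-fold higher
  (median-normalized scale) on two-cycle arrays than on the others.

The same stages are available separately (`amplibias simulate`,
`normalize`, `bias`, `misamp`, `concordance`, `de`) and as library
functions (`amplibias.generate_probe_data`, `rma_summarize`,
`probe_position_bias`, `call_misamplified`, ...). Users with their own
probe-level TSVs (schema in `src/amplibias/io.py`) can enter the pipeline
at any stage.

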