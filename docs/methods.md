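# Methods

## The problem

Two-cycle RNA amplification makes expression arrays usable for tiny
samples, but the second in vitro transcription pass is a second opportunity
for sequence- and abundance-dependent distortion. Two symptoms are
measurable from probe-level data alone: a steeper 3' probe-position bias
(incomplete reverse transcription/IVT leaves more signal near the 3' end of
the transcript), and a small set of loci whose summarized expression is
shifted up or down under two-cycle labelling relative to one-cycle or
IVT-Express labelling of the same RNA. The pipeline quantifies the first
and detects the second.

## Synthetic data generator

The generator emulates the structure of a protocol-comparison experiment:
two dissected tissues (root meristem MS and elongation zone EZ), three
labelling protocols (one_cycle, two_cycle, ivt_e), three biological
replicates, eleven perfect-match probes per probe set. Per
(gene g, tissue t, protocol k, replicate r, probe p) the log2 intensity is

    y = θ_g + τ_{g,t} + φ_{g,p} + δ_k (p − p_mid)/span + s_g·1[k = two_cycle] + ε

with θ_g ~ N(baseline_mean, baseline_sd) the gene's base expression,
τ ~ N(0, tissue_effect_sd) gene × tissue effects, φ ~ N(0, affinity_sd)
probe affinities, δ_k the protocol's 3' gradient (log2 units over the full
probe span; p_mid = 6, span = 5 for 11 probes), s_g the planted signed
shift (non-zero only for planted genes, applied only under two-cycle) and
ε ~ N(0, noise_sd) i.i.d. replicate noise. Intensities are 2^y, floored
at 1 so log2 stays defined under extreme draws. All effects are additive
on the log2 scale so planted shifts have exact fold-change semantics, and
the gradient is linear in probe index — the simplest monotone shape
producing left-shifted bias distributions.

Defaults (one choice, used throughout the tests):

| parameter | default | why |
|---|---|---|
| n_probe_sets | 2000 | desk-scale version of a ~22k-probe-set array; full size by config |
| n_probes_per_set | 11 | PM probe count of the emulated platform |
| baseline_mean, baseline_sd | 7, 2 log2 | typical RMA-summarized expression spread |
| affinity_sd | 0.5 log2 | probe-to-probe affinity scatter within a set |
| tissue_effect_sd | 1.0 log2 | tissue signal dominates protocol signal (drives PC1) |
| gradient δ | 0.2 / 0.8 / 0.3 (1cyc / 2cyc / IVT-E) | every protocol somewhat 3'-biased, two-cycle most, IVT-E slightly above one-cycle |
| n_over, n_under | 20, 20 | planted mis-amplified classes |
| shift bounds | [2, 6] log2 | 4–64-fold distortions, uniform magnitude |
| noise_sd | 0.25 log2 | replicate noise per probe cell |

What the generator does *not* model: optical background, scanner
saturation, spatial artifacts, mismatch probes, cross-hybridisation, or
any mechanistic cause of mis-amplification (shifts are planted
phenomenologically; no mechanism for which loci mis-amplify is attempted).
Replicates differ only by i.i.d. noise, so replicate R² on synthetic data
runs higher (~0.996) than on real biological replicates (~0.98); passing
recovery tests demonstrates the statistics behave as designed under the
assumed model, not that real arrays meet those assumptions.

## Summarization

Probe intensities are log2-transformed, quantile-normalized across arrays
(each rank receives the across-array mean of that rank's order statistics;
ties within an array receive the mean of the reference values at their
tied ranks, making the result independent of sort order among equals), and
summarized per probe set by Tukey median polish (overall + probe effect +
array effect; alternating row/column median sweeps, max_iter = 10,
tol = 0.01 log2 units; probe-set expression on an array = overall + array
effect). Even-length medians are the mean of the two central order
statistics. Single-probe sets pass through unpolished with a logged
notice. The convolution background-correction step of literal RMA is
omitted: the downstream statistics (within-gene probe contrasts,
cross-protocol regressions, median-normalized folds) operate on relative
structure, and the generator produces no optical background. Quantile
normalization is exactly idempotent on tie-free data; with the tie rule
above a second pass can differ at affected ranks when arrays tie at
different positions, which is why the idempotency property is stated for
continuous inputs.

Reported "expression levels" on the natural scale mean 2^value.

## Bias statistic

Per probe set and array: median(log2 values at probe positions 1–5) −
median(positions 7–11); position 6 unused; positive = 5' bias, negative =
3' bias. For n ≠ 11 probes the blocks generalize to the first and last
⌊(n−1)/2⌋ positions. Under a pure linear gradient δ with no probe
affinity scatter and no noise the statistic equals −1.2δ exactly
(median of positions 1–5 sits at p = 3, of 7–11 at p = 9, and
δ·((3−6)−(9−6))/5 = −1.2δ). Bias is computed on quantile-normalized
values by default for cross-array comparability (a `quantile=False` /
`--raw` flag uses raw log2); protocol summaries are the arithmetic mean of
the pooled gene × array values per protocol (pooling, rather than
per-array-then-across-array averaging, weights every observation equally;
with balanced designs the two coincide). Quantile curves are restricted
to q ∈ [0.05, 0.95] because the extreme tails of the bias distribution are
dominated by a few very large values; quantiles interpolate linearly
between order statistics.

## Mis-amplification classifier

For each comparison (one_cycle vs two_cycle, ivt_e vs two_cycle), tissue
and replicate, the two-cycle log2 expression vector is regressed by OLS on
the matched reference-protocol vector. The two-cycle sample is the
response, so a positive residual means "higher under two-cycle" =
over-amplified (a flag reverses the orientation). Residuals are
externally studentised — e_i / (s₍ᵢ₎√(1−h_ii)) with the leave-one-out
scale s₍ᵢ₎ and hat diagonal h_ii — the standard outlier diagnostic, with a
t(n−3) null that is indistinguishable from standard Normal at array scale.
An exact fit defines all studentised residuals as 0 (logged). Calls use
strict inequalities: t > 3.5 over, t < −3.5 under, |t| = 3.5 none.
`expected_exceedances(n, c)` returns n·2(1−Φ(c)) (≈ 10.5 → 10 for
n = 22543, c = 3.5, 99.95% coverage).

Tissues are fitted separately and the two tissue calls of each
(comparison, replicate) pooled: over if either tissue fit says over and
neither says under, symmetrically for under, conflicts resolve to none
(logged). Consensus (strict reading, the default): a gene is consensus
over-amplified iff called over in ≥ min_replicates (default 2) replicates
within *each* comparison; a laxer pooled reading (≥ min_replicates calls
across both comparisons with ≥ 1 in each) sits behind `pooled=True`, since
the replicate quantifier of the consensus rule admits both scopes. Genes
qualifying in both directions are excluded and reported as discordant.

## Concordance and differential expression

R² is the squared Pearson correlation of matched log2 vectors. PCA is a
gene-centered, unscaled SVD with arrays as samples — standard for
expression data and preserving magnitude structure. Cross-dataset
comparison divides each array's natural-scale expression by its median
(output median 1), removing global hybridisation-level differences; fold
summaries over a gene set are arithmetic means of per-gene folds with
SE = SD/√n (folds are compared on the natural, not log, scale because
median-normalized ratios are the reporting convention; a log-scale mean
would be a geometric mean instead).

DE between tissues per protocol: per-gene Welch t-test on log2 values
(equal-variance option available; with 3-vs-3 replicates no moderated
variance estimator is attempted), Benjamini–Hochberg adjustment
(statsmodels step-up), flag iff |log2 FC| > log2(2) strictly and adjusted
p ≤ 0.05. Genes with zero variance in both groups get p = 0 if the means
differ, 1 otherwise (logged); zero variance is detected up to the float
rounding of identical values. Venn percentages are the triple
intersection over each protocol's list size, rounded to nearest integer.

## Numerical conventions and degenerate inputs

- Deterministic: one `numpy.random.default_rng(seed)` stream drawn in a
  fixed order; identical (config, seed) gives bit-identical datasets, and
  `run_all` output is reproducible end to end.
- TSV round trips use 17-significant-digit formatting and round-trip float
  parsing, so write-then-read is exact.
- Probe sets lacking a full position complement are excluded from bias
  computation with a logged count; the full complement is the maximum
  observed probe count.
- Zero-variance reference vectors make the pairwise fit degenerate
  (raised, not guessed); single arrays cannot be quantile-normalized
  against anything (passed through) or PCA-decomposed (raised).

## Problem sizes

The default simulation (2000 probe sets) keeps every stage under a few
seconds while leaving all rates — null exceedance counts, recovery,
R²/PCA structure — at the same per-locus calibration as a full-size array;
full-size runs (≥ 22k probe sets) are a config change
(`SimConfig(n_probe_sets=22810)`).

## Known limitations

- The identity of genuinely mis-amplified probe sets on real arrays cannot
  be derived from simulation; the pipeline reproduces the *procedure* and
  its calibration, and ingests real probe-level tables when users have
  them.
- Binary platform files (.cel and chip definition files) are not parsed;
  inputs are plain TSV.
- No robust-regression or mixture-model alternative to the studentised
  OLS residual; gross heteroscedasticity between protocols would inflate
  both tails.
- The lax/strict consensus readings can disagree for genes flagged exactly
  once per comparison; both are available, strict is the default.
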