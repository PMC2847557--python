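"""Cross-protocol regression, studentised residuals (vs delete-one and
statsmodels oracles), classification and consensus logic."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import amplibias as ab
from amplibias.misamp import (
    AmplificationCallSet,
    COMPARISONS,
    classify,
    consensus,
    expected_exceedances,
    fit_pairwise,
    fit_summary,
)


def delete_one_studentised(x, y):
    """Brute-force oracle: refit OLS without each point, scale its residual."""
    n = len(x)
    out = np.empty(n)
    X = np.column_stack([np.ones(n), x])
    for i in range(n):
        mask = np.arange(n) != i
        beta, *_ = np.linalg.lstsq(X[mask], y[mask], rcond=None)
        resid_i = y[i] - X[i] @ beta
        resid_rest = y[mask] - X[mask] @ beta
        s2 = resid_rest @ resid_rest / (n - 1 - 2)
        h = X[i] @ np.linalg.inv(X[mask].T @ X[mask]) @ X[i]
        out[i] = resid_i / np.sqrt(s2 * (1 + h))
    return out


class TestFit:
    def test_exact_line_recovers_coefficients_with_zero_residuals(self):
        x = pd.Series(np.linspace(0, 10, 8))
        fit = fit_pairwise(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        np.testing.assert_allclose(fit.residuals, 0.0, atol=1e-12)
        np.testing.assert_allclose(fit.studentised, 0.0)

    def test_displaced_point_matches_normal_equations_oracle(self, rng):
        n = 30
        x = rng.normal(size=n)
        y = x.copy()
        y[4] += 3.0
        fit = fit_pairwise(pd.Series(x), pd.Series(y))
        X = np.column_stack([np.ones(n), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose([fit.intercept, fit.slope], beta, atol=1e-10)
        np.testing.assert_allclose(fit.residuals, y - X @ beta, atol=1e-10)

    def test_permuting_loci_permutes_residuals_identically(self, rng):
        n = 25
        x = pd.Series(rng.normal(size=n))
        y = pd.Series(x + rng.normal(scale=0.1, size=n))
        fit = fit_pairwise(x, y)
        perm = rng.permutation(n)
        fit_p = fit_pairwise(x.iloc[perm].reset_index(drop=True),
                             y.iloc[perm].reset_index(drop=True))
        np.testing.assert_allclose(
            fit_p.residuals.to_numpy(), fit.residuals.to_numpy()[perm], atol=1e-12
        )

    def test_zero_variance_reference_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_pairwise(pd.Series([1.0, 1.0, 1.0, 1.0]),
                         pd.Series([1.0, 2.0, 3.0, 4.0]))


class TestStudentise:
    def test_matches_delete_one_oracle_on_200_random_instances(self, rng):
        for _ in range(200):
            n = int(rng.integers(6, 51))
            x = rng.normal(size=n)
            y = 0.5 + 0.9 * x + rng.normal(scale=0.3, size=n)
            if rng.random() < 0.5:
                y[int(rng.integers(n))] += rng.normal(scale=4)
            fit = fit_pairwise(pd.Series(x), pd.Series(y))
            oracle = delete_one_studentised(x, y)
            np.testing.assert_allclose(fit.studentised, oracle, rtol=1e-9,
                                       atol=1e-9)

    def test_matches_statsmodels_external_studentisation(self, rng):
        import statsmodels.api as sm
        from statsmodels.stats.outliers_influence import OLSInfluence

        n = 40
        x = rng.normal(size=n)
        y = 1.0 + x + rng.normal(scale=0.5, size=n)
        fit = fit_pairwise(pd.Series(x), pd.Series(y))
        model = sm.OLS(y, sm.add_constant(x)).fit()
        ref = OLSInfluence(model).resid_studentized_external
        np.testing.assert_allclose(fit.studentised, ref, rtol=1e-9)

    def test_large_null_sample_tail_fraction_near_normal(self, rng):
        n = 22543
        x = rng.normal(size=n)
        y = x + rng.normal(scale=0.2, size=n)
        fit = fit_pairwise(pd.Series(x), pd.Series(y))
        frac = float((fit.studentised.abs() > 3.5).mean())
        p = 2 * stats.norm.sf(3.5)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(frac - p) <= 3 * se


class TestExpectedExceedances:
    def test_reference_array_size_rounds_to_ten(self):
        expected, rounded, coverage = expected_exceedances(22543, 3.5)
        assert rounded == 10
        assert round(coverage, 2) == 99.95

    def test_limits(self):
        assert expected_exceedances(1000, 50.0)[1] == 0
        assert expected_exceedances(1000, 0.0)[0] == pytest.approx(1000.0)


class TestClassify:
    def _fit_with_t(self, t_values):
        fit = fit_pairwise(
            pd.Series(np.arange(5.0)), pd.Series(np.arange(5.0) * 2 + 1)
        )
        fit.studentised = pd.Series(t_values,
                                    index=[f"g{i}" for i in range(len(t_values))])
        return fit

    @pytest.mark.parametrize(
        "t, expected",
        [(3.6, "over"), (-3.6, "under"), (3.5, "none"), (-3.5, "none"),
         (0.0, "none")],
    )
    def test_strict_threshold_boundaries(self, t, expected):
        fit = self._fit_with_t([t])
        assert classify(fit, 3.5).iloc[0] == expected

    def test_raising_threshold_never_enlarges_call_sets(self, rng):
        fit = self._fit_with_t(rng.normal(scale=2, size=500))
        low = classify(fit, 2.0)
        high = classify(fit, 3.0)
        assert set(high.index[high != "none"]) <= set(low.index[low != "none"])


def make_callset(call_map, comparisons=("one_cycle_vs_two_cycle",
                                        "ivt_e_vs_two_cycle")):
    """call_map: gene -> {(comparison, replicate): call}; fills 'none'."""
    rows = []
    genes = sorted(call_map)
    for gene in genes:
        for comp in comparisons:
            for rep in (1, 2, 3):
                rows.append({
                    "probe_set_id": gene, "comparison": comp, "tissue": "MS",
                    "replicate": rep,
                    "call": call_map[gene].get((comp, rep), "none"),
                })
    return AmplificationCallSet(calls=pd.DataFrame(rows), threshold=3.5)


class TestConsensus:
    C1, C2 = "one_cycle_vs_two_cycle", "ivt_e_vs_two_cycle"

    def test_two_reps_in_each_comparison_qualifies(self):
        cs = make_callset({"g": {(self.C1, 1): "over", (self.C1, 2): "over",
                                 (self.C2, 1): "over", (self.C2, 3): "over"}})
        over, under, disc = consensus(cs)
        assert over == {"g"} and not under and not disc

    def test_single_comparison_support_fails_both_lists_clause(self):
        cs = make_callset({"g": {(self.C1, 1): "over", (self.C1, 2): "over"}})
        over, under, _ = consensus(cs)
        assert not over and not under

    def test_one_replicate_per_comparison_fails_strict_but_passes_pooled(self):
        cs = make_callset({"g": {(self.C1, 1): "over", (self.C2, 2): "over"}})
        over_strict, _, _ = consensus(cs, min_replicates=2, pooled=False)
        assert not over_strict
        over_pooled, _, _ = consensus(cs, min_replicates=2, pooled=True)
        assert over_pooled == {"g"}

    def test_opposite_directions_are_discordant_and_excluded(self):
        cs = make_callset({"g": {(self.C1, 1): "over", (self.C1, 2): "over",
                                 (self.C2, 1): "under", (self.C2, 2): "under"}})
        over, under, disc = consensus(cs)
        assert not over and not under and not disc  # fails both-lists per dir

        cs2 = make_callset({
            "g": {(self.C1, 1): "over", (self.C1, 2): "over",
                  (self.C2, 1): "over", (self.C2, 2): "over"}})
        # force both-direction qualification via under calls too
        extra = cs2.calls.copy()
        extra["call"] = extra["call"].replace({"over": "under"})
        both = AmplificationCallSet(
            calls=pd.concat(
                [cs2.calls, extra.assign(tissue="EZ")], ignore_index=True
            ),
            threshold=3.5,
        )
        over, under, disc = consensus(both)
        assert not over and not under  # tissue conflict resolves to none


class TestEndToEnd:
    def test_planted_genes_recovered_with_correct_signs(self, default_sim,
                                                        default_expr):
        _, truth = default_sim
        callset, _ = ab.call_misamplified(default_expr)
        over, under = set(callset.consensus_over), set(callset.consensus_under)
        planted = set(truth.over_genes) | set(truth.under_genes)
        recovered = (over & set(truth.over_genes)) | (under & set(truth.under_genes))
        assert len(recovered) / len(planted) >= 0.90
        assert not (over & set(truth.under_genes))
        assert not (under & set(truth.over_genes))

    def test_null_exceedance_counts_within_poisson_bounds(self, null_expr):
        callset, fits = ab.call_misamplified(null_expr)
        diag = fit_summary(fits)
        lam = 2000 * 2 * stats.norm.sf(3.5)
        lo, hi = stats.poisson.ppf([0.005, 0.995], lam)
        per_fit = (diag.n_over + diag.n_under).to_numpy()
        assert ((per_fit >= lo) & (per_fit <= hi)).all()
        assert not callset.consensus_over and not callset.consensus_under
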