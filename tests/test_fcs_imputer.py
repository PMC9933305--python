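"""Chained-equations engine: predictor sets, univariate imputers, invariants."""

import numpy as np
import pytest
from scipy.special import expit

import mistrat as ms
from mistrat.datagen import generate_complete
from mistrat.errors import ConfigError, DegenerateStratumError
from mistrat.fcs_imputer import (
    ImputationSpec,
    build_predictor_set,
    eg_imputation_count,
    impute_fcs,
    impute_univariate_gaussian,
    impute_univariate_logistic,
    _logistic_fit,
)
from mistrat.missingness import impose_missingness


def _spec(label, masked=("C4", "C5", "Y"), m=5, iterations=3):
    return ImputationSpec.from_method(label, masked_variables=masked, m=m,
                                      iterations=iterations)


class TestPredictorSets:
    def test_target_outcome_with_confounder_interaction(self):
        got = build_predictor_set("Y", _spec("MI-ExC"))
        assert got == ["X", "C1", "C2", "C3", "C4", "C5", "A", ("X", "C5")]

    def test_interaction_containing_target_is_dropped(self):
        got = build_predictor_set("C5", _spec("MI-ExC"))
        assert got == ["X", "C1", "C2", "C3", "C4", "Y", "A"]

    def test_exclusion_rule_over_all_targets(self):
        """MI-ExI: every X-by-incomplete-variable term except the target's own."""
        spec = _spec("MI-ExI")
        for target in ("C4", "C5", "Y"):
            got = build_predictor_set(target, spec)
            inters = {t for t in got if isinstance(t, tuple)}
            expected = {("X", v) for v in ("C4", "C5", "Y") if v != target}
            assert inters == expected
            assert ("X", target) not in inters

    def test_stratified_mode_excludes_exposure(self):
        got = build_predictor_set("Y", _spec("MI-EG"))
        assert "X" not in got and not any(isinstance(t, tuple) for t in got)

    def test_outcome_only_reductions(self):
        """With only Y incomplete, MI-ExO collapses to MI-NI and MI-ExOC to
        MI-ExC at the predictor-set level (X*Y cannot predict Y itself)."""
        assert build_predictor_set("Y", _spec("MI-ExO")) == build_predictor_set(
            "Y", _spec("MI-NI")
        )
        assert build_predictor_set("Y", _spec("MI-ExOC")) == build_predictor_set(
            "Y", _spec("MI-ExC")
        )


class TestSpecValidation:
    def test_interaction_sets_enforced(self):
        with pytest.raises(ConfigError):
            ImputationSpec("MI-NI", interaction_terms=frozenset({("X", "Y")}))
        with pytest.raises(ConfigError):
            ImputationSpec("MI-EG", stratify_by_exposure=False)
        with pytest.raises(ConfigError):
            ImputationSpec("MI-NI", m=1)

    def test_eg_imputation_count_rule(self, table):
        gen = table.generation_config(0.30, 0.0, n=2000)
        mis = table.missingness_config(0.30, "outcome_only", "ii")
        inc = impose_missingness(generate_complete(gen, seed=8), mis, seed=9)
        m = eg_imputation_count(inc)
        # exposed missingness ~ 48% in scenario (ii) at 30% prevalence
        assert m >= 30
        assert m == max(30, eg_imputation_count(inc, minimum=2))


@pytest.fixture(scope="module")
def incomplete(table):
    gen = table.generation_config(0.30, -0.5, n=700)
    mis = table.missingness_config(0.30, "outcome_and_confounders", "iii")
    return impose_missingness(generate_complete(gen, seed=71), mis, seed=72)


class TestEngineInvariants:
    def test_zero_masked_cells_returns_input(self, table):
        gen = table.generation_config(0.30, 0.0, n=300)
        data = generate_complete(gen, seed=20)
        mis = table.missingness_config(0.30, "outcome_only", "i")
        inc = impose_missingness(data, mis, seed=21)
        inc.indicators[:] = 0
        for attr in ("mask", "values", "mask_any"):  # rebuild cached views
            inc.__dict__.pop(attr, None)
        stack = impute_fcs(inc, _spec("MI-NI", masked=("Y",)), seed=3)
        assert stack.m == 5
        for arr in stack.arrays:
            np.testing.assert_array_equal(arr, inc.true_values)

    def test_observed_cells_preserved_and_binaries_valid(self, incomplete):
        stack = impute_fcs(incomplete, _spec("MI-ExI"), seed=4)
        obs = ~incomplete.mask
        col = incomplete.column_index
        for arr in stack.arrays:
            np.testing.assert_array_equal(arr[obs], incomplete.true_values[obs])
            assert not np.isnan(arr).any()
            for v in ("C4", "C5"):
                assert set(np.unique(arr[:, col[v]])) <= {0.0, 1.0}
        # streams differ on masked cells
        assert not np.array_equal(stack.arrays[0], stack.arrays[1])

    def test_determinism_and_stream_independence(self, incomplete):
        a = impute_fcs(incomplete, _spec("MI-NI"), seed=5)
        b = impute_fcs(incomplete, _spec("MI-NI"), seed=5)
        for x, y in zip(a.arrays, b.arrays):
            np.testing.assert_array_equal(x, y)
        c = impute_fcs(incomplete, _spec("MI-NI"), seed=6)
        assert not np.array_equal(a.arrays[0], c.arrays[0])

    def test_stratified_recombination_preserves_rows(self, incomplete):
        stack = impute_fcs(incomplete, _spec("MI-EG"), seed=7)
        col = incomplete.column_index
        for arr in stack.arrays:
            np.testing.assert_array_equal(
                arr[:, col["X"]], incomplete.true_values[:, col["X"]]
            )
            obs = ~incomplete.mask
            np.testing.assert_array_equal(arr[obs], incomplete.true_values[obs])

    def test_degenerate_stratum_raises(self, table):
        gen = table.generation_config(0.30, 0.0, n=40)
        data = generate_complete(gen, seed=23)
        mis = table.missingness_config(0.30, "outcome_and_confounders", "i")
        inc = impose_missingness(data, mis, seed=24)
        with pytest.raises(DegenerateStratumError):
            impute_fcs(inc, _spec("MI-EG"), seed=8)

    def test_cca_label_rejected(self, incomplete):
        with pytest.raises(ConfigError):
            impute_fcs(incomplete, ImputationSpec.from_method("CCA"), seed=1)


class TestGaussianImputer:
    def test_conjugate_posterior_oracle(self, rng):
        """Moments of the posterior-predictive draws match the closed-form
        normal-inverse-chi-square posterior for a small fixture."""
        n_obs, p = 50, 3
        x = np.column_stack([np.ones(n_obs), rng.standard_normal((n_obs, p - 1))])
        beta_true = np.array([1.0, 2.0, -1.0])
        y = x @ beta_true + 0.7 * rng.standard_normal(n_obs)
        x0 = np.array([[1.0, 0.5, -0.5]])
        draws = np.array(
            [
                impute_univariate_gaussian(y, x, x0, rng)[0]
                for _ in range(40_000)
            ]
        )
        xtx_inv = np.linalg.inv(x.T @ x)
        beta_hat = xtx_inv @ x.T @ y
        rss = float((y - x @ beta_hat) @ (y - x @ beta_hat))
        dof = n_obs - p
        exp_sigma2 = rss / (dof - 2)  # mean of the scaled inverse chi-square
        mean_oracle = (x0 @ beta_hat).item()
        var_oracle = exp_sigma2 * (1.0 + (x0 @ xtx_inv @ x0.T).item())
        assert draws.mean() == pytest.approx(
            mean_oracle, abs=4 * np.sqrt(var_oracle / draws.size)
        )
        # chi-square MC error on the variance: ~4 relative SDs
        assert draws.var() == pytest.approx(var_oracle, rel=0.08)

    def test_degenerate_constant_target(self, rng):
        x = np.ones((40, 1))
        y = np.ones(40)
        draws = impute_univariate_gaussian(y, x, np.ones((5, 1)), rng)
        np.testing.assert_allclose(draws, 1.0, atol=1e-12)

    def test_collinear_columns_dropped(self, rng):
        x = np.column_stack([np.ones(30), rng.standard_normal(30)])
        x = np.column_stack([x, x[:, 1]])  # duplicated column
        y = x[:, 1] + rng.standard_normal(30)
        draws = impute_univariate_gaussian(y, x, x[:5], rng)
        assert np.isfinite(draws).all()


class TestLogisticImputer:
    def test_irls_oracle_and_draw_moments(self, rng):
        """MLE agrees with an independent IRLS fit (statsmodels) and the mean
        of the coefficient draws stays within Monte-Carlo error of it."""
        sm = pytest.importorskip("statsmodels.api")
        n = 10_000
        x = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
        beta_true = np.array([-0.3, 0.8, -0.5])
        y = (rng.random(n) < expit(x @ beta_true)).astype(float)
        beta, info_chol = _logistic_fit(y, x)
        oracle = sm.Logit(y, x).fit(disp=0)
        np.testing.assert_allclose(beta, oracle.params, atol=2e-4)
        cov = np.linalg.inv(info_chol @ info_chol.T)
        np.testing.assert_allclose(cov, oracle.cov_params(), rtol=0.02, atol=1e-6)
        # imputed-value rate at a probe point matches the fitted probability
        x0 = np.tile([1.0, 1.0, 0.0], (20_000, 1))
        draws = impute_univariate_logistic(y, x, x0, rng)
        p0 = expit(np.array([1.0, 1.0, 0.0]) @ oracle.params)
        assert draws.mean() == pytest.approx(p0, abs=0.02)

    def test_separation_engages_ridge_and_stays_finite(self, rng):
        n = 60
        z = np.r_[np.zeros(30), np.ones(30)]
        x = np.column_stack([np.ones(n), z])
        y = z.copy()  # perfectly separated
        diag = {}
        draws = impute_univariate_logistic(y, x, x, rng, diagnostics=diag)
        assert diag.get("n_ridge_fallbacks", 0) >= 1
        assert set(np.unique(draws)) <= {0.0, 1.0}

    def test_one_class_target_imputes_that_class_mostly(self, rng):
        x = np.column_stack([np.ones(80), rng.standard_normal(80)])
        y = np.ones(80)
        draws = np.concatenate(
            [impute_univariate_logistic(y, x, x, rng) for _ in range(20)]
        )
        assert draws.mean() > 0.9
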