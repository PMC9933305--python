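"""Analysis-model fitting, CCA, Rubin's-rules pooling and method dispatch."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import mistrat as ms
from mistrat.datagen import COLUMNS, generate_complete
from mistrat.errors import EstimationError, PoolingError
from mistrat.estimation import apply_method, cca_estimate, fit_outcome_regression, pool_rubin
from mistrat.fcs_imputer import ImputationSpec
from mistrat.missingness import impose_missingness


def _toy_frame(n=8, seed=0):
    rng = np.random.Generator(np.random.PCG64(seed))
    frame = pd.DataFrame(
        rng.integers(0, 2, (n, 6)).astype(float), columns=["X", "C1", "C2", "C3", "C4", "C5"]
    )
    frame["A"] = rng.standard_normal(n)
    frame["Y"] = rng.standard_normal(n) + frame["X"]
    return frame[list(COLUMNS)]


def test_fit_matches_normal_equations_oracle():
    """Direct matrix solve of the normal equations on a tiny dataset."""
    frame = _toy_frame(n=8, seed=4)
    design = np.column_stack(
        [np.ones(8)] + [frame[v].to_numpy() for v in ("X", "C1", "C2", "C3", "C4", "C5")]
    )
    y = frame["Y"].to_numpy()
    beta_oracle = np.linalg.solve(design.T @ design, design.T @ y)
    fit = fit_outcome_regression(frame)
    np.testing.assert_allclose(fit.params.to_numpy(), beta_oracle, atol=1e-10)
    assert fit.df_resid == 1


def test_fit_matches_statsmodels_oracle():
    sm = pytest.importorskip("statsmodels.api")
    frame = _toy_frame(n=60, seed=5)
    design = sm.add_constant(
        frame[["X", "C1", "C2", "C3", "C4", "C5"]].to_numpy()
    )
    oracle = sm.OLS(frame["Y"].to_numpy(), design).fit()
    fit = fit_outcome_regression(frame)
    np.testing.assert_allclose(fit.params.to_numpy(), oracle.params, atol=1e-10)
    np.testing.assert_allclose(fit.cov.to_numpy(), oracle.cov_params(), atol=1e-10)
    assert fit.df_resid == int(oracle.df_resid)


def test_fit_rejects_missing_and_collinear_data():
    frame = _toy_frame(n=30, seed=6)
    bad = frame.copy()
    bad.loc[0, "Y"] = np.nan
    with pytest.raises(EstimationError):
        fit_outcome_regression(bad)
    collinear = frame.copy()
    collinear["C1"] = collinear["X"]
    collinear["C2"] = collinear["X"]
    with pytest.raises(EstimationError):
        fit_outcome_regression(collinear)


class TestCCA:
    def test_no_missingness_equals_full_fit(self, table):
        gen = table.generation_config(0.30, 0.0, n=400)
        data = generate_complete(gen, seed=60)
        mis = table.missingness_config(0.30, "outcome_only", "i")
        inc = impose_missingness(data, mis, seed=61)
        inc.indicators[:] = 0
        for attr in ("mask", "values", "mask_any"):
            inc.__dict__.pop(attr, None)
        rec = cca_estimate(inc)
        full = fit_outcome_regression(data.frame)
        assert rec.theta1_hat == pytest.approx(full.params["X"], abs=1e-12)
        assert rec.n_complete_cases == 400

    def test_complete_case_count_under_thinning(self, table):
        gen = table.generation_config(0.30, 0.0, n=5000)
        data = generate_complete(gen, seed=62)
        mis = table.missingness_config(0.30, "outcome_only", "i")
        inc = impose_missingness(data, mis, seed=63)
        rec = cca_estimate(inc)
        assert rec.n_complete_cases == pytest.approx(0.7 * 5000, rel=0.05)
        assert rec.ci_low < rec.theta1_hat < rec.ci_high


class TestPoolRubin:
    def test_identical_estimates_have_no_between_variance(self):
        qbar, se, df = pool_rubin([0.5] * 4, [0.1] * 4, df_complete=100)
        assert qbar == 0.5
        assert se == pytest.approx(0.1, abs=1e-12)

    def test_two_estimate_worked_example(self):
        """Hand evaluation: pooled 0.3, B = 0.02, T = 0.01 + 1.5*0.02 = 0.04."""
        qbar, se, _ = pool_rubin([0.2, 0.4], [0.1, 0.1], df_complete=50)
        assert qbar == pytest.approx(0.3, abs=1e-15)
        assert se**2 == pytest.approx(0.04, abs=1e-15)

    @settings(max_examples=200, deadline=None)
    @given(
        data=st.lists(
            st.tuples(
                st.floats(-5, 5),
                st.floats(0.01, 2.0),
            ),
            min_size=2,
            max_size=40,
        ),
        df_complete=st.integers(5, 5000),
    )
    def test_brute_force_oracle(self, data, df_complete):
        """Agreement with an independently coded implementation to 1e-12."""
        q = [d[0] for d in data]
        u = [d[1] for d in data]
        m = len(q)
        qbar_o = sum(q) / m
        w_o = sum(x * x for x in u) / m
        b_o = sum((x - qbar_o) ** 2 for x in q) / (m - 1)
        t_o = w_o + (1 + 1 / m) * b_o
        qbar, se, df = pool_rubin(q, u, df_complete=df_complete)
        assert qbar == pytest.approx(qbar_o, abs=1e-12)
        assert se == pytest.approx(np.sqrt(t_o), abs=1e-12)
        lam = (1 + 1 / m) * b_o / t_o
        if lam**2 > 0:
            df_old = (m - 1) / lam**2
            df_obs = (df_complete + 1) / (df_complete + 3) * df_complete * (1 - lam)
            assert df == pytest.approx(
                min(1 / (1 / df_old + 1 / df_obs), 1e12), rel=1e-9
            )
            _, _, df_r = pool_rubin(q, u, df_method="rubin")
            assert df_r == pytest.approx(min(df_old, 1e12), rel=1e-9)

    def test_too_few_imputations_raise(self):
        with pytest.raises(PoolingError):
            pool_rubin([0.3], [0.1], df_complete=10)


class TestApplyMethod:
    def test_zero_masked_cells_reduce_to_full_fit(self, table):
        gen = table.generation_config(0.30, 0.0, n=300)
        data = generate_complete(gen, seed=64)
        mis = table.missingness_config(0.30, "outcome_only", "i")
        inc = impose_missingness(data, mis, seed=65)
        inc.indicators[:] = 0
        for attr in ("mask", "values", "mask_any"):
            inc.__dict__.pop(attr, None)
        full = fit_outcome_regression(data.frame)
        for label in ("CCA", "MI-NI", "MI-EG"):
            spec = ImputationSpec.from_method(label, masked_variables=("Y",), m=5)
            rec = apply_method(inc, spec, seed=2)
            assert rec.theta1_hat == pytest.approx(full.params["X"], abs=1e-10)

    def test_cca_and_mini_agree_at_large_n(self, table):
        """Outcome-only missingness not depending on Y: MI with no
        interactions is asymptotically equivalent to complete-case analysis."""
        gen = table.generation_config(0.30, 0.0, n=60_000)
        data = generate_complete(gen, seed=66)
        mis = table.missingness_config(0.30, "outcome_only", "i")
        inc = impose_missingness(data, mis, seed=67)
        cca = apply_method(inc, ImputationSpec.from_method("CCA"), seed=3)
        mini = apply_method(
            inc, ImputationSpec.from_method("MI-NI", masked_variables=("Y",), m=20), seed=3
        )
        assert mini.theta1_hat == pytest.approx(cca.theta1_hat, abs=3 * cca.se / 4)

    def test_estimate_record_carries_provenance(self, table):
        gen = table.generation_config(0.30, 0.5, n=700)
        data = generate_complete(gen, seed=68)
        mis = table.missingness_config(0.30, "outcome_only", "ii")
        inc = impose_missingness(data, mis, seed=69)
        spec = ImputationSpec.from_method("MI-ExC", masked_variables=("Y",), m=4)
        rec = apply_method(inc, spec, seed=4, replicate=7, scenario={"delta": 0.5})
        assert rec.m_used == 4
        assert rec.replicate == 7
        assert rec.scenario["delta"] == 0.5
        assert rec.ci_low < rec.theta1_hat < rec.ci_high
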