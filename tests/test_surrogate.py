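"""Surrogate regressions: features, OLS, published equations, chaining."""

import numpy as np
import pandas as pd
import pytest

import aortameta as am
from aortameta.surrogate import (
    PUBLISHED_MODELS,
    RatioTerm,
    SURROGATE_SPECS,
    build_features,
    chain_predict,
    chain_predict_record,
    correlation_report,
    fit_all_surrogates,
    fit_linear,
    load_models,
    save_models,
)

RECORD = {"D1": 10.0, "D2": 10.5, "D3": 9.0, "D0": 6.0, "D4": 9.0,
          "D5": 9.0, "DBCA": 5.0, "DLCCA": 4.0, "DLSCA": 4.0}


class TestFeatures:
    def test_single_ratio_term(self):
        x = build_features({"D1": 10.0, "DBCA": 5.0},
                           [RatioTerm("D1", "DBCA")])
        assert np.isclose(x[0], 0.4)

    def test_denominator_scaling_homogeneity(self):
        terms = SURROGATE_SPECS["v_O5"].terms
        base = build_features(RECORD, terms)
        scaled = dict(RECORD)
        k = 2.5
        scaled["D5"] = k * scaled["D5"]
        assert np.allclose(build_features(scaled, terms), base / k ** 2)

    def test_matches_hand_coded_oracle_for_vM4_spec(self):
        """All four ratio regressors of the v(M4) form, recomputed by hand."""
        m = RECORD
        expected = np.array([m["D1"] / m["D4"] ** 2,
                             m["DBCA"] / m["D4"] ** 2,
                             m["DLCCA"] / m["D4"] ** 2,
                             m["D3"] / m["D4"] ** 2,
                             7.7])
        got = build_features(m, SURROGATE_SPECS["v_M4"].terms, p_hat_P1=7.7,
                             chain_pressure=True)
        assert np.allclose(got, expected)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ZeroDivisionError, match="DBCA"):
            build_features({"D1": 1.0, "DBCA": 0.0},
                           [RatioTerm("D1", "DBCA")])

    def test_unknown_diameter_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            RatioTerm("D9")


class TestFitLinear:
    def test_exact_linear_data_recovered(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 3))
        beta = np.array([1.5, -2.0, 0.25])
        y = 4.0 + X @ beta
        b0, coef, diag = fit_linear(X, y)
        assert abs(b0 - 4.0) < 1e-8
        assert np.allclose(coef, beta, atol=1e-8)
        assert diag["r_squared"] > 1.0 - 1e-12

    def test_constant_response_gives_zero_r2(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 2))
        _, coef, diag = fit_linear(X, np.full(20, 3.0))
        assert np.allclose(coef, 0.0, atol=1e-10)
        assert diag["r_squared"] == 0.0

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        b0, coef, _ = fit_linear(X, y)
        A = np.column_stack([np.ones(20), X])
        oracle = np.linalg.solve(A.T @ A, A.T @ y)
        assert abs(b0 - oracle[0]) < 1e-8
        assert np.allclose(coef, oracle[1:], atol=1e-8)

    def test_diagnostics_match_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 4))
        y = X @ [1, 0.5, 0, -1] + rng.normal(size=40)
        b0, coef, diag = fit_linear(X, y)
        ref = sm.OLS(y, sm.add_constant(X)).fit()
        assert np.allclose([b0, *coef], ref.params, atol=1e-10)
        assert abs(diag["r_squared"] - ref.rsquared) < 1e-10
        assert abs(diag["p_level"] - ref.f_pvalue) < 1e-10
        assert np.allclose(diag["stderr"], ref.bse, atol=1e-10)

    def test_rank_deficiency_names_collinear_terms(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=20)
        X = np.column_stack([x, 2 * x, rng.normal(size=20)])
        with pytest.raises(ValueError, match="collinear"):
            fit_linear(X, rng.normal(size=20), ["a", "twice_a", "b"])

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="n > p"):
            fit_linear(np.ones((3, 3)), np.ones(3))


class TestPublishedEquations:
    def test_intercepts_at_zero_diameters(self):
        """With every regressor zeroed only the intercepts remain."""
        zero = {k: 0.0 for k in RECORD}
        for resp, expect in (("p_P1", 11.14), ("p_M2", 11.2)):
            m = PUBLISHED_MODELS[resp]
            x = np.zeros(len(m.coef))
            assert np.isclose(m.intercept + x @ m.coef, expect)
        m = PUBLISHED_MODELS["v_OBCA"]
        assert np.isclose(m.intercept, -0.42)

    def test_inlet_pressure_hand_arithmetic(self):
        m = {"D1": 10.0, "DBCA": 8.0, "D0": 6.0, "D5": 9.0}
        full = {**RECORD, **m}
        assert round(am.predict_pressure_P1(full), 2) == 16.03

    def test_d0_coefficient_lowers_inlet_pressure(self):
        a = dict(RECORD)
        b = dict(RECORD)
        b["D0"] += 1.0
        diff = am.predict_pressure_P1(b) - am.predict_pressure_P1(a)
        assert np.isclose(diff, -0.55)

    def test_branch_velocity_hand_arithmetic(self):
        m = {**RECORD, "D1": 8.0, "D0": 4.0, "D4": 8.0, "DBCA": 2.0}
        assert round(am.predict_velocity(m, "OBCA", p_hat_P1=10.0), 2) == 1.35

    def test_wider_d0_slows_branch_velocity(self):
        """Without coarctation less flow is diverted into the branches."""
        a = dict(RECORD)
        b = dict(RECORD)
        b["D0"] += 2.0
        p = am.predict_pressure_P1(a)
        # direct term only (same chained pressure): the D0 coefficient is negative
        assert (am.predict_velocity(b, "OBCA", p)
                < am.predict_velocity(a, "OBCA", p))
        # full chain: the D0 path through p(P1) does not flip the sign
        assert (chain_predict_record(b)["v_OBCA"]
                < chain_predict_record(a)["v_OBCA"])

    def test_unknown_velocity_name_rejected(self):
        with pytest.raises(ValueError, match="M3"):
            am.predict_velocity(RECORD, "M3", 10.0)


class TestChaining:
    def test_chain_equals_manual_two_step(self):
        p_hat = am.predict_pressure_P1(RECORD)
        manual = {
            "p_P1": p_hat,
            "p_M2": am.predict_pressure_M2(RECORD),
            "v_OBCA": am.predict_velocity(RECORD, "OBCA", p_hat),
            "v_M4": am.predict_velocity(RECORD, "M4", p_hat),
            "v_O5": am.predict_velocity(RECORD, "O5", p_hat),
        }
        assert chain_predict_record(RECORD) == manual

    def test_sensitivity_matches_finite_differences(self):
        """Perturbing D1 moves v(O5) through both the direct ratio term and
        the chained p(P1) path; the analytic total matches finite
        differences."""
        h = 1e-6
        up, dn = dict(RECORD), dict(RECORD)
        up["D1"] += h
        dn["D1"] -= h
        fd = (chain_predict_record(up)["v_O5"]
              - chain_predict_record(dn)["v_O5"]) / (2 * h)
        mo = PUBLISHED_MODELS["v_O5"]
        direct = mo.coef[0] / RECORD["D5"] ** 2
        through_pressure = mo.coef[-1] * PUBLISHED_MODELS["p_P1"].coef[0]
        assert abs(fd - (direct + through_pressure)) < 1e-6
        assert abs(through_pressure) > 0  # the indirect path contributes

    def test_noise_free_equation_cohort_identifies_truth(self):
        cfg = am.CohortConfig(seed=5, hemodynamics_model="equation",
                              ).with_noise_scale(0.0)
        df = am.generate_cohort(cfg)
        models = fit_all_surrogates(df)
        for resp, m in models.items():
            pub = PUBLISHED_MODELS[resp]
            assert abs(m.intercept - pub.intercept) < 1e-6
            assert np.allclose(m.coef, pub.coef, atol=1e-6)

    def test_table_prediction_matches_per_record(self, default_cohort):
        table = chain_predict(default_cohort)
        row = default_cohort.iloc[13]
        rec = chain_predict_record({k: row[k] for k in RECORD})
        for resp, value in rec.items():
            assert np.isclose(table[resp].iloc[13], value)


class TestCorrelationReport:
    def test_perfect_prediction_gives_unit_r(self, default_cohort):
        obs = default_cohort[["p_P1", "v_O5"]]
        rep = correlation_report(obs, obs.copy())
        assert np.allclose(rep["r"], 1.0)

    def test_independent_prediction_is_null(self):
        rng = np.random.default_rng(0)
        hits = 0
        n_seeds = 200
        for _ in range(n_seeds):
            obs = pd.DataFrame({"v_O5": rng.normal(size=60)})
            pred = pd.DataFrame({"v_O5": rng.normal(size=60)})
            r = correlation_report(obs, pred).loc["v_O5", "r"]
            hits += abs(r) < 0.35
        assert hits >= 0.95 * n_seeds

    def test_v_o5_is_best_predicted_on_default_cohort(self):
        """The hiatus-level velocity tops the observed-vs-predicted ranking."""
        best = 0
        ge_obca = 0
        for seed in range(20):
            df = am.generate_cohort(am.CohortConfig(seed=seed))
            models = fit_all_surrogates(df)
            rep = correlation_report(
                df[["p_P1", "p_M2", "v_OBCA", "v_M4", "v_O5"]],
                chain_predict(df, models))
            ge_obca += rep.loc["v_O5", "r"] >= rep.loc["v_OBCA", "r"]
            best += bool(rep.loc["v_O5", "best"])
        assert ge_obca >= 18
        assert best >= 15

    def test_too_few_pairs_rejected(self):
        df = pd.DataFrame({"v_O5": [1.0, 2.0]})
        with pytest.raises(ValueError):
            correlation_report(df, df.copy())


class TestSerialization:
    def test_models_round_trip_through_json(self, tmp_path, default_cohort):
        models = fit_all_surrogates(default_cohort)
        path = tmp_path / "models.json"
        save_models(models, path)
        back = load_models(path)
        for resp, m in models.items():
            b = back[resp]
            assert b.spec == m.spec
            assert np.allclose(b.coef, m.coef)
            assert b.intercept == m.intercept
            assert b.r_squared == m.r_squared
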