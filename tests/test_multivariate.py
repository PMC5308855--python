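"""Collinearity screen, predictor selection and the logistic fit."""

import numpy as np
import pandas as pd
import pytest

import pvscreen as pv
from pvscreen import multivariate as mv
from pvscreen.disproportionality import Contingency2x2, compute_signal


class TestCollinearityScreen:
    def test_duplicated_column_is_flagged(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=200)
        matrix = pd.DataFrame({"event": rng.integers(0, 2, 200).astype(float),
                               "x1": x, "x2": x})
        report = mv.collinearity_screen(matrix)
        assert report.has_internal_correlation
        assert report.flagged[0][:2] == ("x1", "x2")
        assert report.flagged[0][2] == pytest.approx(1.0)

    def test_negated_column_is_flagged(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=200)
        matrix = pd.DataFrame({"x1": x, "x2": np.exp(-x)})
        report = mv.collinearity_screen(matrix, exclude=())
        assert report.flagged[0][2] == pytest.approx(1.0)

    def test_independent_columns_not_flagged(self):
        rng = np.random.default_rng(3)
        matrix = pd.DataFrame(rng.uniform(size=(1000, 4)),
                              columns=["a", "b", "c", "d"])
        report = mv.collinearity_screen(matrix, exclude=())
        assert not report.has_internal_correlation

    def test_constant_column_reported_as_undefined(self):
        matrix = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        report = mv.collinearity_screen(matrix, exclude=())
        assert ("a", "b") in report.undefined

    def test_needs_two_columns(self):
        with pytest.raises(ValueError):
            mv.collinearity_screen(pd.DataFrame({"event": [0, 1], "a": [1.0, 2.0]}))


class TestSelectPredictors:
    def _result(self, label, a, p_scale):
        # contingency chosen so Fisher P is tiny when p_scale is small
        return compute_signal(label, Contingency2x2(a, 50, 5 * p_scale, 5000))

    def test_published_screen_shape_seven_drugs_plus_covariates(self):
        counts = [("dexamethasone", 6), ("levofolinate", 8), ("oxaliplatin", 12),
                  ("fluorouracil", 8), ("irinotecan", 5), ("carboplatin", 4),
                  ("cisplatin", 5)]
        results = [self._result(name, a, 1) for name, a in counts]
        terms = mv.select_predictors(results)
        assert len(terms) == 11
        assert set(mv.DEFAULT_COVARIATES) <= set(terms)
        assert "dexamethasone" in terms

    def test_drug_at_threshold_count_excluded(self):
        results = [self._result("borderline", 3, 1)]
        terms = mv.select_predictors(results)
        assert "borderline" not in terms

    def test_nonsignificant_drug_excluded(self):
        result = compute_signal("null-drug", Contingency2x2(5, 50, 500, 5000))
        assert result.p_value > 0.05
        assert "null-drug" not in mv.select_predictors([result])

    def test_empty_results_give_covariates_only(self):
        assert mv.select_predictors([]) == list(mv.DEFAULT_COVARIATES)


class TestModelMatrix:
    def test_case_level_aggregation_and_complete_cases(self, suspected_records):
        matrix = mv.build_model_matrix(suspected_records, "hiccups",
                                       ["dexamethasone"])
        assert not matrix.isna().any().any()
        assert set(matrix.columns) == {"event", "sex_male", "age", "height",
                                       "weight", "dexamethasone"}
        assert len(matrix) <= suspected_records["case_id"].nunique()
        assert set(matrix["dexamethasone"].unique()) <= {0.0, 1.0}

    def test_record_level_keeps_rows(self, suspected_records):
        case_level = mv.build_model_matrix(suspected_records, "hiccups", [])
        record_level = mv.build_model_matrix(suspected_records, "hiccups", [],
                                             unit="record")
        assert len(record_level) >= len(case_level)


class TestFitLogistic:
    def test_null_predictor_gives_zero_coefficient(self):
        # identical event rates in both arms
        y = np.repeat([1.0, 0.0, 1.0, 0.0], [20, 80, 20, 80])
        x = np.repeat([1.0, 0.0], [100, 100])
        fit = mv.fit_logistic(pd.DataFrame({"event": y, "arm": x}))
        assert fit["arm"].coefficient == pytest.approx(0.0, abs=1e-8)
        assert fit["arm"].p_value == pytest.approx(1.0, abs=1e-6)

    def test_reproduces_contingency_odds_ratio(self):
        # replica of a published-scale table, thinned 1:100 to keep the fit small
        a, b, c, d = 6, 164, 154, 9704
        y = np.repeat([1.0, 0.0, 1.0, 0.0], [a, b, c, d])
        x = np.repeat([1.0, 1.0, 0.0, 0.0], [a, b, c, d])
        fit = mv.fit_logistic(pd.DataFrame({"event": y, "exposed": x}))
        assert fit["exposed"].odds_ratio == pytest.approx(a * d / (b * c), rel=1e-6)

    def test_parameter_recovery_with_planted_log_odds(self):
        rng = np.random.default_rng(99)
        n = 50_000
        male = rng.integers(0, 2, n).astype(float)
        drug = (rng.random(n) < 0.1).astype(float)
        eta = -5.0 + 1.5 * male + 2.0 * drug
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        fit = mv.fit_logistic(pd.DataFrame({"event": y, "male": male, "drug": drug}))
        assert fit["male"].ci_low <= np.exp(1.5) <= fit["male"].ci_high
        assert fit["drug"].ci_low <= np.exp(2.0) <= fit["drug"].ci_high

    def test_matches_statsmodels_reference(self, suspected_records):
        import statsmodels.api as sm

        matrix = mv.build_model_matrix(suspected_records, "hiccups",
                                       ["dexamethasone", "oxaliplatin"])
        fit = mv.fit_logistic(matrix)
        X = sm.add_constant(matrix.drop(columns="event"))
        reference = sm.Logit(matrix["event"], X).fit(disp=0)
        for term in ("dexamethasone", "sex_male", "height"):
            assert fit[term].coefficient == pytest.approx(
                reference.params[term], rel=1e-5, abs=1e-8)
            assert fit[term].std_error == pytest.approx(
                reference.bse[term], rel=1e-4)

    def test_complete_separation_names_the_term(self):
        y = np.repeat([1.0, 0.0], [15, 15])
        x = np.repeat([1.0, 0.0], [15, 15])
        noise = np.tile([0.0, 1.0], 15)
        with pytest.raises(mv.SeparationError, match="culprit"):
            mv.fit_logistic(pd.DataFrame({"event": y, "culprit": x, "noise": noise}))

    def test_quasi_separation_detected_or_firth_recovers(self):
        # no events among the unexposed: the unpenalized MLE diverges
        y = np.repeat([1.0, 0.0, 0.0], [5, 5, 90])
        x = np.repeat([1.0, 1.0, 0.0], [5, 5, 90])
        with pytest.raises(mv.SeparationError):
            mv.fit_logistic(pd.DataFrame({"event": y, "drug": x}))
        firth = mv.fit_logistic(pd.DataFrame({"event": y, "drug": x}), firth=True)
        assert np.isfinite(firth["drug"].coefficient)

    def test_rescaling_covariate_rescales_coefficient_only(self):
        rng = np.random.default_rng(5)
        n = 4000
        height = rng.normal(160, 10, n)
        eta = -4.0 + 0.05 * (height - 160)
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        fit_cm = mv.fit_logistic(pd.DataFrame({"event": y, "height": height}))
        fit_m = mv.fit_logistic(pd.DataFrame({"event": y, "height": height / 100}))
        assert fit_m["height"].coefficient == pytest.approx(
            100 * fit_cm["height"].coefficient, rel=1e-6)
        assert fit_m["height"].p_value == pytest.approx(
            fit_cm["height"].p_value, rel=1e-6)

    def test_wald_ci_coverage_over_simulations(self):
        rng = np.random.default_rng(1234)
        n, n_sims = 2000, 500
        covered_male = covered_drug = 0
        for _ in range(n_sims):
            male = rng.integers(0, 2, n).astype(float)
            drug = (rng.random(n) < 0.15).astype(float)
            eta = -3.0 + 1.0 * male + 1.2 * drug
            y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
            fit = mv.fit_logistic(pd.DataFrame({"event": y, "male": male,
                                                "drug": drug}))
            covered_male += (fit["male"].ci_low <= np.exp(1.0)
                             <= fit["male"].ci_high)
            covered_drug += (fit["drug"].ci_low <= np.exp(1.2)
                             <= fit["drug"].ci_high)
        assert covered_male / n_sims == pytest.approx(0.95, abs=0.03)
        assert covered_drug / n_sims == pytest.approx(0.95, abs=0.03)

    def test_non_binary_response_rejected(self):
        with pytest.raises(ValueError):
            mv.fit_logistic(pd.DataFrame({"event": [0.0, 0.5, 1.0],
                                          "x": [1.0, 2.0, 3.0]}))

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError):
            mv.fit_logistic(pd.DataFrame({"event": [0.0, 1.0, np.nan],
                                          "x": [1.0, 2.0, 3.0]}))


def test_coefficient_table_sorted_by_descending_or(suspected_records):
    matrix = mv.build_model_matrix(suspected_records, "hiccups", ["dexamethasone"])
    fit = mv.fit_logistic(matrix)
    table = mv.coefficient_table(fit)
    assert "intercept" not in table["term"].tolist()
    assert table["odds_ratio"].is_monotonic_decreasing
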