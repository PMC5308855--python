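"""ROR, Woolf interval, two-sided Fisher test, signal rule and screens."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pvscreen as pv
from pvscreen.disproportionality import VOLCANO_BASELINE, compute_signal

from conftest import fisher_two_sided_oracle

cell = st.integers(min_value=0, max_value=30)


class TestContingency:
    def test_rejects_negative_and_empty_tables(self):
        with pytest.raises(ValueError):
            pv.Contingency2x2(-1, 1, 1, 1)
        with pytest.raises(ValueError):
            pv.Contingency2x2(0, 0, 0, 0)

    def test_build_from_records_partitions_units(self, suspected_records):
        t = pv.build_contingency(
            suspected_records,
            lambda df: df["drug_name"] == "dexamethasone",
            lambda df: df["event_term"] == "hiccups",
        )
        assert t.total == len(suspected_records)

    def test_direct_count_four_records(self):
        db = pv.fixture_from_counts(1, 1, 1, 1, exposure_label="drugX",
                                    comparator_label="drugY")
        records = pv.build_all_data_table(db).records
        t = pv.build_contingency(records, lambda df: df["drug_name"] == "drugX",
                                 lambda df: df["event_term"] == "hiccups")
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)

    def test_exposure_never_true_gives_empty_exposed_row(self, suspected_records):
        t = pv.build_contingency(
            suspected_records,
            lambda df: df["drug_name"] == "no-such-drug",
            lambda df: df["event_term"] == "hiccups",
        )
        assert (t.a, t.b) == (0, 0)

    def test_case_unit_counts_unique_cases(self, suspected_records):
        t = pv.build_contingency(
            suspected_records,
            lambda df: df["drug_name"] == "dexamethasone",
            lambda df: df["event_term"] == "hiccups",
            unit="case",
        )
        assert t.total == suspected_records["case_id"].nunique()

    def test_empty_records_raise(self, suspected_records):
        with pytest.raises(ValueError, match="empty"):
            pv.build_contingency(suspected_records.iloc[:0],
                                 lambda df: df["drug_name"] == "x",
                                 lambda df: df["event_term"] == "y")

    def test_planted_counts_recovered_through_pipeline(self):
        db = pv.fixture_from_counts(7, 93, 41, 859)
        records = pv.filter_suspected(pv.build_all_data_table(db).records)
        t = pv.build_contingency(records, lambda df: df["drug_name"] == "drug-x",
                                 lambda df: df["event_term"] == "hiccups")
        assert (t.a, t.b, t.c, t.d) == (7, 93, 41, 859)


class TestRor:
    def test_symmetric_table_gives_unity(self):
        assert pv.compute_ror(pv.Contingency2x2(5, 5, 5, 5)) == 1.0

    def test_direct_arithmetic(self):
        ror = pv.compute_ror(pv.Contingency2x2(6, 1641, 154, 970419))
        assert ror == pytest.approx(23.04, abs=0.005)

    def test_zero_numerator_gives_zero(self):
        assert pv.compute_ror(pv.Contingency2x2(0, 10, 10, 10)) == 0.0

    def test_zero_denominator_is_undefined(self):
        assert math.isnan(pv.compute_ror(pv.Contingency2x2(5, 0, 5, 5)))
        assert math.isnan(pv.compute_ror(pv.Contingency2x2(5, 5, 0, 5)))

    def test_continuity_correction_keeps_ratio_defined(self):
        ror = pv.compute_ror(pv.Contingency2x2(5, 0, 5, 5), continuity=True)
        assert ror == pytest.approx((5.5 * 5.5) / (0.5 * 5.5))

    @given(a=cell, b=cell, c=cell, d=cell)
    def test_transpose_symmetry(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        original = pv.compute_ror(pv.Contingency2x2(a, b, c, d))
        swapped = pv.compute_ror(pv.Contingency2x2(a, c, b, d))
        if math.isnan(original):
            assert math.isnan(swapped)
        else:
            assert swapped == pytest.approx(original, rel=1e-12)


class TestWoolfCI:
    def test_known_interval(self):
        low, high = pv.ror_ci(pv.Contingency2x2(5, 5, 5, 5))
        assert low == pytest.approx(0.173, abs=5e-4)
        assert high == pytest.approx(5.772, abs=5e-3)

    @given(a=st.integers(1, 40), b=st.integers(1, 40))
    def test_log_symmetry_when_cells_pair_up(self, a, b):
        # with a=d and b=c the interval is symmetric about ROR on the log scale
        t = pv.Contingency2x2(a, b, b, a)
        low, high = pv.ror_ci(t)
        assert low * high == pytest.approx(pv.compute_ror(t) ** 2, rel=1e-9)

    def test_wider_level_strictly_contains_narrower(self):
        t = pv.Contingency2x2(6, 1641, 154, 970419)
        lo95, hi95 = pv.ror_ci(t, level=0.95)
        lo99, hi99 = pv.ror_ci(t, level=0.99)
        assert lo99 < lo95 < hi95 < hi99

    def test_zero_cell_undefined_without_correction(self):
        assert all(math.isnan(v) for v in pv.ror_ci(pv.Contingency2x2(0, 5, 5, 5)))
        low, high = pv.ror_ci(pv.Contingency2x2(0, 5, 5, 5), continuity=True)
        assert 0 < low < high

    def test_coverage_at_fixed_true_odds_ratio(self):
        # two-arm binomial tables, all expected cells >= 5, true OR = 2
        rng = np.random.default_rng(20240917)
        n1 = n0 = 200
        p0 = 0.2
        true_or = 2.0
        p1 = true_or * p0 / (1 - p0) / (1 + true_or * p0 / (1 - p0))
        covered = 0
        n_tables = 1200
        for _ in range(n_tables):
            a = int(rng.binomial(n1, p1))
            c = int(rng.binomial(n0, p0))
            t = pv.Contingency2x2(a, n1 - a, c, n0 - c)
            low, high = pv.ror_ci(t)
            covered += bool(low <= true_or <= high)
        assert covered / n_tables == pytest.approx(0.95, abs=0.02)


class TestFisher:
    def test_reproduces_printed_route_p_values(self):
        assert pv.fisher_exact_two_sided(
            pv.Contingency2x2(2, 3379, 158, 968681)) == pytest.approx(0.108, abs=5e-4)
        assert pv.fisher_exact_two_sided(pv.Contingency2x2(0, 950, 160, 971110)) == 1.0

    def test_modal_table_from_enumeration(self):
        assert pv.fisher_exact_two_sided(pv.Contingency2x2(2, 3, 4, 5)) == \
            pytest.approx(fisher_two_sided_oracle(2, 3, 4, 5), rel=1e-9)

    def test_zero_margin_convention(self):
        assert pv.fisher_exact_two_sided(pv.Contingency2x2(0, 0, 5, 5)) == 1.0
        assert pv.fisher_exact_two_sided(pv.Contingency2x2(0, 5, 0, 5)) == 1.0

    @settings(max_examples=300, derandomize=True)
    @given(a=cell, b=cell, c=cell, d=cell)
    def test_matches_enumeration_oracle(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        ours = pv.fisher_exact_two_sided(pv.Contingency2x2(a, b, c, d))
        assert ours == pytest.approx(fisher_two_sided_oracle(a, b, c, d), rel=1e-7)


class TestSignalRule:
    def test_printed_lower_limit_flags_signal(self):
        assert pv.evaluate_signal(22.6, 9.97) is True

    def test_boundary_is_strict(self):
        assert pv.evaluate_signal(2.0, 1.0) is False

    def test_undefined_ci_is_never_a_signal(self):
        assert pv.evaluate_signal(math.nan, math.nan) is False

    @given(a=st.integers(0, 25), b=st.integers(0, 25),
           c=st.integers(0, 25), d=st.integers(0, 25))
    def test_flag_fires_iff_ci_low_above_one(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        t = pv.Contingency2x2(a, b, c, d)
        result = compute_signal("x", t)
        low = result.ci_low
        assert result.is_signal == (not math.isnan(low) and low > 1)


class TestVolcano:
    @pytest.mark.parametrize("ror, p, expected", [
        (1.0, 1.0, (0.0, 0.0)),
        (math.e, 0.1, (1.0, 1.0)),
        (22.6, 1e-4, (3.118, 4.0)),
    ])
    def test_coordinates(self, ror, p, expected):
        x, y = pv.volcano_coordinates(ror, p)
        assert x == pytest.approx(expected[0], abs=5e-4)
        assert y == pytest.approx(expected[1], abs=1e-9)

    def test_significance_baseline(self):
        assert VOLCANO_BASELINE == pytest.approx(1.301, abs=5e-4)
        _, just_significant = pv.volcano_coordinates(1.0, 0.05)
        assert just_significant == pytest.approx(VOLCANO_BASELINE)
        _, y = pv.volcano_coordinates(1.0, 0.049)
        assert y > VOLCANO_BASELINE

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            pv.volcano_coordinates(0.0, 0.5)
        with pytest.raises(ValueError):
            pv.volcano_coordinates(1.0, 0.0)


class TestScreens:
    def test_planted_signal_has_smallest_p(self):
        spec = pv.SyntheticSpec(
            n_cases=50_000, seed=42, male_log_odds=0.0,
            drugs=tuple(
                [pv.DrugSpec("planted", prevalence=0.05, event_odds_multiplier=5.0)]
                + [pv.DrugSpec(f"null-{i}", prevalence=0.04) for i in range(9)]
            ),
        )
        db, _ = pv.generate_database(spec)
        suspected = pv.filter_suspected(pv.build_all_data_table(
            pv.deduplicate(db).database).records)
        results = pv.screen_drugs(suspected, "hiccups")
        assert results[0].exposure_label == "planted"
        assert results[0].is_signal

    def test_single_exposure_covering_all_records_degenerates(self):
        db = pv.fixture_from_counts(3, 7, 0, 0)
        records = pv.build_all_data_table(db).records
        records = records[records["drug_name"] == "drug-x"]
        results = pv.screen_drugs(records, "hiccups")
        only = results[0]
        assert (only.c, only.d) == (0, 0)
        assert math.isnan(only.ror)
        assert not only.is_signal

    def test_results_sorted_and_deterministic(self, suspected_records):
        first = pv.screen_drugs(suspected_records, "hiccups")
        second = pv.screen_drugs(suspected_records, "hiccups")
        assert [r.exposure_label for r in first] == [r.exposure_label for r in second]
        p_values = [r.p_value for r in first]
        assert p_values == sorted(p_values)

    def test_empty_axis_gives_empty_result(self, suspected_records):
        assert pv.screen_drugs(suspected_records, "hiccups", drugs=[]) == []

    def test_event_screen_matches_transposed_drug_screen(self, suspected_records):
        # sex-wise event screen: ROR of an event term vs male exposure equals the
        # ROR computed from the transposed table by hand
        results = pv.screen_events(suspected_records,
                                   lambda df: df["sex"] == "male",
                                   events=["hiccups"])
        t = pv.build_contingency(suspected_records,
                                 lambda df: df["sex"] == "male",
                                 lambda df: df["event_term"] == "hiccups")
        assert results[0].ror == pytest.approx(pv.compute_ror(t), rel=1e-12)


class TestFilterMinReports:
    def _result(self, label, a):
        return compute_signal(label, pv.Contingency2x2(a, 10, 20, 400))

    def test_strict_threshold(self):
        results = [self._result("A", 4), self._result("B", 3), self._result("C", 12)]
        kept = {r.exposure_label for r in pv.filter_min_reports(results, 3)}
        assert kept == {"A", "C"}

    def test_zero_threshold_keeps_reported(self):
        results = [self._result("A", 1), self._result("B", 5)]
        assert pv.filter_min_reports(results, 0) == results

    def test_published_screen_counts_all_pass(self):
        counts = {"dexamethasone": 6, "levofolinate": 8, "oxaliplatin": 12,
                  "fluorouracil": 8, "irinotecan": 5, "carboplatin": 4,
                  "cisplatin": 5}
        results = [self._result(name, a) for name, a in counts.items()]
        assert len(pv.filter_min_reports(results, 3)) == len(counts)


def test_benjamini_hochberg_is_monotone_extension(suspected_records):
    results = pv.screen_drugs(suspected_records, "hiccups")
    adjusted = pv.benjamini_hochberg(results)
    assert all(q >= r.p_value - 1e-12 for q, r in zip(adjusted, results))
    frame = pv.signal_table(results, adjusted=True)
    assert "p_bh_adjusted" in frame.columns


def test_logistic_odds_ratio_matches_contingency(suspected_records):
    """Cross-module check: single-binary-exposure logistic MLE equals ad/bc."""
    import pandas as pd

    from pvscreen import multivariate as mv

    t = pv.build_contingency(suspected_records,
                             lambda df: df["drug_name"] == "dexamethasone",
                             lambda df: df["event_term"] == "hiccups")
    y = np.repeat([1.0, 0.0, 1.0, 0.0], [t.a, t.b, t.c, t.d])
    x = np.repeat([1.0, 1.0, 0.0, 0.0], [t.a, t.b, t.c, t.d])
    fit = mv.fit_logistic(pd.DataFrame({"event": y, "exposed": x}))
    assert fit["exposed"].odds_ratio == pytest.approx(pv.compute_ror(t), rel=1e-6)
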