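"""Shared fixtures and independent oracles for the test suite."""

import math
from fractions import Fraction

import pandas as pd
import pytest
from hypothesis import settings

import pvscreen as pv

settings.register_profile("reproducible", derandomize=True)
settings.load_profile("reproducible")


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Exhaustive-enumeration two-sided Fisher P (minimum-likelihood definition).

    Sums exact hypergeometric probabilities — integer binomial coefficients
    over a common denominator, so the 'no more probable than observed'
    comparison is exact — for every table sharing the observed margins.
    Independent of any scipy machinery.
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = a + b + c + d

    def numerator(k: int) -> int:
        return math.comb(r1, k) * math.comb(r2, c1 - k)

    observed = numerator(a)
    denominator = math.comb(n, c1)
    total = sum(
        numerator(k)
        for k in range(max(0, c1 - r2), min(r1, c1) + 1)
        if numerator(k) <= observed
    )
    return float(Fraction(total, denominator))


@pytest.fixture
def small_database() -> pv.ReportDatabase:
    """Two cases, three drug rows, two event rows; one duplicated drug row."""
    cases = [
        pv.CaseProfile("A1", sex="male", age_code="50s", height_code="160-169",
                       weight_code="60-69", report_year=2012),
        pv.CaseProfile("A2", sex="female", age_code="30s", report_year=2014),
    ]
    drugs = [
        pv.DrugEntry("A1", "dexamethasone", "suspected", "intravenous"),
        pv.DrugEntry("A1", "fluorouracil", "concomitant", "intravenous"),
        pv.DrugEntry("A2", "amlodipine", "suspected", "oral"),
    ]
    events = [
        pv.EventEntry("A1", "hiccups"),
        pv.EventEntry("A2", "nausea"),
    ]
    return pv.ReportDatabase.from_entries(cases, drugs, events)


@pytest.fixture
def suspected_records() -> pd.DataFrame:
    """A deduplicated, suspected-only analysis table from a seeded simulation."""
    db, _ = pv.generate_database(pv.demo_spec(n_cases=8000, seed=11))
    joined = pv.build_all_data_table(pv.deduplicate(db).database)
    return pv.filter_suspected(joined.records)


def write_csv(path, header, rows):
    lines = [",".join(header)] + [",".join(str(v) for v in row) for row in rows]
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def table_files(tmp_path):
    """Three well-formed CSV inputs: 2 cases, 3 drug rows, 2 event rows."""
    demo = write_csv(tmp_path / "demo.csv",
                     ["case_id", "sex", "age_code", "height_code", "weight_code",
                      "report_year"],
                     [["A1", "male", "50s", "160-169", "60-69", 2012],
                      ["A2", "female", "", "", "40-49", 2014]])
    drug = write_csv(tmp_path / "drug.csv",
                     ["case_id", "drug_name", "involvement", "route"],
                     [["A1", "dexamethasone", "suspected", "intravenous"],
                      ["A1", "fluorouracil", "concomitant", "iv"],
                      ["A2", "amlodipine", "suspected", "oral"]])
    reac = write_csv(tmp_path / "reac.csv",
                     ["case_id", "event_term"],
                     [["A1", "hiccups"], ["A2", "nausea"]])
    return demo, drug, reac
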