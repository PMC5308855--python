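"""Synthetic spontaneous-report databases with known ground truth.

Real spontaneous reporting databases cannot be redistributed, so every stage
of the pipeline is exercised against simulated databases that reproduce the
structural features that matter for the analysis: one demographics row per
case; one-to-many case-to-drug and case-to-event links; reporter-assigned
involvement labels (suspected / concomitant / interaction); administration
routes; exact-copy duplicated rows; missing demographic values; a rare
target event; and — crucially — *configurable drug-event reporting odds
ratios* planted on the odds scale, so the estimand of the disproportionality
screen is known.

The event model is a logistic regression on the case's drug exposures:

    logit P(event) = logit(background_rate) + sum_j 1[drug_j] * ln(multiplier_j)
                     + 1[male] * male_log_odds
                     + (height - 160) * height_log_odds_per_cm

For a rare event the planted ``event_odds_multiplier`` of a drug is, to
first order, both the odds ratio the logistic fit estimates and the ROR the
screen estimates.

:func:`fixture_from_counts` goes the other way: it expands any printed 2x2
table into a minimal database whose screen reproduces the table exactly,
letting published contingency tables be replayed through the full pipeline.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special

from .reporting_db import (
    DEMO_COLUMNS,
    DRUG_COLUMNS,
    INVOLVEMENT_VALUES,
    REAC_COLUMNS,
    ROUTE_VALUES,
    ReportDatabase,
)

__all__ = [
    "DrugSpec",
    "SyntheticSpec",
    "GroundTruth",
    "generate_database",
    "write_database",
    "fixture_from_counts",
    "fixture_cotreatment",
    "demo_spec",
]

#: Adverse-event vocabulary for the non-target reports.
DEFAULT_OTHER_EVENTS = (
    "nausea", "rash", "pyrexia", "hepatic disorder", "interstitial lung disease",
    "vomiting", "diarrhoea", "dizziness", "anaemia", "renal impairment",
    "pruritus", "headache",
)

_DECADES = ("10s", "20s", "30s", "40s", "50s", "60s", "70s", "80s")
_HEIGHTS = ("130-139", "140-149", "150-159", "160-169", "170-179", "180-189")
_WEIGHTS = ("30-39", "40-49", "50-59", "60-69", "70-79", "80-89", "90-99")


def _uniform(categories: Sequence[str]) -> dict[str, float]:
    return {c: 1.0 / len(categories) for c in categories}


def _check_distribution(name: str, dist: Mapping[str, float]) -> None:
    if not dist:
        raise ValueError(f"{name} must not be empty")
    values = np.array(list(dist.values()), dtype=float)
    if (values < 0).any() or not math.isclose(values.sum(), 1.0, abs_tol=1e-9):
        raise ValueError(f"{name} probabilities must be non-negative and sum to 1")


@dataclass(frozen=True)
class DrugSpec:
    """One simulated drug and its planted reporting behaviour.

    ``event_odds_multiplier`` is the factor applied to a case's event odds
    when the case takes the drug; 1 plants a null drug.  Planted signal
    drugs default to all-suspected involvement — when a drug actually drives
    the event, the reporter marks it suspected — while null drugs are
    typically given a mixed involvement distribution.
    """

    name: str
    prevalence: float
    event_odds_multiplier: float = 1.0
    route_distribution: Mapping[str, float] = field(
        default_factory=lambda: {"intravenous": 0.3, "oral": 0.6, "other": 0.1})
    involvement_distribution: Mapping[str, float] = field(
        default_factory=lambda: {"suspected": 1.0})

    def validate(self) -> None:
        if not self.name:
            raise ValueError("drug name must be non-empty")
        if not 0 < self.prevalence < 1:
            raise ValueError(f"prevalence must be in (0,1), got {self.prevalence}")
        if not self.event_odds_multiplier > 0:
            raise ValueError("event_odds_multiplier must be positive")
        _check_distribution(f"{self.name} route_distribution", self.route_distribution)
        _check_distribution(f"{self.name} involvement_distribution",
                            self.involvement_distribution)
        if set(self.route_distribution) - set(ROUTE_VALUES):
            raise ValueError(f"unknown routes in {self.name} route_distribution")
        if set(self.involvement_distribution) - set(INVOLVEMENT_VALUES):
            raise ValueError(f"unknown involvement in {self.name} involvement_distribution")


@dataclass(frozen=True)
class SyntheticSpec:
    """Full parameterization of a simulated reporting database.

    Demographic marginals default to the shape of a national
    pharmacovigilance database: roughly balanced sexes with a small unknown
    fraction, age reported for nearly all cases but height and weight
    missing for about half, and reports spread over 2004-2015.  Missingness
    is completely at random per field.
    """

    n_cases: int = 50_000
    male_fraction: float = 0.5
    sex_unknown_fraction: float = 0.02
    age_decades: Mapping[str, float] = field(default_factory=lambda: _uniform(_DECADES))
    height_ranges: Mapping[str, float] = field(default_factory=lambda: _uniform(_HEIGHTS))
    weight_ranges: Mapping[str, float] = field(default_factory=lambda: _uniform(_WEIGHTS))
    age_missing_fraction: float = 0.04
    height_missing_fraction: float = 0.53
    weight_missing_fraction: float = 0.45
    year_range: tuple[int, int] = (2004, 2015)
    background_event_rate: float = 0.01
    event_term: str = "hiccups"
    male_log_odds: float = math.log(4.0)
    height_log_odds_per_cm: float = 0.0
    other_event_terms: Sequence[str] = DEFAULT_OTHER_EVENTS
    filler_drug_name: str = "unspecified-medicine"
    drugs: Sequence[DrugSpec] = ()
    duplicate_fraction: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        for name in ("male_fraction", "sex_unknown_fraction", "age_missing_fraction",
                     "height_missing_fraction", "weight_missing_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if not 0 <= self.duplicate_fraction < 1:
            raise ValueError("duplicate_fraction must be in [0,1)")
        if not 0 < self.background_event_rate < 1:
            raise ValueError("background_event_rate must be in (0,1)")
        if self.n_cases * self.background_event_rate < 1:
            raise ValueError("expected event count below 1; raise n_cases or the rate")
        if self.year_range[0] > self.year_range[1]:
            raise ValueError("year_range must be (first, last) with first <= last")
        if not self.drugs:
            raise ValueError("at least one DrugSpec is required")
        if not self.event_term:
            raise ValueError("event_term must be non-empty")
        for name in ("age_decades", "height_ranges", "weight_ranges"):
            _check_distribution(name, getattr(self, name))
        names = [d.name for d in self.drugs]
        if len(set(names)) != len(names):
            raise ValueError("drug names must be unique")
        for drug in self.drugs:
            drug.validate()


@dataclass(frozen=True)
class GroundTruth:
    """Planted parameters of a generated database."""

    seed: int
    n_cases: int
    event_term: str
    background_event_rate: float
    male_log_odds: float
    multipliers: dict[str, float]
    prevalences: dict[str, float]
    n_event_cases: int

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _sample_codes(rng, n: int, dist: Mapping[str, float], missing_fraction: float
                  ) -> np.ndarray:
    keys = np.array(list(dist.keys()), dtype=object)
    probs = np.array(list(dist.values()), dtype=float)
    codes = rng.choice(keys, size=n, p=probs / probs.sum())
    codes[rng.random(n) < missing_fraction] = None
    return codes


def _height_cm(codes: np.ndarray) -> np.ndarray:
    out = np.full(len(codes), 160.0)
    for i, code in enumerate(codes):
        if code is not None:
            out[i] = float(str(code).split("-")[0])
    return out


def generate_database(spec: SyntheticSpec, seed: int | None = None
                      ) -> tuple[ReportDatabase, GroundTruth]:
    """Draw one database from the spec; identical spec and seed give identical tables.

    ``seed`` overrides ``spec.seed`` when given.
    """
    spec.validate()
    seed = spec.seed if seed is None else int(seed)
    rng = np.random.default_rng(seed)
    n = spec.n_cases

    case_ids = np.array([f"C{i:07d}" for i in range(1, n + 1)], dtype=object)
    sex = np.where(rng.random(n) < spec.male_fraction, "male", "female").astype(object)
    sex[rng.random(n) < spec.sex_unknown_fraction] = "unknown"
    age = _sample_codes(rng, n, spec.age_decades, spec.age_missing_fraction)
    height = _sample_codes(rng, n, spec.height_ranges, spec.height_missing_fraction)
    weight = _sample_codes(rng, n, spec.weight_ranges, spec.weight_missing_fraction)
    years = rng.integers(spec.year_range[0], spec.year_range[1] + 1, size=n)

    exposure = {d.name: rng.random(n) < d.prevalence for d in spec.drugs}

    log_odds = np.full(n, special.logit(spec.background_event_rate))
    for d in spec.drugs:
        if d.event_odds_multiplier != 1.0:
            log_odds += exposure[d.name] * math.log(d.event_odds_multiplier)
    log_odds += (sex == "male") * spec.male_log_odds
    if spec.height_log_odds_per_cm:
        log_odds += (_height_cm(height) - 160.0) * spec.height_log_odds_per_cm
    event = rng.random(n) < special.expit(log_odds)

    demo = pd.DataFrame({
        "case_id": case_ids, "sex": sex, "age_code": age, "height_code": height,
        "weight_code": weight, "report_year": pd.array(years, dtype="Int64"),
    })[DEMO_COLUMNS]

    drug_frames = []
    for d in spec.drugs:
        idx = np.flatnonzero(exposure[d.name])
        if len(idx) == 0:
            continue
        inv_keys = list(d.involvement_distribution.keys())
        inv_p = np.array(list(d.involvement_distribution.values()), dtype=float)
        route_keys = list(d.route_distribution.keys())
        route_p = np.array(list(d.route_distribution.values()), dtype=float)
        drug_frames.append(pd.DataFrame({
            "case_id": case_ids[idx],
            "drug_name": d.name,
            "involvement": rng.choice(inv_keys, size=len(idx), p=inv_p / inv_p.sum()),
            "route": rng.choice(route_keys, size=len(idx), p=route_p / route_p.sum()),
        }))
    # every case reports at least one drug: cases with no planted exposure get a
    # filler medicine with mixed involvement
    covered = np.zeros(n, dtype=bool)
    for mask in exposure.values():
        covered |= mask
    idx = np.flatnonzero(~covered)
    if len(idx):
        drug_frames.append(pd.DataFrame({
            "case_id": case_ids[idx],
            "drug_name": spec.filler_drug_name,
            "involvement": rng.choice(["suspected", "concomitant"], size=len(idx),
                                      p=[0.6, 0.4]),
            "route": rng.choice(["oral", "intravenous", "other"], size=len(idx),
                                p=[0.6, 0.3, 0.1]),
        }))
    drug = pd.concat(drug_frames, ignore_index=True)[DRUG_COLUMNS]
    drug = drug.sort_values("case_id", kind="stable", ignore_index=True)

    other = rng.choice(np.array(spec.other_event_terms, dtype=object), size=n)
    reac = pd.DataFrame({
        "case_id": case_ids,
        "event_term": np.where(event, spec.event_term, other).astype(object),
    })[REAC_COLUMNS]

    # duplicated rows: re-emit a random subset as exact copies appended at the end
    if spec.duplicate_fraction > 0:
        dup = drug[rng.random(len(drug)) < spec.duplicate_fraction]
        drug = pd.concat([drug, dup], ignore_index=True)
        dup = reac[rng.random(len(reac)) < spec.duplicate_fraction]
        reac = pd.concat([reac, dup], ignore_index=True)

    truth = GroundTruth(
        seed=seed, n_cases=n, event_term=spec.event_term,
        background_event_rate=spec.background_event_rate,
        male_log_odds=spec.male_log_odds,
        multipliers={d.name: d.event_odds_multiplier for d in spec.drugs},
        prevalences={d.name: d.prevalence for d in spec.drugs},
        n_event_cases=int(event.sum()),
    )
    return ReportDatabase(demo=demo, drug=drug, reac=reac), truth


def write_database(db: ReportDatabase, outdir, truth: GroundTruth | None = None,
                   delimiter: str = ",") -> dict[str, Path]:
    """Write the three tables (and the ground-truth manifest) as delimited text."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, table in (("demo", db.demo), ("drug", db.drug), ("reac", db.reac)):
        path = outdir / f"{name}.csv"
        table.to_csv(path, sep=delimiter, index=False)
        paths[name] = path
    if truth is not None:
        path = outdir / "ground_truth.json"
        path.write_text(truth.to_json())
        paths["ground_truth"] = path
    return paths


def fixture_from_counts(a: int, b: int, c: int, d: int,
                        exposure_label: str = "drug-x",
                        event_term: str = "hiccups",
                        comparator_label: str = "other-medicine",
                        other_event_term: str = "other-event",
                        route: str | None = None,
                        comparator_route: str | None = None) -> ReportDatabase:
    """Expand a printed 2x2 table into a minimal single-drug-per-case database.

    The result has exactly ``a+b+c+d`` cases, each with one suspected drug
    row (the exposure for the first ``a+b`` cases, a comparator otherwise)
    and one event row (the event for cells a and c, another term otherwise),
    so a record- or case-level screen reproduces the table verbatim.
    """
    for name, v in (("a", a), ("b", b), ("c", c), ("d", d)):
        if v < 0:
            raise ValueError(f"count {name} must be non-negative")
    total = a + b + c + d
    if total == 0:
        raise ValueError("the table must contain at least one case")
    case_ids = np.array([f"F{i:07d}" for i in range(1, total + 1)], dtype=object)
    drug_names = np.repeat([exposure_label, comparator_label], [a + b, c + d])
    events = np.concatenate([
        np.repeat([event_term, other_event_term], [a, b]),
        np.repeat([event_term, other_event_term], [c, d]),
    ])
    routes = np.repeat([route, comparator_route], [a + b, c + d])
    demo = pd.DataFrame({
        "case_id": case_ids, "sex": "unknown", "age_code": None,
        "height_code": None, "weight_code": None,
        "report_year": pd.array([2010] * total, dtype="Int64"),
    })[DEMO_COLUMNS]
    drug = pd.DataFrame({
        "case_id": case_ids, "drug_name": drug_names,
        "involvement": "suspected", "route": routes,
    })[DRUG_COLUMNS]
    reac = pd.DataFrame({"case_id": case_ids, "event_term": events})[REAC_COLUMNS]
    return ReportDatabase(demo=demo, drug=drug, reac=reac)


def fixture_cotreatment(n_both: int, n_drug_only: int, n_class_only: int,
                        n_neither: int, drug: str = "dexamethasone",
                        class_drug: str = "fluorouracil",
                        event_term: str = "hiccups") -> ReportDatabase:
    """Event-case fixture for the co-treatment cross-tabulation.

    Every case reports the event once; drug rows mix involvement categories
    (the drug suspected, the class drug concomitant) so that only an
    all-involvement analysis classifies the cases correctly.
    """
    total = n_both + n_drug_only + n_class_only + n_neither
    if total == 0:
        raise ValueError("at least one case is required")
    case_ids = [f"T{i:05d}" for i in range(1, total + 1)]
    groups = np.repeat(["both", "drug", "class", "neither"],
                       [n_both, n_drug_only, n_class_only, n_neither])
    drug_rows = []
    for cid, group in zip(case_ids, groups):
        if group in ("both", "drug"):
            drug_rows.append((cid, drug, "suspected", "intravenous"))
        if group in ("both", "class"):
            drug_rows.append((cid, class_drug, "concomitant", "intravenous"))
        if group == "neither":
            drug_rows.append((cid, "unrelated-medicine", "suspected", "oral"))
    demo = pd.DataFrame({
        "case_id": case_ids, "sex": "unknown", "age_code": None,
        "height_code": None, "weight_code": None,
        "report_year": pd.array([2010] * total, dtype="Int64"),
    })[DEMO_COLUMNS]
    drug_df = pd.DataFrame(drug_rows, columns=DRUG_COLUMNS)
    reac = pd.DataFrame({"case_id": case_ids, "event_term": event_term})[REAC_COLUMNS]
    return ReportDatabase(demo=demo, drug=drug_df, reac=reac)


def demo_spec(n_cases: int = 20_000, seed: int = 0) -> SyntheticSpec:
    """A ready-made spec with one strong signal drug, moderate signals and nulls.

    Mirrors the qualitative situation of a chemotherapy-support screen: an
    intravenous antiemetic with a strong planted reporting odds multiplier,
    a few co-administered agents with moderate multipliers, and null drugs
    with mixed involvement.
    """
    mixed = {"suspected": 0.5, "concomitant": 0.4, "interaction": 0.1}
    return SyntheticSpec(
        n_cases=n_cases,
        seed=seed,
        drugs=(
            DrugSpec("dexamethasone", prevalence=0.03, event_odds_multiplier=12.0,
                     route_distribution={"intravenous": 0.7, "oral": 0.25, "other": 0.05}),
            DrugSpec("oxaliplatin", prevalence=0.02, event_odds_multiplier=5.0,
                     route_distribution={"intravenous": 1.0}),
            DrugSpec("fluorouracil", prevalence=0.02, event_odds_multiplier=4.0,
                     route_distribution={"intravenous": 0.8, "oral": 0.2}),
            DrugSpec("loxoprofen", prevalence=0.08,
                     route_distribution={"oral": 1.0},
                     involvement_distribution=mixed),
            DrugSpec("amlodipine", prevalence=0.06,
                     route_distribution={"oral": 1.0},
                     involvement_distribution=mixed),
            DrugSpec("omeprazole", prevalence=0.04,
                     route_distribution={"oral": 0.9, "intravenous": 0.1},
                     involvement_distribution=mixed),
        ),
    )
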