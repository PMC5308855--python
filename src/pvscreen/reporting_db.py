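"""Data model and construction pipeline for spontaneous-report analysis tables.

A spontaneous adverse-event reporting database (JADER, FAERS and relatives)
distributes case reports across several linked tables: a demographics table
(one row per case), a drug table (one row per reported drug, annotated with
the reporter-assigned involvement category and the administration route) and
a reaction table (one row per reported adverse-event term).  This module
reads those tables from delimited text, removes exact duplicate rows, joins
them on the case identifier into a single *all-data* table (one row per
case x drug x event combination) and restricts it to records whose drug
involvement is "suspected" — the subset on which disproportionality screens
are normally run.

Tables are held as :class:`pandas.DataFrame` objects with fixed canonical
column names (:data:`DEMO_COLUMNS`, :data:`DRUG_COLUMNS`, :data:`REAC_COLUMNS`);
light dataclasses (:class:`CaseProfile`, :class:`DrugEntry`,
:class:`EventEntry`) are provided for typed row-wise construction in tests
and simulations.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SEX_VALUES",
    "INVOLVEMENT_VALUES",
    "ROUTE_VALUES",
    "DEMO_COLUMNS",
    "DRUG_COLUMNS",
    "REAC_COLUMNS",
    "RECORD_COLUMNS",
    "SchemaError",
    "CaseProfile",
    "DrugEntry",
    "EventEntry",
    "ReportDatabase",
    "FormatOptions",
    "DedupResult",
    "JoinResult",
    "read_tables",
    "deduplicate",
    "build_all_data_table",
    "filter_suspected",
    "normalize_drug_names",
    "write_records",
]

SEX_VALUES = ("male", "female", "unknown")
INVOLVEMENT_VALUES = ("suspected", "concomitant", "interaction")
ROUTE_VALUES = ("intravenous", "oral", "other")

DEMO_COLUMNS = ["case_id", "sex", "age_code", "height_code", "weight_code", "report_year"]
DRUG_COLUMNS = ["case_id", "drug_name", "involvement", "route"]
REAC_COLUMNS = ["case_id", "event_term"]

#: Fixed column order of the all-data / suspected-medicine tables.
RECORD_COLUMNS = [
    "case_id", "sex", "age_code", "height_code", "weight_code",
    "report_year", "drug_name", "involvement", "route", "event_term",
]

_SEX_SYNONYMS = {"male": "male", "m": "male", "female": "female", "f": "female",
                 "unknown": "unknown"}
_ROUTE_SYNONYMS = {
    "intravenous": "intravenous", "iv": "intravenous", "injection": "intravenous",
    "oral": "oral", "po": "oral",
}


class SchemaError(ValueError):
    """An input table does not conform to the expected schema."""


@dataclass(frozen=True)
class CaseProfile:
    """Demographics of one case report.

    Coded demographics follow the reporting-database convention: age as a
    decade code (``"50s"``), height and weight as range codes
    (``"160-169"`` cm, ``"50-59"`` kg).  Missing values are ``None``.
    """

    case_id: str
    sex: str = "unknown"
    age_code: str | None = None
    height_code: str | None = None
    weight_code: str | None = None
    report_year: int | None = None

    def __post_init__(self) -> None:
        if not self.case_id:
            raise ValueError("case_id must be non-empty")
        if self.sex not in SEX_VALUES:
            raise ValueError(f"sex must be one of {SEX_VALUES}, got {self.sex!r}")


@dataclass(frozen=True)
class DrugEntry:
    """One reported drug exposure of a case."""

    case_id: str
    drug_name: str
    involvement: str = "suspected"
    route: str | None = None

    def __post_init__(self) -> None:
        if not self.drug_name:
            raise ValueError("drug_name must be non-empty")
        if self.involvement not in INVOLVEMENT_VALUES:
            raise ValueError(
                f"involvement must be one of {INVOLVEMENT_VALUES}, got {self.involvement!r}"
            )
        if self.route is not None and self.route not in ROUTE_VALUES:
            raise ValueError(f"route must be one of {ROUTE_VALUES} or None, got {self.route!r}")


@dataclass(frozen=True)
class EventEntry:
    """One reported adverse-event term of a case."""

    case_id: str
    event_term: str

    def __post_init__(self) -> None:
        if not self.event_term:
            raise ValueError("event_term must be non-empty")


def _empty(columns: Sequence[str]) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in columns})


@dataclass
class ReportDatabase:
    """The three linked tables of a spontaneous reporting database."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame

    def __post_init__(self) -> None:
        for name, table, cols in (
            ("demo", self.demo, DEMO_COLUMNS),
            ("drug", self.drug, DRUG_COLUMNS),
            ("reac", self.reac, REAC_COLUMNS),
        ):
            missing = [c for c in cols if c not in table.columns]
            if missing:
                raise SchemaError(f"{name} table is missing column(s) {missing}")

    @property
    def counts(self) -> tuple[int, int, int]:
        """Row counts ``(n_demo, n_drug, n_reac)``."""
        return (len(self.demo), len(self.drug), len(self.reac))

    @classmethod
    def from_entries(
        cls,
        cases: Iterable[CaseProfile],
        drugs: Iterable[DrugEntry],
        events: Iterable[EventEntry],
    ) -> "ReportDatabase":
        """Build a database from typed row objects (mainly for tests/simulation)."""
        demo = pd.DataFrame(
            [(c.case_id, c.sex, c.age_code, c.height_code, c.weight_code, c.report_year)
             for c in cases],
            columns=DEMO_COLUMNS,
        )
        drug = pd.DataFrame(
            [(d.case_id, d.drug_name, d.involvement, d.route) for d in drugs],
            columns=DRUG_COLUMNS,
        )
        reac = pd.DataFrame([(e.case_id, e.event_term) for e in events], columns=REAC_COLUMNS)
        if demo.empty:
            demo = _empty(DEMO_COLUMNS)
        if drug.empty:
            drug = _empty(DRUG_COLUMNS)
        if reac.empty:
            reac = _empty(REAC_COLUMNS)
        return cls(demo=demo, drug=drug, reac=reac)


@dataclass(frozen=True)
class FormatOptions:
    """Dialect and column mapping of the delimited input tables.

    ``*_columns`` map file column names to the canonical names; file columns
    not mentioned are dropped, canonical columns not produced by the mapping
    are created as missing (except the mandatory ones, which raise).
    """

    delimiter: str = ","
    encoding: str = "utf-8"
    demo_columns: Mapping[str, str] = field(default_factory=dict)
    drug_columns: Mapping[str, str] = field(default_factory=dict)
    reac_columns: Mapping[str, str] = field(default_factory=dict)


_MANDATORY = {
    "demo": ["case_id"],
    "drug": ["case_id", "drug_name", "involvement"],
    "reac": ["case_id", "event_term"],
}


def _read_one(path, options: FormatOptions, which: str, columns: Sequence[str]) -> pd.DataFrame:
    mapping = getattr(options, f"{which}_columns")
    df = pd.read_csv(
        path,
        sep=options.delimiter,
        encoding=options.encoding,
        dtype=str,
        keep_default_na=False,
    )
    if mapping:
        df = df.rename(columns=dict(mapping))
    for col in _MANDATORY[which]:
        if col not in df.columns:
            raise SchemaError(f"{which} table {path!s} is missing mandatory column {col!r}")
    out = pd.DataFrame(index=df.index)
    for col in columns:
        if col in df.columns:
            out[col] = df[col].str.strip()
            out.loc[out[col] == "", col] = None
        else:
            out[col] = None
    return out


def _clean_sex(series: pd.Series) -> pd.Series:
    mapped = series.str.lower().map(_SEX_SYNONYMS)
    n_bad = int((mapped.isna() & series.notna()).sum())
    if n_bad:
        logger.warning("demo table: %d unrecognized sex value(s) set to 'unknown'", n_bad)
    return mapped.fillna("unknown")


def _clean_route(series: pd.Series) -> pd.Series:
    lowered = series.str.lower()
    mapped = lowered.map(_ROUTE_SYNONYMS)
    # any non-missing, unrecognized route is binned as "other"
    mapped = mapped.where(mapped.notna() | lowered.isna(), "other")
    return mapped


def read_tables(demo_path, drug_path, reac_path,
                format_options: FormatOptions | None = None) -> ReportDatabase:
    """Read the demographics, drug and reaction tables from delimited text.

    Unparseable demographic values (report year that is not an integer,
    unrecognized sex) become missing/``unknown`` with a logged count; an
    unrecognized involvement category is a :class:`SchemaError` because the
    suspected-medicine extraction depends on it.
    """
    options = format_options or FormatOptions()

    demo = _read_one(demo_path, options, "demo", DEMO_COLUMNS)
    demo["sex"] = _clean_sex(demo["sex"])
    year = pd.to_numeric(demo["report_year"], errors="coerce")
    n_bad_year = int((year.isna() & demo["report_year"].notna()).sum())
    if n_bad_year:
        logger.warning("demo table: %d unparseable report_year value(s) set to missing", n_bad_year)
    demo["report_year"] = year.astype("Int64")

    drug = _read_one(drug_path, options, "drug", DRUG_COLUMNS)
    inv = drug["involvement"].str.lower()
    bad = sorted(set(inv.dropna()) - set(INVOLVEMENT_VALUES))
    if bad or inv.isna().any():
        raise SchemaError(
            f"drug table {drug_path!s}: involvement must be one of {INVOLVEMENT_VALUES}; "
            f"found {bad or 'missing values'}"
        )
    drug["involvement"] = inv
    drug["route"] = _clean_route(drug["route"])
    if drug["drug_name"].isna().any():
        raise SchemaError(f"drug table {drug_path!s}: drug_name has empty values")

    reac = _read_one(reac_path, options, "reac", REAC_COLUMNS)
    if reac["event_term"].isna().any():
        raise SchemaError(f"reac table {reac_path!s}: event_term has empty values")

    db = ReportDatabase(demo=demo, drug=drug, reac=reac)
    logger.info("read tables: demo=%d drug=%d reac=%d rows", *db.counts)
    return db


@dataclass(frozen=True)
class DedupResult:
    """Deduplicated database plus the number of rows removed per table."""

    database: ReportDatabase
    removed: dict[str, int]


def deduplicate(db: ReportDatabase, *, subset: Mapping[str, Sequence[str]] | None = None
                ) -> DedupResult:
    """Drop duplicate rows from each table, keeping first occurrences.

    A duplicate is a row identical on *all* fields of its table (the most
    conservative reading); pass ``subset={"drug": [...], ...}`` to
    deduplicate on a key subset instead.  Demographics must identify each
    case uniquely afterwards.
    """
    subset = subset or {}
    removed: dict[str, int] = {}
    tables = {}
    for name, table in (("demo", db.demo), ("drug", db.drug), ("reac", db.reac)):
        deduped = table.drop_duplicates(subset=subset.get(name), keep="first", ignore_index=True)
        removed[name] = len(table) - len(deduped)
        tables[name] = deduped
    if tables["demo"]["case_id"].duplicated().any():
        dupes = tables["demo"].loc[tables["demo"]["case_id"].duplicated(), "case_id"]
        raise SchemaError(
            f"demographics contain conflicting rows for case_id(s) {sorted(set(dupes))[:5]}"
        )
    logger.info("deduplicate: removed %s", removed)
    return DedupResult(database=ReportDatabase(**tables), removed=removed)


@dataclass(frozen=True)
class JoinResult:
    """The all-data table and the orphan rows dropped while joining."""

    records: pd.DataFrame
    n_orphan_drug_rows: int
    n_orphan_event_rows: int

    @property
    def n_records(self) -> int:
        return len(self.records)


def build_all_data_table(db: ReportDatabase, orphan_policy: str = "drop") -> JoinResult:
    """Join demographics with drugs and events on the case identifier.

    The result has one row per (case, drug, event) combination — the
    *all-data table*.  Drug or event rows whose case identifier has no
    demographics row are orphans: with ``orphan_policy="drop"`` (default)
    they are dropped with a logged warning count, with ``"error"`` they
    raise.
    """
    if orphan_policy not in ("drop", "error"):
        raise ValueError(f"orphan_policy must be 'drop' or 'error', got {orphan_policy!r}")
    known = set(db.demo["case_id"])
    orphan_drug = int((~db.drug["case_id"].isin(known)).sum())
    orphan_event = int((~db.reac["case_id"].isin(known)).sum())
    if (orphan_drug or orphan_event) and orphan_policy == "error":
        raise ValueError(
            f"orphan rows: {orphan_drug} drug, {orphan_event} event row(s) "
            "have no demographics entry"
        )
    if orphan_drug or orphan_event:
        logger.warning(
            "dropping orphan rows: %d drug, %d event", orphan_drug, orphan_event
        )
    records = db.demo.merge(db.drug, on="case_id", how="inner").merge(
        db.reac, on="case_id", how="inner"
    )
    records = records[RECORD_COLUMNS].reset_index(drop=True)
    logger.info("all data table: %d records", len(records))
    return JoinResult(records=records,
                      n_orphan_drug_rows=orphan_drug,
                      n_orphan_event_rows=orphan_event)


def filter_suspected(records: pd.DataFrame) -> pd.DataFrame:
    """Restrict the all-data table to records with involvement ``"suspected"``."""
    out = records[records["involvement"] == "suspected"].reset_index(drop=True)
    logger.info("suspected medicine table: %d records", len(out))
    return out


def normalize_drug_names(records: pd.DataFrame, synonym_map: Mapping[str, str]) -> pd.DataFrame:
    """Replace registered (often route-specific) drug names by canonical generic names.

    Names absent from ``synonym_map`` pass through unchanged; matching is
    exact after trimming whitespace.
    """
    out = records.copy()
    trimmed = out["drug_name"].str.strip()
    out["drug_name"] = trimmed.map(lambda name: synonym_map.get(name, name))
    return out


def write_records(records: pd.DataFrame, path) -> None:
    """Write an analysis table as tab-separated text in the fixed column order."""
    records[RECORD_COLUMNS].to_csv(path, sep="\t", index=False)
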