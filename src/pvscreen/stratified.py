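"""Stratified analyses: administration route and co-treatment cross-tabulation.

Two follow-up questions after a drug flags in the primary screen:

* **Route.**  Is the event reported disproportionately for one administration
  route of the drug?  For each route, the records of the drug given by that
  route are cross-tabulated against the remainder of the whole
  suspected-medicine table (event vs non-event) and tested with the
  two-sided Fisher exact test.  Comparing each route against the rest of the
  database — rather than against the drug's other routes — keeps every
  route's comparator identical and the per-route counts additive to the
  drug's total row.

* **Co-treatment.**  Among unique event cases (deduplicated by case
  identifier), how does use of the drug co-occur with use of a drug class
  (for example anti-cancer agents)?  This uses the *all-data* table — every
  involvement category, not just suspected — because co-medications are
  mostly recorded as concomitant.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .disproportionality import (
    Contingency2x2,
    build_contingency,
    fisher_exact_two_sided,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RouteResult",
    "route_screen",
    "route_table",
    "CotreatmentTable",
    "cotreatment_cross_tab",
    "cotreatment_percentages",
]

_ROUTE_ORDER = {"intravenous": 0, "oral": 1, "other": 2}


@dataclass(frozen=True)
class RouteResult:
    """One administration route of a drug versus the rest of the table."""

    route: str
    n_event: int
    n_nonevent: int
    p_value: float
    table: Contingency2x2


def route_screen(records: pd.DataFrame, drug: str, event_term: str,
                 routes: Sequence[str] | None = None) -> list[RouteResult]:
    """Per-route event cross-tabulations for one drug.

    ``records`` is normally the suspected-medicine table.  Routes are taken
    from the drug's own records unless given explicitly; an expected route
    with no records is omitted with a warning.  A route that covers the
    entire table leaves no comparator and raises.
    """
    drug_mask = records["drug_name"] == drug
    if not drug_mask.any():
        raise ValueError(f"no records for drug {drug!r}")
    observed = set(records.loc[drug_mask, "route"].dropna())
    if routes is None:
        routes = sorted(observed, key=lambda r: (_ROUTE_ORDER.get(r, 99), r))
    results = []
    for route in routes:
        exposure = drug_mask & (records["route"] == route)
        n_exposed = int(exposure.sum())
        if n_exposed == 0:
            logger.warning("route %r has no records for drug %r; omitted", route, drug)
            continue
        if n_exposed == len(records):
            raise ValueError(
                f"route {route!r} covers every record; no comparator remains"
            )
        t = build_contingency(records, exposure, lambda df: df["event_term"] == event_term)
        results.append(RouteResult(
            route=route, n_event=t.a, n_nonevent=t.b,
            p_value=fisher_exact_two_sided(t), table=t,
        ))
    return results


def route_table(results: Sequence[RouteResult]) -> pd.DataFrame:
    """Route results as a DataFrame with a leading Total row (counts sum by route)."""
    rows = [("total", sum(r.n_nonevent for r in results),
             sum(r.n_event for r in results), math.nan)]
    rows += [(r.route, r.n_nonevent, r.n_event, r.p_value) for r in results]
    return pd.DataFrame(rows, columns=["route", "n_nonevent", "n_event", "p_value"])


@dataclass(frozen=True)
class CotreatmentTable:
    """Unique event cases classified by use of a drug and of a drug class."""

    n_both: int
    n_drug_only: int
    n_class_only: int
    n_neither: int

    def __post_init__(self) -> None:
        for name in ("n_both", "n_drug_only", "n_class_only", "n_neither"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_cases(self) -> int:
        return self.n_both + self.n_drug_only + self.n_class_only + self.n_neither

    @property
    def n_drug_users(self) -> int:
        return self.n_both + self.n_drug_only

    @property
    def n_nonusers(self) -> int:
        return self.n_class_only + self.n_neither


def cotreatment_cross_tab(all_data_records: pd.DataFrame, event_term: str,
                          drug: str, drug_class: Sequence[str]) -> CotreatmentTable:
    """Classify unique event cases by (drug use) x (drug-class use).

    ``all_data_records`` must be the all-data table so that suspected,
    concomitant and interaction records all count as use.  Each case is
    counted once regardless of how many records it contributes.
    """
    class_names = set(drug_class)
    if not class_names:
        raise ValueError("drug_class must name at least one drug")
    event_cases = set(all_data_records.loc[
        all_data_records["event_term"] == event_term, "case_id"])
    if not event_cases:
        raise ValueError(f"no cases report event {event_term!r}")
    subset = all_data_records[all_data_records["case_id"].isin(event_cases)]
    per_case = subset.groupby("case_id").agg(
        uses_drug=("drug_name", lambda names: (names == drug).any()),
        uses_class=("drug_name", lambda names: names.isin(class_names).any()),
    )
    n_both = int((per_case["uses_drug"] & per_case["uses_class"]).sum())
    n_drug_only = int((per_case["uses_drug"] & ~per_case["uses_class"]).sum())
    n_class_only = int((~per_case["uses_drug"] & per_case["uses_class"]).sum())
    n_neither = int((~per_case["uses_drug"] & ~per_case["uses_class"]).sum())
    return CotreatmentTable(n_both, n_drug_only, n_class_only, n_neither)


def _pct(numerator: int, denominator: int) -> int:
    # integer percent, half away from zero (matches hand-rounded summaries)
    if denominator == 0:
        return 0
    return int(math.floor(100 * numerator / denominator + 0.5))


def cotreatment_percentages(table: CotreatmentTable) -> dict[str, int]:
    """Whole-percent co-treatment shares.

    Keys: ``pct_users_cotreated`` (drug users also on the class),
    ``pct_users_among_cases`` (drug users among all event cases),
    ``pct_cases_nonusers`` (event cases not on the drug) and
    ``pct_class_among_nonusers`` (class use among those non-users).
    """
    return {
        "pct_users_cotreated": _pct(table.n_both, table.n_drug_users),
        "pct_users_among_cases": _pct(table.n_drug_users, table.n_cases),
        "pct_cases_nonusers": _pct(table.n_nonusers, table.n_cases),
        "pct_class_among_nonusers": _pct(table.n_class_only, table.n_nonusers),
    }
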