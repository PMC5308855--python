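"""Reporting odds ratio screening of a spontaneous-report table.

For one exposure (a drug, a sex, an administration route) and one adverse
event, the units of the analysis table are cross-tabulated as

    ==============  =============  =============
                    event present  event absent
    exposed         a              b
    not exposed     c              d
    ==============  =============  =============

and summarized by the reporting odds ratio ROR = a*d / (b*c), its Woolf
(log-normal) confidence interval

    exp( ln ROR  ±  z * sqrt(1/a + 1/b + 1/c + 1/d) ),

and the two-sided Fisher exact test P value (minimum-likelihood definition:
the sum of hypergeometric probabilities of all tables with the same margins
that are no more probable than the observed one).  A drug-event pair is a
*signal* when the lower 95% confidence limit of the ROR exceeds one.  Screens
over many exposures are visualized as volcano plots with x = ln(ROR) and
y = -log10(P).

The ROR measures disproportionate *reporting*, not causal risk; it
approximates the rate-ratio interpretation only when the event is rare among
reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Contingency2x2",
    "SignalResult",
    "build_contingency",
    "compute_ror",
    "ror_ci",
    "fisher_exact_two_sided",
    "evaluate_signal",
    "volcano_coordinates",
    "compute_signal",
    "screen_exposures",
    "screen_drugs",
    "screen_events",
    "filter_min_reports",
    "benjamini_hochberg",
    "signal_table",
]

#: -log10(0.05), the red baseline drawn on volcano plots.
VOLCANO_BASELINE = -math.log10(0.05)


@dataclass(frozen=True)
class Contingency2x2:
    """Counts of the exposure x event cross-tabulation.

    ``a``: exposed with event, ``b``: exposed without event,
    ``c``: unexposed with event, ``d``: unexposed without event.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")
        if self.total == 0:
            raise ValueError("contingency table must contain at least one unit")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])

    def corrected(self) -> tuple[float, float, float, float]:
        """Cells with the Haldane-Anscombe +0.5 continuity correction."""
        return (self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5)


def _as_mask(predicate, records: pd.DataFrame) -> pd.Series:
    mask = predicate(records) if callable(predicate) else predicate
    return pd.Series(np.asarray(mask, dtype=bool), index=records.index)


def build_contingency(records: pd.DataFrame, exposure_predicate, event_predicate,
                      unit: str = "record") -> Contingency2x2:
    """Cross-tabulate the analysis table by exposure and event presence.

    ``exposure_predicate`` and ``event_predicate`` are boolean masks or
    callables mapping the records frame to boolean masks.  With
    ``unit="record"`` every row of the table is one unit; with
    ``unit="case"`` units are unique case identifiers and a case counts as
    exposed (or as an event case) when *any* of its rows matches.
    """
    if len(records) == 0:
        raise ValueError("cannot build a contingency table from an empty record set")
    if unit not in ("record", "case"):
        raise ValueError(f"unit must be 'record' or 'case', got {unit!r}")
    exposed = _as_mask(exposure_predicate, records)
    event = _as_mask(event_predicate, records)
    if unit == "case":
        grouped = pd.DataFrame({"e": exposed, "v": event}).groupby(
            records["case_id"].to_numpy()).any()
        exposed, event = grouped["e"], grouped["v"]
    a = int((exposed & event).sum())
    b = int((exposed & ~event).sum())
    c = int((~exposed & event).sum())
    d = int((~exposed & ~event).sum())
    return Contingency2x2(a, b, c, d)


def compute_ror(t: Contingency2x2, continuity: bool = False) -> float:
    """Reporting odds ratio a*d/(b*c); ``nan`` when b or c is zero.

    With ``continuity=True`` the Haldane-Anscombe +0.5 correction keeps the
    ratio defined for any table.
    """
    a, b, c, d = t.corrected() if continuity else (t.a, t.b, t.c, t.d)
    if b == 0 or c == 0:
        return math.nan
    return (a * d) / (b * c)


def ror_ci(t: Contingency2x2, level: float = 0.95, continuity: bool = False
           ) -> tuple[float, float]:
    """Woolf (log-normal) confidence interval for the ROR.

    Undefined — ``(nan, nan)`` — when any cell is zero, unless the
    continuity correction is enabled.
    """
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level!r}")
    a, b, c, d = t.corrected() if continuity else (t.a, t.b, t.c, t.d)
    if min(a, b, c, d) == 0:
        return (math.nan, math.nan)
    z = stats.norm.ppf(0.5 + level / 2)
    log_ror = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return (math.exp(log_ror - z * se), math.exp(log_ror + z * se))


def fisher_exact_two_sided(t: Contingency2x2) -> float:
    """Two-sided Fisher exact P value (minimum-likelihood summation).

    A table with a zero margin (no events, or no exposed units) is the only
    table with its margins, so P = 1.
    """
    return float(stats.fisher_exact(t.as_array(), alternative="two-sided").pvalue)


def evaluate_signal(ror: float, ci_low: float) -> bool:
    """Signal criterion: the lower confidence limit of the ROR exceeds one (strictly)."""
    if ci_low is None or math.isnan(ci_low):
        return False
    return bool(ci_low > 1)


def volcano_coordinates(ror: float, p_value: float) -> tuple[float, float]:
    """Volcano-plot coordinates ``(ln ROR, -log10 P)``."""
    if not ror > 0:
        raise ValueError(f"ror must be positive, got {ror!r}")
    if not 0 < p_value <= 1:
        raise ValueError(f"p_value must be in (0, 1], got {p_value!r}")
    return (math.log(ror), -math.log10(p_value))


@dataclass(frozen=True)
class SignalResult:
    """Disproportionality summary of one exposure against one event."""

    exposure_label: str
    a: int
    b: int
    c: int
    d: int
    ror: float
    ci_low: float
    ci_high: float
    p_value: float
    ln_ror: float
    neg_log10_p: float
    is_signal: bool

    @property
    def n_event_reports(self) -> int:
        """Number of units with both the exposure and the event (cell a)."""
        return self.a


def compute_signal(exposure_label: str, t: Contingency2x2, level: float = 0.95,
                   continuity: bool = False) -> SignalResult:
    """ROR, Woolf CI, Fisher P, volcano coordinates and signal flag for one table."""
    ror = compute_ror(t, continuity=continuity)
    ci_low, ci_high = ror_ci(t, level=level, continuity=continuity)
    p = fisher_exact_two_sided(t)
    ln_ror = math.log(ror) if (not math.isnan(ror) and ror > 0) else math.nan
    return SignalResult(
        exposure_label=exposure_label,
        a=t.a, b=t.b, c=t.c, d=t.d,
        ror=ror, ci_low=ci_low, ci_high=ci_high,
        p_value=p,
        ln_ror=ln_ror,
        neg_log10_p=-math.log10(p),
        is_signal=evaluate_signal(ror, ci_low),
    )


def _sort_key(r: SignalResult):
    ror = r.ror if not math.isnan(r.ror) else -math.inf
    return (r.p_value, -ror, r.exposure_label)


def screen_exposures(records: pd.DataFrame,
                     exposure_values: Iterable,
                     exposure_predicate: Callable[[pd.DataFrame, object], object],
                     event_predicate,
                     unit: str = "record",
                     level: float = 0.95,
                     continuity: bool = False) -> list[SignalResult]:
    """One :class:`SignalResult` per exposure value.

    ``exposure_predicate(records, value)`` yields the boolean exposure mask
    for each value of the screened axis; ``event_predicate`` is shared by
    all of them.  Results are sorted by ``(p_value, -ror, label)`` so that
    repeated screens of the same table are reproducible.
    """
    results = [
        compute_signal(
            str(value),
            build_contingency(records, lambda df, v=value: exposure_predicate(df, v),
                              event_predicate, unit=unit),
            level=level,
            continuity=continuity,
        )
        for value in exposure_values
    ]
    return sorted(results, key=_sort_key)


def screen_drugs(records: pd.DataFrame, event_term: str, unit: str = "record",
                 level: float = 0.95, continuity: bool = False,
                 drugs: Sequence[str] | None = None) -> list[SignalResult]:
    """Screen every drug in the table for disproportionate reporting of one event.

    For each drug the exposed units are its own records (or cases), the
    comparator is the remainder of the table.
    """
    if drugs is None:
        drugs = sorted(records["drug_name"].dropna().unique())
    return screen_exposures(
        records,
        drugs,
        lambda df, drug: df["drug_name"] == drug,
        lambda df: df["event_term"] == event_term,
        unit=unit, level=level, continuity=continuity,
    )


def screen_events(records: pd.DataFrame, exposure_predicate, unit: str = "record",
                  level: float = 0.95, continuity: bool = False,
                  events: Sequence[str] | None = None) -> list[SignalResult]:
    """Screen every adverse-event term against one fixed binary exposure stratum.

    This is the sex- or route-wise volcano: the exposure (for example
    ``sex == "male"`` or ``route == "intravenous"``) is fixed while the
    event term varies.  The ROR of each term is invariant under transposing
    the table, so results are directly comparable with the drug screen.
    """
    if events is None:
        events = sorted(records["event_term"].dropna().unique())
    return screen_exposures(
        records,
        events,
        lambda df, term: df["event_term"] == term,
        exposure_predicate,
        unit=unit, level=level, continuity=continuity,
    )


def filter_min_reports(results: Iterable[SignalResult], min_count: int = 3
                       ) -> list[SignalResult]:
    """Keep exposures with strictly more than ``min_count`` event reports (cell a)."""
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    return [r for r in results if r.n_event_reports > min_count]


def benjamini_hochberg(results: Sequence[SignalResult]) -> list[float]:
    """Benjamini-Hochberg adjusted P values, aligned with ``results``.

    Offered as an extension: the screening convention in this field reports
    raw Fisher P values with a 0.05 significance line and no multiplicity
    adjustment.
    """
    p = np.array([r.p_value for r in results], dtype=float)
    return list(stats.false_discovery_control(p, method="bh"))


def signal_table(results: Sequence[SignalResult], adjusted: bool = False) -> pd.DataFrame:
    """Screen results as a DataFrame in the fixed output column order."""
    frame = pd.DataFrame(
        [
            (r.exposure_label, r.a, r.b, r.c, r.d, r.ror, r.ci_low, r.ci_high,
             r.p_value, r.ln_ror, r.neg_log10_p, r.is_signal)
            for r in results
        ],
        columns=["exposure", "a", "b", "c", "d", "ror", "ci_low", "ci_high",
                 "p_value", "ln_ror", "neg_log10_p", "is_signal"],
    )
    if adjusted and len(results):
        frame["p_bh_adjusted"] = benjamini_hochberg(results)
    return frame
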