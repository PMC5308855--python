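"""Patient-background comparisons between event and non-event report groups.

Reporting databases code age in decades (``"50s"``) and height/weight as
range codes (``"160-169"`` cm).  Following common practice these codes are
decoded to numbers (by default the leading integer, i.e. the lower bound of
the range) and analyzed as continuous variables; sex is compared with the
two-sided Fisher exact test and continuous variables with a t test.  All
comparisons use only non-missing values and report the number of units
actually analyzed.  A Spearman rank-correlation trend test across reporting
years checks whether the event's share of all reports drifts over time.
"""

from __future__ import annotations

import itertools
import logging
import math
import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .disproportionality import Contingency2x2, fisher_exact_two_sided

logger = logging.getLogger(__name__)

__all__ = [
    "numeric_from_code",
    "GroupComparison",
    "compare_categorical",
    "compare_continuous",
    "TrendResult",
    "yearly_trend",
    "background_table",
]

_LEADING_INT = re.compile(r"\s*(\d+)")
_RANGE = re.compile(r"\s*(\d+)\s*-\s*(\d+)")


def numeric_from_code(code, convention: str = "lower") -> float:
    """Decode an age-decade or range code to a number; missing stays missing.

    ``convention="lower"`` (default) takes the leading integer — ``"50s"``
    -> 50, ``"160-169"`` -> 160.  ``convention="midpoint"`` takes the range
    midpoint — ``"160-169"`` -> 164.5, and treats a decade code as a 10-wide
    range (``"50s"`` -> 54.5).  Codes without a leading integer decode to
    missing with a logged warning.
    """
    if convention not in ("lower", "midpoint"):
        raise ValueError(f"convention must be 'lower' or 'midpoint', got {convention!r}")
    if code is None or (isinstance(code, float) and math.isnan(code)):
        return math.nan
    text = str(code)
    m = _LEADING_INT.match(text)
    if m is None:
        logger.warning("unparseable demographic code %r treated as missing", code)
        return math.nan
    lower = float(m.group(1))
    if convention == "lower":
        return lower
    rng = _RANGE.match(text)
    upper = float(rng.group(2)) if rng else lower + 9.0
    return (lower + upper) / 2.0


def decode_column(series: pd.Series, convention: str = "lower") -> pd.Series:
    """Vectorized :func:`numeric_from_code` over a pandas column."""
    return series.map(lambda v: numeric_from_code(v, convention))


@dataclass(frozen=True)
class GroupComparison:
    """One row of the patient-background table.

    ``n_event`` / ``n_nonevent`` count the non-missing values actually used.
    Mean/SD fields are ``None`` for categorical variables.
    """

    variable: str
    test: str  # "fisher" or "t_test"
    n_event: int
    n_nonevent: int
    p_value: float
    mean_event: float | None = None
    sd_event: float | None = None
    mean_nonevent: float | None = None
    sd_nonevent: float | None = None


def compare_categorical(event_counts: Sequence[int], nonevent_counts: Sequence[int],
                        variable: str = "sex") -> GroupComparison:
    """Fisher exact comparison of a binary category between the two groups.

    ``event_counts`` and ``nonevent_counts`` are ``(n_first, n_second)``
    category counts (for sex: male, female) within the event and non-event
    group respectively.
    """
    (a, b), (c, d) = (tuple(event_counts), tuple(nonevent_counts))
    p = fisher_exact_two_sided(Contingency2x2(int(a), int(b), int(c), int(d)))
    return GroupComparison(
        variable=variable, test="fisher",
        n_event=int(a + b), n_nonevent=int(c + d), p_value=p,
    )


def compare_continuous(values_event, values_nonevent, variant: str = "welch",
                       variable: str = "") -> GroupComparison:
    """Two-sided t test of a continuous variable between the groups.

    ``variant="welch"`` (default) allows unequal group variances;
    ``variant="pooled"`` is the classic equal-variance test.  Missing values
    are dropped; each group needs at least two non-missing values.
    """
    if variant not in ("welch", "pooled"):
        raise ValueError(f"variant must be 'welch' or 'pooled', got {variant!r}")
    x = np.asarray(values_event, dtype=float)
    y = np.asarray(values_nonevent, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 non-missing values")
    res = stats.ttest_ind(x, y, equal_var=(variant == "pooled"))
    return GroupComparison(
        variable=variable, test="t_test",
        n_event=len(x), n_nonevent=len(y),
        p_value=float(res.pvalue),
        mean_event=float(x.mean()), sd_event=float(x.std(ddof=1)),
        mean_nonevent=float(y.mean()), sd_nonevent=float(y.std(ddof=1)),
    )


@dataclass(frozen=True)
class TrendResult:
    """Spearman trend of the event's yearly reporting fraction."""

    years: tuple[int, ...]
    event_fraction_per_year: tuple[float, ...]
    rho: float
    p_value: float


def _spearman_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided permutation P for Spearman rho (n <= 10).

    Enumerates all permutations of one rank vector; with ties, average ranks
    are used and the multiset of ranks is fixed, so rho is monotone in the
    rank dot product.
    """
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    centered_x = rx - rx.mean()
    sy2 = ((ry - ry.mean()) ** 2).sum()  # invariant under permutation of ry
    denom = math.sqrt((centered_x ** 2).sum() * sy2)
    n_extreme = 0
    n_total = 0
    it = itertools.permutations(ry)
    while True:
        batch = np.array(list(itertools.islice(it, 200_000)))
        if batch.size == 0:
            break
        rhos = np.abs((batch - ry.mean()) @ centered_x) / denom
        n_extreme += int((rhos >= obs - 1e-12).sum())
        n_total += len(batch)
    return n_extreme / n_total


def yearly_trend(records: pd.DataFrame, event_term: str | None = None,
                 event_predicate=None, statistic: str = "fraction",
                 method: str = "t") -> TrendResult:
    """Spearman rank correlation between reporting year and the event's yearly share.

    Per year, the statistic is the fraction of records reporting the event
    (``statistic="count"`` uses the raw event count instead).  The P value
    uses the t approximation with average ranks (``method="t"``) or exact
    permutation enumeration for up to 10 years (``method="exact"``).
    """
    if statistic not in ("fraction", "count"):
        raise ValueError(f"statistic must be 'fraction' or 'count', got {statistic!r}")
    if method not in ("t", "exact"):
        raise ValueError(f"method must be 't' or 'exact', got {method!r}")
    if event_predicate is None:
        if event_term is None:
            raise ValueError("provide event_term or event_predicate")
        event_predicate = lambda df: df["event_term"] == event_term
    year = pd.to_numeric(records["report_year"], errors="coerce")
    keep = year.notna()
    year = year[keep].astype(int)
    event = pd.Series(np.asarray(event_predicate(records), dtype=bool),
                      index=records.index)[keep]
    grouped = event.groupby(year.to_numpy())
    per_year = grouped.sum() if statistic == "count" else grouped.mean()
    if len(per_year) < 2:
        raise ValueError("need report_year present on at least 2 distinct years")
    years = np.array(sorted(per_year.index))
    values = per_year.loc[years].to_numpy(dtype=float)
    if np.ptp(values) == 0 or np.ptp(years) == 0:
        # all ties: no monotone association measurable
        rho, p = 0.0, 1.0
    elif method == "exact":
        if len(years) > 10:
            raise ValueError("exact permutation P is limited to 10 years")
        rho = float(np.corrcoef(stats.rankdata(years), stats.rankdata(values))[0, 1])
        p = _spearman_exact_p(years, values)
    else:
        res = stats.spearmanr(years, values)
        rho, p = float(res.statistic), float(res.pvalue)
    return TrendResult(
        years=tuple(int(y) for y in years),
        event_fraction_per_year=tuple(float(v) for v in values),
        rho=rho, p_value=p,
    )


def background_table(records: pd.DataFrame, event_term: str,
                     variant: str = "welch", convention: str = "lower") -> pd.DataFrame:
    """Patient-background comparison table for the event vs non-event records.

    One row per variable (sex; age, height, weight decoded from their codes),
    with group summaries, the n actually used per group, the test applied and
    its two-sided P value.
    """
    event = records["event_term"] == event_term
    rows: list[GroupComparison] = []

    known_sex = records["sex"].isin(["male", "female"])
    e = records.loc[event & known_sex, "sex"]
    ne = records.loc[~event & known_sex, "sex"]
    rows.append(compare_categorical(
        ((e == "male").sum(), (e == "female").sum()),
        ((ne == "male").sum(), (ne == "female").sum()),
        variable="sex (male/female)",
    ))

    for variable, column in (("age", "age_code"), ("height", "height_code"),
                             ("weight", "weight_code")):
        decoded = decode_column(records[column], convention)
        rows.append(compare_continuous(
            decoded[event], decoded[~event], variant=variant, variable=variable,
        ))

    return pd.DataFrame(
        [
            (r.variable, r.n_event, r.mean_event, r.sd_event,
             r.n_nonevent, r.mean_nonevent, r.sd_nonevent, r.test, r.p_value)
            for r in rows
        ],
        columns=["variable", "n_event", "mean_event", "sd_event",
                 "n_nonevent", "mean_nonevent", "sd_nonevent", "test", "p_value"],
    )
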