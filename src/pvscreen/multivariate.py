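"""Covariate-adjusted risk-factor estimation by multiple logistic regression.

The disproportionality screen is univariate: a drug's ROR can be inflated by
confounding with patient characteristics or co-reported drugs.  This module
adjusts for that by fitting, on complete cases only, a logistic model

    logit P(event) = b0 + b_sex * male + b_age * age + b_height * height
                     + b_weight * weight + sum_j b_j * drug_j

whose predictors are the decoded patient covariates plus an indicator per
drug that passed the univariate screen (P < 0.05 with more than
``min_reports`` event reports).  Before fitting, predictor pairs are
screened for internal correlation with pairwise-complete Spearman rho**2
(flagged above 0.9).

The fit is maximum likelihood via iteratively reweighted least squares with
step halving (so the log-likelihood never decreases across iterations),
Wald confidence intervals and two-sided P values.  Quasi-complete separation
— common with rare events and sparse drug indicators, and recognizable by
diverging coefficients — raises a diagnostic error naming the separating
term.  A Firth bias-reduced penalized fit is available behind a flag for
near-separated data.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .demographics import decode_column
from .disproportionality import SignalResult

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_COVARIATES",
    "CollinearityReport",
    "collinearity_screen",
    "select_predictors",
    "build_model_matrix",
    "CoefficientEstimate",
    "LogisticFit",
    "SeparationError",
    "fit_logistic",
    "coefficient_table",
]

DEFAULT_COVARIATES = ("sex_male", "age", "height", "weight")


@dataclass(frozen=True)
class CollinearityReport:
    """Pairwise Spearman rho**2 screen of the model's explanatory columns."""

    threshold: float
    flagged: tuple[tuple[str, str, float], ...]
    undefined: tuple[tuple[str, str], ...]

    @property
    def has_internal_correlation(self) -> bool:
        return len(self.flagged) > 0


def collinearity_screen(matrix: pd.DataFrame, threshold: float = 0.9,
                        exclude: Sequence[str] = ("event",)) -> CollinearityReport:
    """Flag predictor pairs whose pairwise-complete Spearman rho**2 exceeds the threshold.

    When nothing is flagged all predictors are treated as mutually
    independent factors and enter the model together.  Pairs involving a
    constant column have undefined rho and are reported separately.
    """
    cols = [c for c in matrix.columns if c not in exclude]
    if len(cols) < 2:
        raise ValueError("need at least 2 explanatory columns to screen")
    rho = matrix[cols].corr(method="spearman")  # pairwise-complete by construction
    flagged, undefined = [], []
    for c1, c2 in itertools.combinations(cols, 2):
        r = rho.loc[c1, c2]
        if pd.isna(r):
            undefined.append((c1, c2))
        elif r * r > threshold:
            flagged.append((c1, c2, float(r * r)))
    return CollinearityReport(threshold=threshold, flagged=tuple(flagged),
                              undefined=tuple(undefined))


def select_predictors(univariate_results: Sequence[SignalResult],
                      alpha: float = 0.05, min_reports: int = 3,
                      covariates: Sequence[str] = DEFAULT_COVARIATES) -> list[str]:
    """Model terms: univariately significant, adequately reported drugs plus covariates.

    A drug qualifies when its Fisher P is below ``alpha`` and it has strictly
    more than ``min_reports`` event reports.
    """
    drugs = sorted(
        r.exposure_label
        for r in univariate_results
        if r.p_value < alpha and r.n_event_reports > min_reports
    )
    return drugs + list(covariates)


def build_model_matrix(records: pd.DataFrame, event_term: str, drugs: Sequence[str],
                       unit: str = "case", convention: str = "lower") -> pd.DataFrame:
    """Complete-case model matrix with the event indicator and all predictors.

    With ``unit="case"`` (default) rows are unique cases: the event indicator
    is 1 when any of the case's records reports the event, and each drug
    indicator is 1 when any record names that drug.  ``unit="record"`` keeps
    one row per record instead.  Rows with unknown sex or a missing decoded
    age/height/weight are dropped (listwise deletion).
    """
    if unit not in ("case", "record"):
        raise ValueError(f"unit must be 'case' or 'record', got {unit!r}")
    frame = pd.DataFrame({
        "case_id": records["case_id"],
        "event": (records["event_term"] == event_term).astype(float),
        "sex_male": np.where(records["sex"] == "male", 1.0,
                             np.where(records["sex"] == "female", 0.0, np.nan)),
        "age": decode_column(records["age_code"], convention),
        "height": decode_column(records["height_code"], convention),
        "weight": decode_column(records["weight_code"], convention),
    })
    for drug in drugs:
        frame[str(drug)] = (records["drug_name"] == drug).astype(float)
    if unit == "case":
        agg = {"event": "max", "sex_male": "first", "age": "first",
               "height": "first", "weight": "first"}
        agg.update({str(d): "max" for d in drugs})
        frame = frame.groupby("case_id", sort=True).agg(agg).reset_index()
    n_before = len(frame)
    frame = frame.dropna(subset=["sex_male", "age", "height", "weight"]).reset_index(drop=True)
    logger.info("model matrix: %d complete %ss of %d", len(frame), unit, n_before)
    matrix = frame.drop(columns=["case_id"])
    if matrix["event"].nunique() < 2:
        raise ValueError("model matrix needs at least one event and one non-event row")
    return matrix


class SeparationError(RuntimeError):
    """The likelihood is maximized at infinity for the named term."""

    def __init__(self, term: str):
        self.term = term
        super().__init__(
            f"(quasi-)complete separation detected for term {term!r}: "
            "its coefficient diverges; consider the Firth-penalized fit"
        )


@dataclass(frozen=True)
class CoefficientEstimate:
    """One fitted model term on the odds-ratio scale."""

    term: str
    coefficient: float
    std_error: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    significant: bool


@dataclass(frozen=True)
class LogisticFit:
    """Converged maximum-likelihood logistic fit."""

    estimates: tuple[CoefficientEstimate, ...]
    log_likelihood: float
    n_obs: int
    n_iter: int
    converged: bool

    def __getitem__(self, term: str) -> CoefficientEstimate:
        for est in self.estimates:
            if est.term == term:
                return est
        raise KeyError(term)

    @property
    def terms(self) -> list[str]:
        return [e.term for e in self.estimates]


def _log_likelihood(y: np.ndarray, eta: np.ndarray) -> float:
    # numerically stable Bernoulli log-likelihood: sum y*eta - log(1+exp(eta))
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _check_complete_separation(X: np.ndarray, y: np.ndarray, names: list[str]) -> None:
    for j, name in enumerate(names):
        col = X[:, j]
        values = np.unique(col)
        if len(values) != 2:
            continue
        lo, hi = values
        if ((y[col == hi] == 1).all() and (y[col == lo] == 0).all()) or (
                (y[col == hi] == 0).all() and (y[col == lo] == 1).all()):
            raise SeparationError(name)


def fit_logistic(matrix: pd.DataFrame, response: str = "event", level: float = 0.95,
                 alpha: float = 0.05, firth: bool = False, max_iter: int = 100,
                 tol: float = 1e-8) -> LogisticFit:
    """Maximum-likelihood logistic regression with Wald inference.

    ``matrix`` holds the binary response column plus numeric predictor
    columns (an intercept is added internally).  Convergence is declared
    when the relative change in log-likelihood falls below ``tol``;
    non-convergence raises rather than returning silently.  ``firth=True``
    applies Firth's bias-reducing penalty, which keeps estimates finite
    under separation.

    A term is ``significant`` when its two-sided Wald P is below ``alpha``
    and its confidence interval excludes an odds ratio of one.
    """
    if response not in matrix.columns:
        raise ValueError(f"response column {response!r} not in matrix")
    if matrix.isna().any().any():
        raise ValueError("model matrix must not contain missing values")
    names = [c for c in matrix.columns if c != response]
    y = matrix[response].to_numpy(dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("response must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("response must include both events and non-events")
    X = np.column_stack([np.ones(len(matrix))] + [matrix[c].to_numpy(dtype=float)
                                                  for c in names])
    all_names = ["intercept"] + names

    _check_complete_separation(X[:, 1:], y, names)

    beta = np.zeros(X.shape[1])
    beta[0] = special.logit(np.clip(y.mean(), 1e-12, 1 - 1e-12))
    eta = X @ beta
    ll = _log_likelihood(y, eta)
    if firth:
        ll += _firth_penalty(X, eta)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        mu = special.expit(eta)
        w = np.clip(mu * (1 - mu), 1e-12, None)
        xtwx = (X * w[:, None]).T @ X
        score = X.T @ (y - mu)
        if firth:
            # Firth adjustment: score_j += sum_i h_i (1/2 - mu_i) x_ij
            h = _hat_diagonal(X, w, xtwx)
            score = X.T @ (y - mu + h * (0.5 - mu))
        try:
            step = np.linalg.solve(xtwx, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(xtwx, score, rcond=None)[0]
        # step halving guarantees a non-decreasing (penalized) log-likelihood
        new_beta, new_eta, new_ll = beta, eta, ll
        factor = 1.0
        for _ in range(40):
            cand = beta + factor * step
            cand_eta = X @ cand
            cand_ll = _log_likelihood(y, cand_eta)
            if firth:
                cand_ll += _firth_penalty(X, cand_eta)
            if cand_ll >= ll - 1e-12:
                new_beta, new_eta, new_ll = cand, cand_eta, cand_ll
                break
            factor /= 2
        beta, eta = new_beta, new_eta
        if abs(new_ll - ll) <= tol * (abs(ll) + tol):
            ll = new_ll
            converged = True
            break
        ll = new_ll

    if not firth:
        _raise_if_separated(matrix, names, y, beta, all_names, converged)
    if not converged:
        raise RuntimeError(f"logistic fit did not converge in {max_iter} iterations")

    mu = special.expit(eta)
    w = np.clip(mu * (1 - mu), 1e-12, None)
    cov = np.linalg.inv((X * w[:, None]).T @ X)
    se = np.sqrt(np.diag(cov))
    z = stats.norm.ppf(0.5 + level / 2)
    wald = beta / se
    p = 2 * stats.norm.sf(np.abs(wald))
    estimates = []
    for j, term in enumerate(all_names):
        lo, hi = math.exp(beta[j] - z * se[j]), math.exp(beta[j] + z * se[j])
        estimates.append(CoefficientEstimate(
            term=term, coefficient=float(beta[j]), std_error=float(se[j]),
            odds_ratio=math.exp(beta[j]), ci_low=lo, ci_high=hi,
            p_value=float(p[j]),
            significant=bool(p[j] < alpha and (lo > 1 or hi < 1)),
        ))
    raw_ll = _log_likelihood(y, eta)
    return LogisticFit(estimates=tuple(estimates), log_likelihood=raw_ll,
                       n_obs=len(y), n_iter=n_iter, converged=converged)


def _hat_diagonal(X: np.ndarray, w: np.ndarray, xtwx: np.ndarray) -> np.ndarray:
    # h_i = w_i * x_i' (X'WX)^-1 x_i
    xtwx_inv = np.linalg.inv(xtwx)
    return w * np.einsum("ij,jk,ik->i", X, xtwx_inv, X)


def _firth_penalty(X: np.ndarray, eta: np.ndarray) -> float:
    mu = special.expit(eta)
    w = np.clip(mu * (1 - mu), 1e-12, None)
    sign, logdet = np.linalg.slogdet((X * w[:, None]).T @ X)
    return 0.5 * logdet if sign > 0 else -math.inf


def _raise_if_separated(matrix: pd.DataFrame, names: list[str], y: np.ndarray,
                        beta: np.ndarray, all_names: list[str], converged: bool) -> None:
    """Diagnose quasi-complete separation from diverging binary-term coefficients."""
    for j, name in enumerate(names, start=1):
        col = matrix[name].to_numpy(dtype=float)
        values = np.unique(col)
        if len(values) != 2 or abs(beta[j]) < 15:
            continue
        hi = col == values.max()
        events_hi, events_lo = y[hi].sum(), y[~hi].sum()
        n_hi, n_lo = hi.sum(), (~hi).sum()
        if events_hi in (0, n_hi) or events_lo in (0, n_lo):
            raise SeparationError(name)
    if not converged and np.abs(beta).max() > 15:
        raise SeparationError(all_names[int(np.abs(beta).argmax())])


def coefficient_table(fit: LogisticFit, include_intercept: bool = False) -> pd.DataFrame:
    """Fitted terms as a DataFrame sorted by descending odds ratio."""
    rows = [e for e in fit.estimates if include_intercept or e.term != "intercept"]
    frame = pd.DataFrame(
        [(e.term, e.p_value, e.odds_ratio, e.ci_low, e.ci_high, e.significant)
         for e in rows],
        columns=["term", "p_value", "odds_ratio", "ci_low", "ci_high", "significant"],
    )
    return frame.sort_values("odds_ratio", ascending=False, ignore_index=True)
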