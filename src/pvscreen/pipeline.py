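"""End-to-end orchestration of the screening pipeline.

Stages: read the three tables, deduplicate, join into the all-data table,
normalize drug names, extract the suspected-medicine table; then produce the
patient-background comparison, the drug screen with its volcano plot, the
sex- and route-stratified volcanoes, the adjusted logistic model, the
per-route tables for the target drug and the co-treatment cross-tabulation.
Every stage appends its record count to a run log, and any stage failure is
re-raised with the stage name attached.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import demographics, disproportionality, multivariate, reporting_db, stratified
from .config import PipelineConfig
from .plots import volcano_plot

logger = logging.getLogger(__name__)

__all__ = ["PipelineError", "PipelineState", "prepare_tables", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {cause}")


@dataclass
class PipelineState:
    """Intermediate tables plus the per-stage record counts."""

    config: PipelineConfig
    database: reporting_db.ReportDatabase | None = None
    all_data: pd.DataFrame | None = None
    suspected: pd.DataFrame | None = None
    stage_counts: list[tuple[str, int]] = field(default_factory=list)
    artifacts: dict[str, Path] = field(default_factory=dict)

    def count(self, stage: str, n: int) -> None:
        self.stage_counts.append((stage, int(n)))
        logger.info("%s: %d records", stage, n)

    @property
    def outdir(self) -> Path:
        out = Path(self.config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        return out

    def save_table(self, name: str, frame: pd.DataFrame) -> Path:
        path = self.outdir / f"{name}.tsv"
        frame.to_csv(path, sep="\t", index=False)
        self.artifacts[name] = path
        return path


def _stage(name: str):
    def decorate(fn):
        def wrapped(state: PipelineState, *args, **kwargs):
            try:
                return fn(state, *args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc
        wrapped.__name__ = fn.__name__
        wrapped.__doc__ = fn.__doc__
        return wrapped
    return decorate


@_stage("build")
def prepare_tables(state: PipelineState) -> PipelineState:
    """Read, deduplicate, join, normalize names and extract suspected records."""
    cfg = state.config
    cfg.validate(require_inputs=True)
    options = reporting_db.FormatOptions(delimiter=cfg.delimiter, encoding=cfg.encoding)
    db = reporting_db.read_tables(cfg.demo_path, cfg.drug_path, cfg.reac_path, options)
    state.count("raw demo rows", len(db.demo))
    state.count("raw drug rows", len(db.drug))
    state.count("raw reac rows", len(db.reac))
    dedup = reporting_db.deduplicate(db)
    state.database = dedup.database
    state.count("deduplicated drug rows", len(dedup.database.drug))
    state.count("deduplicated reac rows", len(dedup.database.reac))
    joined = reporting_db.build_all_data_table(dedup.database, cfg.orphan_policy)
    all_data = joined.records
    if cfg.synonym_map:
        all_data = reporting_db.normalize_drug_names(all_data, cfg.synonym_map)
    state.all_data = all_data
    state.count("all data table", len(all_data))
    state.suspected = reporting_db.filter_suspected(all_data)
    state.count("suspected medicine table", len(state.suspected))
    state.save_table("all_data", all_data)
    state.save_table("suspected", state.suspected)
    return state


@_stage("background")
def run_background(state: PipelineState) -> pd.DataFrame:
    """Patient-background comparisons and the yearly reporting trend."""
    cfg = state.config
    table = demographics.background_table(state.suspected, cfg.event_term,
                                          variant=cfg.t_test_variant)
    state.save_table("background", table)
    trend = demographics.yearly_trend(state.suspected, event_term=cfg.event_term)
    trend_frame = pd.DataFrame({"year": trend.years,
                                "event_fraction": trend.event_fraction_per_year})
    state.save_table("yearly_trend", trend_frame)
    (state.outdir / "yearly_trend.json").write_text(
        json.dumps({"rho": trend.rho, "p_value": trend.p_value}, indent=2))
    logger.info("yearly trend: rho=%.4f P=%.4f", trend.rho, trend.p_value)
    return table


@_stage("screen")
def run_drug_screen(state: PipelineState) -> list[disproportionality.SignalResult]:
    """Drug-wise disproportionality screen and volcano plot."""
    cfg = state.config
    results = disproportionality.screen_drugs(
        state.suspected, cfg.event_term, unit=cfg.screen_unit,
        level=cfg.ci_level, continuity=cfg.continuity_correction)
    state.save_table("screen_drugs", disproportionality.signal_table(results))
    path = state.outdir / "volcano_drugs.png"
    volcano_plot(results, out_path=path, title=f"drug screen: {cfg.event_term}",
                 annotate=5)
    state.artifacts["volcano_drugs"] = path
    return results


@_stage("sex screen")
def run_sex_screen(state: PipelineState) -> list[disproportionality.SignalResult]:
    """Event-wise screen against male sex, with volcano plot."""
    cfg = state.config
    results = disproportionality.screen_events(
        state.suspected, lambda df: df["sex"] == "male", unit=cfg.screen_unit,
        level=cfg.ci_level, continuity=cfg.continuity_correction)
    state.save_table("screen_sex", disproportionality.signal_table(results))
    path = state.outdir / "volcano_sex.png"
    volcano_plot(results, out_path=path, title="events by sex (male vs female)",
                 annotate=5)
    state.artifacts["volcano_sex"] = path
    return results


@_stage("model")
def run_model(state: PipelineState,
              screen_results: list[disproportionality.SignalResult] | None = None
              ) -> multivariate.LogisticFit:
    """Predictor selection, collinearity screen and logistic fit."""
    cfg = state.config
    if screen_results is None:
        screen_results = run_drug_screen(state)
    terms = multivariate.select_predictors(
        screen_results, alpha=cfg.alpha, min_reports=cfg.min_reports)
    drugs = [t for t in terms if t not in multivariate.DEFAULT_COVARIATES]
    matrix = multivariate.build_model_matrix(
        state.suspected, cfg.event_term, drugs, unit=cfg.model_unit)
    state.count("complete-case model rows", len(matrix))
    report = multivariate.collinearity_screen(matrix, cfg.collinearity_threshold)
    (state.outdir / "collinearity.json").write_text(json.dumps({
        "threshold": report.threshold,
        "flagged": [list(f) for f in report.flagged],
        "undefined": [list(u) for u in report.undefined],
    }, indent=2))
    if report.has_internal_correlation:
        logger.warning("internal correlation flagged: %s", report.flagged)
    fit = multivariate.fit_logistic(matrix, level=cfg.ci_level, alpha=cfg.alpha)
    state.save_table("model", multivariate.coefficient_table(fit))
    return fit


@_stage("routes")
def run_routes(state: PipelineState) -> list[stratified.RouteResult]:
    """Per-route Fisher tests for the target drug plus the route-stratum volcano."""
    cfg = state.config
    results = stratified.route_screen(state.suspected, cfg.target_drug, cfg.event_term)
    state.save_table("routes", stratified.route_table(results))
    drug_records = state.suspected[state.suspected["drug_name"] == cfg.target_drug]
    if drug_records["route"].notna().any():
        volcano = disproportionality.screen_events(
            drug_records, lambda df: df["route"] == "intravenous",
            unit=cfg.screen_unit, level=cfg.ci_level,
            continuity=cfg.continuity_correction)
        state.save_table("screen_route", disproportionality.signal_table(volcano))
        path = state.outdir / "volcano_route.png"
        volcano_plot(volcano, out_path=path,
                     title=f"{cfg.target_drug}: events by intravenous route", annotate=5)
        state.artifacts["volcano_route"] = path
    return results


@_stage("cotreatment")
def run_cotreatment(state: PipelineState) -> stratified.CotreatmentTable:
    """Co-treatment cross-tabulation of unique event cases (all involvements)."""
    cfg = state.config
    if not cfg.anticancer_drugs:
        raise ValueError("anticancer_drugs must list at least one drug name")
    table = stratified.cotreatment_cross_tab(
        state.all_data, cfg.event_term, cfg.target_drug, cfg.anticancer_drugs)
    pct = stratified.cotreatment_percentages(table)
    frame = pd.DataFrame([
        ("both", table.n_both), ("drug_only", table.n_drug_only),
        ("class_only", table.n_class_only), ("neither", table.n_neither),
        ("unique_event_cases", table.n_cases),
    ], columns=["cell", "n_cases"])
    state.save_table("cotreatment", frame)
    (state.outdir / "cotreatment_percentages.json").write_text(json.dumps(pct, indent=2))
    return table


def _write_run_log(state: PipelineState) -> None:
    lines = [f"{stage}\t{n}" for stage, n in state.stage_counts]
    path = state.outdir / "run_log.tsv"
    path.write_text("stage\tcount\n" + "\n".join(lines) + "\n")
    state.artifacts["run_log"] = path


def run_pipeline(config: PipelineConfig) -> PipelineState:
    """Run every stage and return the state with all artifact paths."""
    state = PipelineState(config=config)
    prepare_tables(state)
    run_background(state)
    screen_results = run_drug_screen(state)
    run_sex_screen(state)
    run_model(state, screen_results)
    run_routes(state)
    if config.anticancer_drugs:
        run_cotreatment(state)
    else:
        logger.info("cotreatment stage skipped: no anticancer_drugs configured")
    _write_run_log(state)
    return state
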