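"""Adjust the screened drugs for patient covariates with logistic regression.

Selects drugs that pass the univariate screen (P < 0.05, more than three
event reports), screens predictors for internal correlation (Spearman
rho^2 > 0.9), and fits the case-level complete-case logistic model.
"""

import pvscreen as pv
from pvscreen import multivariate as mv

db, truth = pv.generate_database(pv.demo_spec(n_cases=40_000, seed=3))
suspected = pv.filter_suspected(
    pv.build_all_data_table(pv.deduplicate(db).database).records)

screen = pv.screen_drugs(suspected, truth.event_term)
terms = mv.select_predictors(screen)
drugs = [t for t in terms if t not in mv.DEFAULT_COVARIATES]
print(f"predictors entering the model: {drugs} + {list(mv.DEFAULT_COVARIATES)}")

matrix = mv.build_model_matrix(suspected, truth.event_term, drugs)
print(f"complete cases: {len(matrix)} (of {suspected['case_id'].nunique()} cases; "
      "height/weight missingness drives the loss)")

report = mv.collinearity_screen(matrix)
print("internal correlation flagged:", report.flagged or "none")

fit = mv.fit_logistic(matrix)
print(mv.coefficient_table(fit).to_string(index=False,
                                          float_format=lambda v: f"{v:.3g}"))
print(f"\nplanted values — sex_male OR {2.718**truth.male_log_odds:.1f}, drugs:"
      f" {truth.multipliers}")
print("each planted value should fall inside its fitted 95% CI; the adjusted")
print("ORs undo the attenuation the marginal screen shows for rare exposures.")
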