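"""Evaluate a risk model: ROC/AUC with DeLong CI, optimism-corrected
calibration, nomogram scales, and the categorical cohort comparisons.
"""

import numpy as np

from ventidose.evaluation import (
    REFERENCE_FRACTIONATION_TABLE,
    REFERENCE_MACHINE_TABLE,
    REFERENCE_MODEL_AUC,
    REFERENCE_MODEL_AUC_CI,
    calibrate_bootstrap,
    nomogram_points,
    pearson_chi2,
    roc_auc,
)
from ventidose.phantom import CohortSimSpec, simulate_cohort
from ventidose.riskmodel import PUBLISHED_STEPWISE_MODEL, fit_logistic

cohort = simulate_cohort(CohortSimSpec(n_patients=120, seed=21))
covariates = list(PUBLISHED_STEPWISE_MODEL.coefficients)

model = fit_logistic(cohort, covariates)
scores = model.predict_probability(cohort)
roc = roc_auc(scores, cohort["rp_grade2plus"].to_numpy())
print(f"refit model AUC: {roc.auc:.4f} (95% DeLong CI {roc.ci_low:.4f}-{roc.ci_high:.4f})")
print(f"reference cohort AUC for comparison: {REFERENCE_MODEL_AUC} "
      f"(95% CI {REFERENCE_MODEL_AUC_CI[0]}-{REFERENCE_MODEL_AUC_CI[1]})")

cal = calibrate_bootstrap(cohort, covariates, n_boot=200, seed=7)
print(f"optimism-corrected calibration slope: {cal.slope:.3f} "
      f"(1.0 = no overfitting shrinkage needed)")

ranges = {c: (float(cohort[c].min()), float(cohort[c].max())) for c in covariates}
nomo = nomogram_points(model, ranges)
print(f"nomogram: {nomo.max_points_variable} carries the 0-100 point scale")
total = nomo.total_points({c: float(cohort[c].mean()) for c in covariates})
print(f"mean-covariate patient: {total:.0f} total points -> "
      f"risk {nomo.probability_from_total(total):.2f}")

for label, table in (("machine type", REFERENCE_MACHINE_TABLE),
                     ("fractionation", REFERENCE_FRACTIONATION_TABLE)):
    stat, dof, p = pearson_chi2(table)
    print(f"{label}: chi2 = {stat:.3f}, df = {dof}, p = {p:.3f}  "
          f"(no association with pneumonitis grade)")
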