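"""Prognostic evaluation of the per-patient feature table against the
metastasis endpoint: per-feature ROC with bootstrap optimism correction,
per-range folded-AUC summaries with significant-improvement sums, the
stepwise multivariate logistic model, and a cutoff/redundancy demonstration
on the strongest features.

Reads results/per_patient.csv; writes results/per_feature_auc.csv,
results/per_range_summary.csv, results/stepwise_model.csv and
results/cutoffs.csv.
"""

from pathlib import Path

import pandas as pd

from stainslice import RunConfig, evaluate_cohort, optimal_cutoff, spearman_matrix

OUT = Path("results")
cohort = pd.read_csv(OUT / "per_patient.csv")

config = RunConfig(bootstrap_resamples=1000, seed=7)
tables = evaluate_cohort(cohort, config)

tables["per_feature"].to_csv(OUT / "per_feature_auc.csv", index=False)
tables["per_range"].to_csv(OUT / "per_range_summary.csv", index=False)
tables["stepwise"].to_csv(OUT / "stepwise_model.csv", index=False)

sig = tables["per_feature"].dropna(subset=["auc"])
sig = sig[sig["p"] <= 0.05].sort_values("p")
print(f"{len(sig)} of {len(tables['per_feature'])} feature x range AUCs "
      "significant at p <= 0.05; strongest:")
print(sig.head(8).round(3).to_string(index=False))

print("\nper-range summary (mean folded AUC, improvement sums):")
print(tables["per_range"].round(3).to_string(index=False))

print("\nstepwise multivariate model (retained terms):")
print(tables["stepwise"].round(4).to_string(index=False)
      if len(tables["stepwise"]) else "  (empty)")

# dichotomise the top significant features and screen their redundancy
top = [f"{r}|{f}" for r, f in zip(sig["range"].head(4), sig["feature"].head(4))]
cut_rows, categorized = [], {}
for col in top:
    res = optimal_cutoff(cohort[col], cohort["outcome"])
    cut_rows.append({"feature": col, "cutoff": res.cutoff, "chi2": res.chi2,
                     "n_low": res.n_low, "n_high": res.n_high,
                     "high_risk": res.high_risk})
    categorized[col] = (cohort[col] > res.cutoff).astype(int)
pd.DataFrame(cut_rows).to_csv(OUT / "cutoffs.csv", index=False)
rho, _ = spearman_matrix(pd.DataFrame(categorized))
print("\noptimal cutoffs (chi-square maximisation, 10th-90th pct window):")
print(pd.DataFrame(cut_rows).round(3).to_string(index=False))
print("\nSpearman rho between the dichotomised classifiers:")
print(rho.round(2).to_string())
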