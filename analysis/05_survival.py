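#!/usr/bin/env python
"""Survival impact of reduced NEIL1 expression, cohort by cohort.

Kaplan-Meier / log-rank comparison of the reduced-NEIL1 group against the
rest, plus univariate and multivariate (age, stage) Cox fits.  The study
plants a hazard ratio of 2 in cohort SIM02 only.  Writes
results/survival.tsv.
"""

from pathlib import Path

import pandas as pd

from glycoburden.expression_mutload import DichotomyRule
from glycoburden.pipeline import default_study_configs, stage_survival
from glycoburden.synthetic_data import generate_cohort

SEED = 1

def main() -> None:
    cohorts = [generate_cohort(c) for c in default_study_configs(seed=SEED)]
    rule = DichotomyRule(gene="NEIL1", direction="reduced")
    rows = []
    for cohort in cohorts:
        fit = stage_survival(cohort, "NEIL1", rule)
        uni = fit.cox.loc["abnormal"]
        multi = fit.extras["multivariate"].loc["abnormal"]
        rows.append(
            {"cancer_label": cohort.cancer_label,
             "n_abnormal": fit.extras["n_abnormal"], "n_other": fit.extras["n_other"],
             "logrank_p": fit.logrank_p, "hr": round(uni["hr"], 3),
             "ci_low": round(uni["ci_low"], 3), "ci_high": round(uni["ci_high"], 3),
             "hr_multivariate": round(multi["hr"], 3), "converged": fit.converged}
        )
    table = pd.DataFrame(rows)
    Path("results").mkdir(exist_ok=True)
    table.to_csv("results/survival.tsv", sep="\t", index=False)
    print(table.to_string(index=False))
    sig = table[table["logrank_p"] < 0.05]["cancer_label"].tolist()
    print(f"\nSignificant log-rank separation in: {sig} "
          "(the planted hazard-ratio cohort).")


if __name__ == "__main__":
    main()
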