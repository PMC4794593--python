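#!/usr/bin/env python
"""Cross-cancer correlation of normalized expression with mutation load.

For each target gene, correlates the 13 cohort-level medians of
YWHAZ-normalized tumor expression with median mutation load per Mb (total
and SNP-type).  The study design plants a negative trend for NEIL1 and a
positive one for NEIL3; NEIL2 is left uncoupled.  Writes
results/cross_cancer.tsv.
"""

from pathlib import Path

import pandas as pd

from glycoburden.pipeline import default_study_configs, stage_cross_cancer
from glycoburden.synthetic_data import generate_cohort

SEED = 1

def main() -> None:
    cohorts = [generate_cohort(c) for c in default_study_configs(seed=SEED)]
    rows = []
    for gene in ("NEIL1", "NEIL2", "NEIL3"):
        for load_type in ("total", "snp"):
            corr, _ = stage_cross_cancer(cohorts, gene, "YWHAZ", load_type)
            rows.append(
                {"gene": gene, "load_type": load_type, "rho": round(corr.rho, 4),
                 "p_value": corr.p_value, "n_cohorts": corr.n}
            )
    table = pd.DataFrame(rows)
    Path("results").mkdir(exist_ok=True)
    table.to_csv("results/cross_cancer.tsv", sep="\t", index=False)
    print(table.to_string(index=False))
    print("\nNEIL1 tracks mutation load negatively and NEIL3 positively, "
          "as planted; NEIL2 shows no cross-cancer relation.")


if __name__ == "__main__":
    main()
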