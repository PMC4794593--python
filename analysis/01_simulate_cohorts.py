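#!/usr/bin/env python
"""Simulate the default 13-cohort study and tabulate what was planted.

Writes the per-cohort design summary to results/cohort_summary.tsv and the
raw data layers (MAF, expression/methylation/clinical TSVs) for each cohort
under scratch/cohorts/ for inspection with external tools.
"""

from pathlib import Path

import pandas as pd

from glycoburden.pipeline import default_study_configs
from glycoburden.synthetic_data import generate_cohort

SEED = 1

def main() -> None:
    configs = default_study_configs(seed=SEED)
    rows = []
    for cfg in configs:
        bundle = generate_cohort(cfg)
        bundle.write_to_dir(Path("scratch/cohorts") / cfg.cancer_label)
        rows.append(
            {
                "cancer_label": cfg.cancer_label,
                "n_tumor": cfg.n_tumor,
                "n_normal": cfg.n_normal,
                "silenced_fraction": cfg.silenced_fraction,
                "load_coupling": cfg.load_coupling,
                "hazard_ratio": cfg.hazard_ratio,
                "base_mutation_rate": round(cfg.base_mutation_rate, 1),
                "n_mutations": len(bundle.mutations),
            }
        )
    table = pd.DataFrame(rows)
    Path("results").mkdir(exist_ok=True)
    table.to_csv("results/cohort_summary.tsv", sep="\t", index=False)
    n_planted = (table["silenced_fraction"] > 0).sum()
    print(table.to_string(index=False))
    print(f"\n{n_planted}/13 cohorts carry planted NEIL1 silencing; "
          f"cohort {table.loc[table['hazard_ratio'] > 1, 'cancer_label'].iloc[0]} "
          "carries the planted hazard ratio of 2.")


if __name__ == "__main__":
    main()
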