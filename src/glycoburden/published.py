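"""Published pan-cancer summary statistics used as worked-example inputs.

These are per-cancer-type summary rows reported by the original 13-cohort
TCGA analysis of NEIL glycosylase expression and somatic mutation load:
the Mann-Whitney and Spearman P values of the NEIL3/mutation-load and
NEIL3/APOBEC3B association screens, and the per-cohort silencing-criterion
summary values (delta beta, hypermethylated-tumor percentage, fold
expression change, rho) for the NEIL1 promoter probes.  P values printed
as "<0.0001" are carried as the string and parsed as the upper bound
1e-4 for significance counting.

They serve as fixed inputs for the significance-counting and
criteria-checking utilities; nothing here is computed by this package.
"""

from __future__ import annotations

import pandas as pd


def parse_p(p) -> float:
    """Numeric value of a printed P entry; '<x' parses as its upper bound x."""
    if isinstance(p, str) and p.startswith("<"):
        return float(p[1:])
    return float(p)


def neil3_mutation_load_screen() -> pd.DataFrame:
    """Per-cohort NEIL3-dichotomized mutation-load comparison summaries."""
    rows = [
        ("BLCA", 129, "0.0341", 0.1593, "0.0714"),
        ("BRCA", 977, "<0.0001", 0.3006, "<0.0001"),
        ("COAD", 209, "0.0942", 0.1121, "0.1061"),
        ("HNSC", 489, "0.0477", 0.0019, "0.9673"),
        ("KICH", 66, "0.3705", 0.2637, "0.0324"),
        ("KIRC", 212, "0.0770", 0.1179, "0.0867"),
        ("KIRP", 168, "0.7409", 0.0117, "0.8800"),
        ("LUAD", 483, "<0.0001", 0.3287, "<0.0001"),
        ("LUSC", 179, "0.0133", 0.2112, "0.0045"),
        ("PRAD", 258, "0.0012", 0.3030, "<0.0001"),
        ("READ", 81, "0.2707", 0.2900, "0.0086"),
        ("STAD", 224, "<0.0001", 0.5105, "<0.0001"),
        ("THCA", 404, "0.1612", 0.0690, "0.1664"),
    ]
    df = pd.DataFrame(rows, columns=["cohort", "n", "mwu_p", "rho", "rho_p"])
    df["mwu_p_value"] = df["mwu_p"].map(parse_p)
    df["rho_p_value"] = df["rho_p"].map(parse_p)
    return df


def neil1_silencing_summaries() -> pd.DataFrame:
    """Per-cohort NEIL1 silencing-criterion summary values.

    Columns hold the criterion-2 beta difference, criterion-3 fold
    expression change and criterion-4 rho at the promoter probe used, plus
    the hypermethylated-tumor percentage; only cohorts called silenced
    appear.
    """
    rows = [
        ("BRCA", "cg12978308", 0.109, 7.2, 2.039, -0.3729, "<0.0001", False),
        ("COAD", "cg12978308", 0.291, 29.9, 2.087, -0.5241, "<0.0001", False),
        ("HNSC", "cg12978308", 0.323, 57.7, 2.354, -0.3699, "<0.0001", False),
        ("KIRC", "cg00836571", 0.110, 7.1, 2.407, -0.4755, "<0.0001", False),
        ("KIRP", "cg12978308", 0.351, 21.2, 2.276, -0.6219, "<0.0001", False),
        ("LUAD", "cg12978308", 0.109, 64.3, 2.249, -0.3695, "<0.0001", False),
        ("LUSC", "cg12978308", 0.254, 27.0, 1.624, -0.2799, "<0.0001", False),
        ("READ", "cg12978308", 0.145, 11.1, 1.998, -0.3699, "0.0003", False),
        # the gastric cohort lacks normal methylation columns; its fold
        # change used an external normal expression mean (fallback mode)
        ("STAD", "cg12978308", 0.290, 40.3, 2.208, -0.5465, "<0.0001", True),
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "cohort",
            "probe_id",
            "delta_beta",
            "hypermethylated_pct",
            "fold_change",
            "rho",
            "rho_p",
            "fallback_used",
        ],
    )
    df["rho_p_value"] = df["rho_p"].map(parse_p)
    return df


def neil3_apobec3b_screen() -> pd.DataFrame:
    """Per-cohort NEIL3/APOBEC3B co-expression comparison summaries."""
    rows = [
        ("BLCA", 241, "0.0034", 0.0697, "0.2811"),
        ("BRCA", 1056, "<0.0001", 0.5215, "<0.0001"),
        ("COAD", 260, "0.0191", 0.1569, "0.0113"),
        ("HNSC", 498, "0.2122", 0.2326, "<0.0001"),
        ("KICH", 66, "0.5463", 0.1312, "0.2935"),
        ("KIRC", 519, "<0.0001", 0.5777, "<0.0001"),
        ("KIRP", 198, "0.0017", 0.4466, "<0.0001"),
        ("LUAD", 490, "<0.0001", 0.2759, "<0.0001"),
        ("LUSC", 490, "0.0187", 0.1302, "0.0039"),
        ("PRAD", 333, "<0.0001", 0.5876, "<0.0001"),
        ("READ", 92, "0.0985", 0.1559, "0.1379"),
        ("STAD", 238, "0.0007", 0.1848, "0.0042"),
        ("THCA", 508, "<0.0001", 0.4242, "<0.0001"),
    ]
    df = pd.DataFrame(rows, columns=["cohort", "n", "mwu_p", "rho", "rho_p"])
    df["mwu_p_value"] = df["mwu_p"].map(parse_p)
    df["rho_p_value"] = df["rho_p"].map(parse_p)
    return df
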