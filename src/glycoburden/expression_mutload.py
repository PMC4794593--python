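"""Housekeeping normalization, fold-change dichotomization, mutation loads.

These are the primitives behind the per-cancer association analyses:
expression of a target gene divided sample-wise by a constitutive
housekeeping gene (YWHAZ by default in the pipeline), tumors split at a
fold-multiple of the normal-tissue median, and per-sample somatic mutation
counts converted to loads per megabase of captured exome.

Boundary convention (fixed, since either choice is defensible): a
"reduced"-direction rule calls a tumor abnormal when value < cutoff x
reference (strict), an "elevated" rule when value >= cutoff x reference
(inclusive), so symmetric edge cases partition deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError
from .io_formats import ExpressionMatrix, mutations_to_frame

#: Default denominator (Mb) for per-megabase loads: a typical whole-exome
#: capture size.  Every cross-sample rank statistic is invariant to this
#: constant; reports echo the value used.
DEFAULT_CAPTURE_MB = 38.0


@dataclass
class DichotomyRule:
    """Fold-change rule splitting tumors into abnormal vs other.

    ``direction`` is "reduced" (abnormal = low expression, default cutoff
    0.5-fold the normal median) or "elevated" (abnormal = high expression,
    default cutoff 2.5-fold).  ``overrides`` maps a cohort label to a
    cohort-specific fold cutoff (e.g. a 10-fold cutoff for one squamous
    lung cohort in the elevated-gene analysis).
    """

    gene: str
    direction: str
    fold_cutoff: float | None = None
    overrides: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.direction not in ("reduced", "elevated"):
            raise DataError(f"direction must be reduced or elevated, got {self.direction!r}")
        if self.fold_cutoff is None:
            self.fold_cutoff = 0.5 if self.direction == "reduced" else 2.5
        for cutoff in [self.fold_cutoff, *self.overrides.values()]:
            if not cutoff > 0:
                raise DataError("fold_cutoff must be > 0")
            if self.direction == "reduced" and cutoff >= 1:
                raise DataError("reduced-direction cutoff must be < 1")
            if self.direction == "elevated" and cutoff <= 1:
                raise DataError("elevated-direction cutoff must be > 1")

    def cutoff_for(self, cohort: str | None = None) -> float:
        if cohort is not None and cohort in self.overrides:
            return self.overrides[cohort]
        return float(self.fold_cutoff)


def normalize_to_housekeeping(expr: ExpressionMatrix, gene: str, hk_gene: str) -> pd.Series:
    """Per-sample ratio of a gene's expression to a housekeeping gene's."""
    for g in (gene, hk_gene):
        if g not in expr.values.index:
            raise DataError(f"gene {g!r} not in expression matrix")
    hk = expr.values.loc[hk_gene]
    zero = list(hk.index[hk <= 0])
    if zero:
        raise DataError(f"housekeeping expression is 0 in samples: {zero}")
    return expr.values.loc[gene] / hk


def median_normal_expression(expr: ExpressionMatrix, gene: str) -> float:
    """Median expression of ``gene`` over normal-labelled samples."""
    if gene not in expr.values.index:
        raise DataError(f"gene {gene!r} not in expression matrix")
    normals = expr.normal_samples
    if not normals:
        raise DataError("no normal samples to form a reference")
    return float(np.median(expr.values.loc[gene, normals].to_numpy()))


def dichotomize(
    values: pd.Series,
    rule: DichotomyRule,
    reference: float,
    cohort: str | None = None,
) -> pd.Series:
    """Label each tumor sample "abnormal" or "other" under a fold rule.

    ``reference`` is the normal-tissue median of the same gene.  Reduced:
    abnormal iff value < cutoff * reference.  Elevated: abnormal iff
    value >= cutoff * reference.
    """
    if not reference > 0:
        raise DataError(f"reference median must be > 0, got {reference}")
    threshold = rule.cutoff_for(cohort) * reference
    v = values.astype(float)
    if rule.direction == "reduced":
        abnormal = v < threshold
    else:
        abnormal = v >= threshold
    return abnormal.map({True: "abnormal", False: "other"}).rename("group")


def mutation_loads(mutations, samples, capture_mb: float = DEFAULT_CAPTURE_MB) -> pd.DataFrame:
    """Per-sample mutation counts and loads per Mb.

    ``mutations`` is a list of MutationRecord or a tidy mutation DataFrame;
    ``samples`` fixes the output rows (samples without records get zeros).
    SNP-type counts single-nucleotide exchanges only; DNP/TNP/ONP go to
    ``other_count`` (and to the total), insertions and deletions to their
    own columns.
    """
    if not capture_mb > 0:
        raise DataError(f"capture_mb must be > 0, got {capture_mb}")
    samples = list(samples)
    if not samples:
        raise DataError("samples list is empty")
    frame = mutations_to_frame(mutations)
    counts = (
        frame.groupby(["sample_barcode", "variant_type"], sort=True)
        .size()
        .unstack(fill_value=0)
        .reindex(samples, fill_value=0)
    )

    def col(name: str) -> pd.Series:
        return counts[name] if name in counts.columns else pd.Series(0, index=counts.index)

    table = pd.DataFrame(index=pd.Index(samples, name="sample_barcode"))
    table["snp_count"] = col("SNP").astype(int)
    table["ins_count"] = col("INS").astype(int)
    table["del_count"] = col("DEL").astype(int)
    table["other_count"] = (
        col("DNP") + col("TNP") + col("ONP") + col("OTHER")
    ).astype(int)
    table["total_count"] = (
        table["snp_count"] + table["ins_count"] + table["del_count"] + table["other_count"]
    )
    table["total_per_mb"] = table["total_count"] / capture_mb
    table["snp_per_mb"] = table["snp_count"] / capture_mb
    table.attrs["capture_mb"] = float(capture_mb)
    return table
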