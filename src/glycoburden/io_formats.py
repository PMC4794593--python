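"""Readers and writers for the flat files the pipeline touches.

Formats covered: tab-separated MAF somatic mutation files (standard column
names, 1-based coordinates), gene x sample expression TSV (RSEM or RPKM
scale), probe x sample HumanMethylation450 beta-value TSV with a probe ->
gene/TSS-distance annotation, clinical TSV (survival time in days, event
flag, covariates), and deterministic TSV/JSON report output.

Missing beta values are carried as NaN and excluded pairwise downstream;
they are never silently zeroed, which would bias the normal-tissue
methylation mean of the silencing classifier.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, FormatError

# Canonical MAF Variant_Type spellings, matched case-insensitively; anything
# else maps to OTHER and is tallied in the parse report.
VARIANT_TYPES = ("SNP", "DNP", "TNP", "ONP", "INS", "DEL", "OTHER")

MUTATION_COLUMNS = [
    "gene_symbol",
    "sample_barcode",
    "variant_type",
    "chrom",
    "position",
    "variant_classification",
]

_MAF_REQUIRED = {"hugo_symbol", "variant_type", "tumor_sample_barcode"}


@dataclass(slots=True)
class MutationRecord:
    """One somatic mutation call (one MAF data row)."""

    gene_symbol: str
    sample_barcode: str
    variant_type: str
    chrom: str | None = None
    position: int | None = None
    variant_classification: str | None = None

    def __post_init__(self) -> None:
        if self.variant_type not in VARIANT_TYPES:
            raise DataError(f"unknown variant_type {self.variant_type!r}")


@dataclass
class ParseReport:
    """Row accounting for a MAF parse: kept + skipped + OTHER covers all rows."""

    n_rows: int = 0
    n_records: int = 0
    n_skipped: int = 0
    n_other: int = 0
    unrecognized: Counter = field(default_factory=Counter)


def normalize_variant_type(raw: str) -> str:
    token = str(raw).strip().upper()
    return token if token in VARIANT_TYPES[:-1] else "OTHER"


def infer_tissue_from_barcode(barcode: str) -> str:
    """Tissue label from a TCGA aliquot barcode's sample-type code.

    Codes 01-09 are tumors, 10-19 normals (e.g. ``...-01A`` tumor,
    ``...-11A`` solid tissue normal).
    """
    parts = str(barcode).split("-")
    field = None
    if len(parts) >= 4 and len(parts[3]) >= 2 and parts[3][:2].isdigit():
        field = parts[3]
    elif len(parts) >= 2 and len(parts[-1]) >= 2 and parts[-1][:2].isdigit():
        field = parts[-1]  # short barcodes end in the sample-type field
    if field is not None:
        code = int(field[:2])
        if 1 <= code <= 9:
            return "tumor"
        if 10 <= code <= 19:
            return "normal"
    raise DataError(f"cannot infer tissue for sample {barcode!r}; supply a tissue_map")


def _tissue_series(samples: Sequence[str], tissue_map: Mapping[str, str] | None) -> pd.Series:
    labels = {}
    for s in samples:
        if tissue_map is not None and s in tissue_map:
            lab = tissue_map[s]
        else:
            lab = infer_tissue_from_barcode(s)
        if lab not in ("tumor", "normal"):
            raise DataError(f"tissue label for {s!r} must be 'tumor' or 'normal', got {lab!r}")
        labels[s] = lab
    return pd.Series(labels, name="tissue").reindex(samples)


@dataclass
class ExpressionMatrix:
    """Gene x sample non-negative expression values with tumor/normal labels.

    ``values`` is genes (rows) x samples (columns); ``tissue`` maps each
    sample to ``tumor`` or ``normal``; ``unit`` is ``RSEM`` or ``RPKM``.
    """

    values: pd.DataFrame
    tissue: pd.Series
    unit: str = "RSEM"

    def __post_init__(self) -> None:
        if self.unit not in ("RSEM", "RPKM"):
            raise DataError(f"unit must be RSEM or RPKM, got {self.unit!r}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise FormatError(f"duplicate gene rows: {dups}")
        if self.values.columns.duplicated().any():
            raise FormatError("duplicate sample columns")
        if (self.values.to_numpy() < 0).any():
            raise FormatError("negative expression values")
        missing = [s for s in self.values.columns if s not in self.tissue.index]
        if missing:
            raise DataError(f"samples without tissue label: {missing}")
        self.tissue = self.tissue.reindex(self.values.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def sample_ids(self, tissue: str) -> list[str]:
        return list(self.tissue.index[self.tissue == tissue])

    @property
    def tumor_samples(self) -> list[str]:
        return self.sample_ids("tumor")

    @property
    def normal_samples(self) -> list[str]:
        return self.sample_ids("normal")


@dataclass
class MethylationTable:
    """Probe x sample beta values in [0, 1] with probe -> gene/TSS annotation.

    ``beta`` may contain NaN for missing measurements.  ``annotation`` is
    indexed by probe ID with columns ``gene_symbol`` and ``tss_distance``
    (signed bp to the transcription start site).
    """

    beta: pd.DataFrame
    annotation: pd.DataFrame
    tissue: pd.Series

    def __post_init__(self) -> None:
        arr = self.beta.to_numpy(dtype=float)
        finite = arr[~np.isnan(arr)]
        if ((finite < 0) | (finite > 1)).any():
            raise FormatError("beta values outside [0, 1]")
        if not {"gene_symbol", "tss_distance"}.issubset(self.annotation.columns):
            raise FormatError("annotation needs gene_symbol and tss_distance columns")
        missing = [s for s in self.beta.columns if s not in self.tissue.index]
        if missing:
            raise DataError(f"samples without tissue label: {missing}")
        self.tissue = self.tissue.reindex(self.beta.columns)

    @property
    def probes(self) -> list[str]:
        return list(self.beta.index)

    def probes_for_gene(self, gene: str, tss_window_bp: int | None = None) -> list[str]:
        ann = self.annotation[self.annotation["gene_symbol"] == gene]
        if tss_window_bp is not None:
            ann = ann[ann["tss_distance"].abs() <= tss_window_bp]
        return [p for p in ann.index if p in self.beta.index]

    def sample_ids(self, tissue: str) -> list[str]:
        return list(self.tissue.index[self.tissue == tissue])


@dataclass(slots=True)
class SurvivalRecord:
    """One patient's follow-up: time (days), death event flag, covariates."""

    sample_barcode: str
    time: float
    event: bool
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.time >= 0):
            raise FormatError(f"survival time must be >= 0, got {self.time}")
        self.event = bool(self.event)


# ---------------------------------------------------------------------------
# MAF


def read_maf(path) -> tuple[list[MutationRecord], ParseReport]:
    """Parse a tab-separated MAF file into mutation records plus a row report.

    Requires Hugo_Symbol, Variant_Type and Tumor_Sample_Barcode columns
    (case-insensitive); ``#`` comment lines are skipped.  Unrecognized
    Variant_Type strings become OTHER and are counted in the report.
    """
    path = Path(path)
    header: list[str] | None = None
    records: list[MutationRecord] = []
    report = ParseReport()
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = [h.strip().lower() for h in fields]
                missing = _MAF_REQUIRED - set(header)
                if missing:
                    raise FormatError(
                        "MAF header missing required column(s): " + ", ".join(sorted(missing))
                    )
                idx = {name: header.index(name) for name in header}
                i_gene = idx["hugo_symbol"]
                i_type = idx["variant_type"]
                i_samp = idx["tumor_sample_barcode"]
                i_chrom = idx.get("chromosome")
                i_pos = idx.get("start_position")
                i_class = idx.get("variant_classification")
                continue
            report.n_rows += 1
            if len(fields) <= max(i_gene, i_type, i_samp):
                report.n_skipped += 1
                continue
            raw_type = fields[i_type]
            vtype = normalize_variant_type(raw_type)
            if vtype == "OTHER":
                report.n_other += 1
                report.unrecognized[raw_type.strip()] += 1
            pos = None
            if i_pos is not None and len(fields) > i_pos and fields[i_pos].strip():
                try:
                    pos = int(fields[i_pos])
                except ValueError:
                    pos = None
            records.append(
                MutationRecord(
                    gene_symbol=fields[i_gene].strip(),
                    sample_barcode=fields[i_samp].strip(),
                    variant_type=vtype,
                    chrom=fields[i_chrom].strip() if i_chrom is not None and len(fields) > i_chrom else None,
                    position=pos,
                    variant_classification=(
                        fields[i_class].strip() if i_class is not None and len(fields) > i_class else None
                    ),
                )
            )
    if header is None:
        raise FormatError(f"empty MAF file: {path}")
    report.n_records = len(records)
    return records, report


def write_maf(mutations, path) -> None:
    """Write mutation records (list or tidy DataFrame) as a minimal MAF."""
    frame = mutations_to_frame(mutations)
    out = pd.DataFrame(
        {
            "Hugo_Symbol": frame["gene_symbol"],
            "Chromosome": frame["chrom"].fillna(""),
            "Start_Position": frame["position"].map(
                lambda v: "" if v is None or (isinstance(v, float) and math.isnan(v)) else int(v)
            ),
            "Variant_Classification": frame["variant_classification"].fillna(""),
            "Variant_Type": frame["variant_type"],
            "Tumor_Sample_Barcode": frame["sample_barcode"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def mutations_to_frame(mutations) -> pd.DataFrame:
    """Coerce a list of MutationRecord or a tidy DataFrame to the tidy form."""
    if isinstance(mutations, pd.DataFrame):
        missing = set(MUTATION_COLUMNS[:3]) - set(mutations.columns)
        if missing:
            raise DataError(f"mutation frame missing columns: {sorted(missing)}")
        frame = mutations.copy()
        for col in MUTATION_COLUMNS[3:]:
            if col not in frame.columns:
                frame[col] = None
        return frame[MUTATION_COLUMNS]
    rows = [
        (m.gene_symbol, m.sample_barcode, m.variant_type, m.chrom, m.position, m.variant_classification)
        for m in mutations
    ]
    return pd.DataFrame(rows, columns=MUTATION_COLUMNS)


# ---------------------------------------------------------------------------
# Expression / methylation / clinical TSV


def read_expression_tsv(path, tissue_map: Mapping[str, str] | None = None, unit: str = "RSEM") -> ExpressionMatrix:
    """Read a gene x sample expression TSV (first column = gene symbol).

    Tissue labels come from ``tissue_map`` where given; otherwise from the
    TCGA sample-type code embedded in the barcode (01-09 tumor, 10-19 normal).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise FormatError(f"duplicate gene rows in {path}")
    values = df.astype(float)
    values.index.name = None
    values.columns.name = None
    if (values.to_numpy() < 0).any():
        raise FormatError(f"negative expression values in {path}")
    tissue = _tissue_series(list(values.columns), tissue_map)
    return ExpressionMatrix(values=values, tissue=tissue, unit=unit)


def write_expression_tsv(expr: ExpressionMatrix, path) -> None:
    expr.values.rename_axis("gene_symbol").to_csv(path, sep="\t")


def read_methylation_tsv(
    path, annotation_path, tissue_map: Mapping[str, str] | None = None
) -> MethylationTable:
    """Read probe x sample beta TSV plus a probe annotation TSV.

    The annotation file needs columns probe_id, gene_symbol, tss_distance.
    Beta entries may be NA; values outside [0, 1] are a format error.
    """
    beta = pd.read_csv(path, sep="\t", index_col=0).astype(float)
    beta.index.name = None
    beta.columns.name = None
    arr = beta.to_numpy()
    bad = arr[~np.isnan(arr)]
    if ((bad < 0) | (bad > 1)).any():
        raise FormatError(f"beta values outside [0, 1] in {path}")
    ann = pd.read_csv(annotation_path, sep="\t", index_col=0)
    tissue = _tissue_series(list(beta.columns), tissue_map)
    return MethylationTable(beta=beta, annotation=ann, tissue=tissue)


def write_methylation_tsv(meth: MethylationTable, beta_path, annotation_path) -> None:
    meth.beta.rename_axis("probe_id").to_csv(beta_path, sep="\t", na_rep="NA")
    meth.annotation.rename_axis("probe_id").to_csv(annotation_path, sep="\t")


def read_clinical_tsv(path) -> list[SurvivalRecord]:
    """Read clinical TSV with columns sample_barcode, time, event [+ covariates]."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_barcode", "time", "event"}
    if not required.issubset(df.columns):
        raise FormatError(f"clinical file missing columns: {sorted(required - set(df.columns))}")
    extra = [c for c in df.columns if c not in required]
    records = []
    for _, row in df.iterrows():
        try:
            t = float(row["time"])
        except (TypeError, ValueError) as exc:
            raise FormatError(f"non-numeric survival time {row['time']!r}") from exc
        records.append(
            SurvivalRecord(
                sample_barcode=str(row["sample_barcode"]),
                time=t,
                event=bool(int(row["event"])),
                covariates={c: row[c] for c in extra},
            )
        )
    return records


def write_clinical_tsv(records: Iterable[SurvivalRecord], path) -> None:
    rows = []
    for r in records:
        row = {"sample_barcode": r.sample_barcode, "time": r.time, "event": int(r.event)}
        row.update(r.covariates)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def survival_frame(records: Iterable[SurvivalRecord]) -> pd.DataFrame:
    """Tidy DataFrame view of survival records (one row per patient)."""
    rows = []
    for r in records:
        row = {"sample_barcode": r.sample_barcode, "time": r.time, "event": int(r.event)}
        row.update(r.covariates)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Reports


def write_report(results, path, fmt: str | None = None) -> None:
    """Write a result object deterministically: TSV for tables, JSON otherwise.

    JSON output is key-sorted with a fixed float representation so the same
    results always produce byte-identical files.
    """
    path = Path(path)
    if fmt is None:
        fmt = "tsv" if isinstance(results, pd.DataFrame) else "json"
    if fmt == "tsv":
        if not isinstance(results, pd.DataFrame):
            results = pd.DataFrame(results)
        results.to_csv(path, sep="\t", index=False)
    elif fmt == "json":
        with path.open("w") as fh:
            json.dump(_jsonable(results), fh, indent=2, sort_keys=True)
            fh.write("\n")
    else:
        raise DataError(f"unknown report format {fmt!r}")


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, pd.DataFrame):
        return [_jsonable(rec) for rec in obj.to_dict(orient="records")]
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if math.isnan(v) else v
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _jsonable(getattr(obj, k)) for k in obj.__dataclass_fields__}
    return obj
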