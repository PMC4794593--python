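"""Synthetic TCGA-like cohorts with planted, known effects.

Each cohort carries four linked layers for tumor samples (plus normals for
expression and methylation):

* expression — log-normal multiplicative noise around per-gene baselines
  (strictly positive, heavy-tailed like RSEM estimates); an optional shared
  latent factor plants co-expression between chosen genes;
* methylation — Beta-distributed probe beta values parameterized by mean
  and concentration; a planted "silenced" tumor subset gets the target
  gene's promoter beta mean shifted up and its expression knocked down;
* mutations — per-sample Poisson counts with a log-linear rate effect for
  the planted subset, split multinomially into SNP / INS / DEL records;
* survival — exponential baseline hazard with a proportional planted
  hazard ratio for the silenced (low-expression) group and independent
  exponential censoring.

The generator is deterministic: identical config (including seed) yields
identical bundles.  The planted truth travels with the bundle so every
downstream stage has a ground-truth oracle.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io_formats import (
    ExpressionMatrix,
    MethylationTable,
    SurvivalRecord,
    write_clinical_tsv,
    write_expression_tsv,
    write_maf,
    write_methylation_tsv,
)

_DEFAULT_GENES = ("NEIL1", "NEIL2", "NEIL3", "APOBEC3B", "YWHAZ")


@dataclass
class SimConfig:
    """Parameters of one simulated cohort.

    Defaults emulate a mid-sized TCGA cohort: 200 tumors with 30 adjacent
    normals, around 100 somatic exome mutations per tumor of which 90% are
    single-nucleotide, promoter beta centred at 0.2 in normal tissue, and
    0.5 log-scale expression noise.
    """

    cancer_label: str = "SIM01"
    n_tumor: int = 200
    n_normal: int = 30
    genes: tuple[str, ...] = _DEFAULT_GENES
    hk_gene: str = "YWHAZ"
    base_expression: dict[str, float] | None = None
    silenced_gene: str = "NEIL1"
    silenced_fraction: float = 0.0
    silencing_expression_factor: float = 0.2
    silenced_beta_shift: float = 0.4
    normal_beta_mean: float = 0.2
    beta_concentration: float = 20.0
    expression_sigma: float = 0.5
    base_mutation_rate: float = 100.0
    load_coupling: float = 0.0
    snp_fraction: float = 0.9
    hazard_ratio: float = 1.0
    baseline_hazard: float = 1.0 / 1000.0  # per day
    censoring_rate: float = 0.3
    coexpression: dict[str, float] = field(default_factory=dict)
    n_probes: int = 1
    tss_distances: tuple[int, ...] = (100,)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("silenced_fraction", "snp_fraction", "censoring_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for name in ("base_mutation_rate", "hazard_ratio", "baseline_hazard", "beta_concentration"):
            v = getattr(self, name)
            if not v > 0:
                raise ConfigError(f"{name} must be > 0, got {v}")
        if not 0.0 < self.silencing_expression_factor < 1.0:
            raise ConfigError("silencing_expression_factor must be in (0, 1)")
        if not 0.0 < self.silenced_beta_shift <= 1.0:
            raise ConfigError("silenced_beta_shift must be in (0, 1]")
        if not 0.0 < self.normal_beta_mean < 1.0:
            raise ConfigError("normal_beta_mean must be in (0, 1)")
        if self.n_tumor < 1 or self.n_normal < 0:
            raise ConfigError("n_tumor must be >= 1 and n_normal >= 0")
        if self.hk_gene not in self.genes:
            raise ConfigError(f"genes must include the housekeeping symbol {self.hk_gene!r}")
        if self.silenced_gene not in self.genes:
            raise ConfigError(f"genes must include the silenced gene {self.silenced_gene!r}")
        if self.base_expression is None:
            base = {g: 200.0 for g in self.genes}
            base[self.hk_gene] = 2000.0  # housekeeping genes sit high and stable
            self.base_expression = base
        missing = [g for g in self.genes if g not in self.base_expression]
        if missing:
            raise ConfigError(f"base_expression missing genes: {missing}")
        if len(self.tss_distances) != self.n_probes:
            raise ConfigError("tss_distances must list one distance per probe")


@dataclass
class CohortBundle:
    """One simulated cohort: linked expression, mutations, methylation,
    clinical records, plus the planted truth."""

    cancer_label: str
    expression: ExpressionMatrix
    mutations: pd.DataFrame  # tidy records: gene_symbol, sample_barcode, variant_type, ...
    methylation: MethylationTable
    clinical: list[SurvivalRecord]
    truth: dict

    def write_to_dir(self, directory) -> dict[str, Path]:
        """Write every layer in the formats the readers consume."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        paths = {
            "expression": d / "expression.tsv",
            "maf": d / "mutations.maf",
            "beta": d / "methylation.tsv",
            "annotation": d / "probe_annotation.tsv",
            "clinical": d / "clinical.tsv",
        }
        write_expression_tsv(self.expression, paths["expression"])
        write_maf(self.mutations, paths["maf"])
        write_methylation_tsv(self.methylation, paths["beta"], paths["annotation"])
        write_clinical_tsv(self.clinical, paths["clinical"])
        return paths


def _beta_draw(rng, mean: np.ndarray, concentration: float) -> np.ndarray:
    mean = np.clip(mean, 1e-3, 1 - 1e-3)
    return rng.beta(mean * concentration, (1 - mean) * concentration)


def generate_cohort(config: SimConfig) -> CohortBundle:
    """Simulate one cohort under ``config`` (deterministic in the seed)."""
    rng = np.random.default_rng(config.seed)
    lab = config.cancer_label
    tumors = [f"{lab}-T{i:04d}-01A" for i in range(config.n_tumor)]
    normals = [f"{lab}-N{i:04d}-11A" for i in range(config.n_normal)]
    samples = tumors + normals
    n_sil = int(round(config.silenced_fraction * config.n_tumor))
    silenced = sorted(rng.choice(tumors, size=n_sil, replace=False)) if n_sil else []
    sil_mask = np.array([s in set(silenced) for s in tumors])

    # expression: log-normal noise, optional shared latent factor, knockdown
    latent = rng.standard_normal(len(samples))
    values = {}
    for g in config.genes:
        log_e = (
            np.log(config.base_expression[g])
            + config.expression_sigma * rng.standard_normal(len(samples))
            + config.coexpression.get(g, 0.0) * latent
        )
        e = np.exp(log_e)
        if g == config.silenced_gene and n_sil:
            e[:config.n_tumor][sil_mask] *= config.silencing_expression_factor
        values[g] = e
    expr_df = pd.DataFrame(values, index=samples).T
    expr_df = expr_df.loc[list(config.genes)]
    tissue = pd.Series(
        ["tumor"] * len(tumors) + ["normal"] * len(normals), index=samples, name="tissue"
    )
    expression = ExpressionMatrix(values=expr_df, tissue=tissue, unit="RSEM")

    # methylation: n_probes probes per gene
    probe_rows, ann_rows = [], []
    probe_counter = 1
    for g in config.genes:
        for j in range(config.n_probes):
            probe_id = f"cg{probe_counter:08d}"
            probe_counter += 1
            mean = np.full(len(samples), config.normal_beta_mean)
            if g == config.silenced_gene and n_sil:
                mean[:config.n_tumor][sil_mask] += config.silenced_beta_shift
            beta = _beta_draw(rng, mean, config.beta_concentration)
            probe_rows.append(pd.Series(beta, index=samples, name=probe_id))
            ann_rows.append((probe_id, g, config.tss_distances[j]))
    beta_df = pd.DataFrame(probe_rows)
    annotation = pd.DataFrame(
        ann_rows, columns=["probe_id", "gene_symbol", "tss_distance"]
    ).set_index("probe_id")
    methylation = MethylationTable(beta=beta_df, annotation=annotation, tissue=tissue.copy())

    # mutations: Poisson counts with a log-linear planted-group effect
    rates = config.base_mutation_rate * np.exp(config.load_coupling * sil_mask.astype(float))
    counts = rng.poisson(rates)
    p_ins = p_del = (1.0 - config.snp_fraction) / 2.0
    type_counts = np.array(
        [rng.multinomial(c, [config.snp_fraction, p_ins, p_del]) for c in counts]
    )
    sample_col, vtype_col = [], []
    for s, (n_snp, n_ins, n_del) in zip(tumors, type_counts):
        total = n_snp + n_ins + n_del
        sample_col.append(np.repeat(s, total))
        vtype_col.append(np.repeat(["SNP", "INS", "DEL"], [n_snp, n_ins, n_del]))
    sample_arr = np.concatenate(sample_col) if sample_col else np.array([], dtype=object)
    vtype_arr = np.concatenate(vtype_col) if vtype_col else np.array([], dtype=object)
    total_muts = len(sample_arr)
    mutations = pd.DataFrame(
        {
            "gene_symbol": pd.Series(rng.integers(1, 20000, total_muts)).map("G{:05d}".format),
            "sample_barcode": sample_arr,
            "variant_type": vtype_arr,
            "chrom": pd.Series(rng.integers(1, 23, total_muts)).astype(str),
            "position": rng.integers(1, 250_000_000, total_muts),
            "variant_classification": "Missense_Mutation",
        }
    )

    # survival: exponential baseline, proportional planted hazard for the
    # silenced group, independent exponential censoring
    lam = config.baseline_hazard * np.where(sil_mask, config.hazard_ratio, 1.0)
    death = rng.exponential(1.0 / lam)
    if config.censoring_rate > 0:
        lam_c = config.baseline_hazard * config.censoring_rate / (1.0 - config.censoring_rate)
        censor = rng.exponential(1.0 / lam_c, size=config.n_tumor)
    else:
        censor = np.full(config.n_tumor, np.inf)
    time = np.minimum(death, censor)
    event = death <= censor
    ages = np.clip(rng.normal(65.0, 10.0, config.n_tumor), 30.0, 90.0)
    stages = rng.integers(1, 5, config.n_tumor)
    clinical = [
        SurvivalRecord(
            sample_barcode=s,
            time=float(np.round(t, 4)),
            event=bool(ev),
            covariates={"age": float(np.round(a, 1)), "stage": int(st)},
        )
        for s, t, ev, a, st in zip(tumors, time, event, ages, stages)
    ]

    truth = {
        "silenced_gene": config.silenced_gene,
        "silenced_samples": list(silenced),
        "silenced_fraction": config.silenced_fraction,
        "hazard_ratio": config.hazard_ratio,
        "load_coupling": config.load_coupling,
        "group_labels": pd.Series(
            np.where(sil_mask, "abnormal", "other"), index=tumors, name="truth_group"
        ),
    }
    return CohortBundle(
        cancer_label=lab,
        expression=expression,
        mutations=mutations,
        methylation=methylation,
        clinical=clinical,
        truth=truth,
    )


def generate_multi_cancer(
    configs: list[SimConfig],
    trend: float,
    gene: str | None = None,
    trend_scale: float = 0.6,
    cohort_noise: float = 0.2,
    seed: int | None = None,
) -> list[CohortBundle]:
    """Simulate several cohorts with a planted cross-cancer trend.

    Across cohorts, the target gene's expression scale follows a graded
    log-linear gradient and the mutation rate follows ``trend`` times that
    gradient, plus independent per-cohort log-normal jitter
    (``cohort_noise``).  ``trend = 0`` therefore plants independence between
    cohort-level median expression and median mutation load; the sign of a
    nonzero ``trend`` is the sign of the planted monotone relation.
    """
    if len(configs) < 3:
        raise ConfigError("need >= 3 cohorts for a cross-cancer correlation")
    gene = gene or configs[0].silenced_gene
    rng = np.random.default_rng(seed if seed is not None else configs[0].seed + 7919)
    u = np.linspace(-1.0, 1.0, len(configs))
    bundles = []
    for i, cfg in enumerate(configs):
        e_jit, m_jit = rng.standard_normal(2)
        expr_scale = float(np.exp(trend_scale * u[i] + cohort_noise * e_jit))
        rate_scale = float(np.exp(trend * trend_scale * u[i] + cohort_noise * m_jit))
        base = dict(cfg.base_expression)
        base[gene] = base[gene] * expr_scale
        bundles.append(
            generate_cohort(
                dataclasses.replace(
                    cfg,
                    base_expression=base,
                    base_mutation_rate=cfg.base_mutation_rate * rate_scale,
                )
            )
        )
    return bundles


def default_multi_configs(
    n_cohorts: int = 13,
    seed: int = 0,
    n_tumor: int = 200,
    n_normal: int = 30,
    **overrides,
) -> list[SimConfig]:
    """A panel of cohort configs with TCGA-style labels and distinct seeds."""
    return [
        SimConfig(
            cancer_label=f"SIM{i + 1:02d}",
            n_tumor=n_tumor,
            n_normal=n_normal,
            seed=seed * 100_003 + i,
            **overrides,
        )
        for i in range(n_cohorts)
    ]
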