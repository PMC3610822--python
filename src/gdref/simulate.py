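"""Synthetic two-color array datasets and qPCR Ct tables with known truth.

The simulated design mirrors a four-stage, three-replicate time course
hybridized against a shared genomic-DNA reference: the Cy5 channel is
drawn from a gene-independent log-normal gDNA abundance model shared
across arrays, and the Cy3 channel multiplies it by 2^(baseline +
condition effect + noise). An optional smooth intensity-dependent dye
bias is added to the log-ratio as a polynomial in average log intensity,
giving the normalization step a controllable artifact to remove. Pixel
statistics are generated directly (no image simulation).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .probes import CROSSHYB, INTERGENIC, SCAN_COLUMNS, VALID

__all__ = [
    "DEFAULT_CONDITIONS",
    "SimulationConfig",
    "SyntheticTruth",
    "generate_array_dataset",
    "generate_qpcr_dataset",
    "write_dataset",
]

DEFAULT_CONDITIONS = ("MI16", "MII24", "MII48", "MII72")


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 100
    probes_per_gene: int = 3
    frac_crosshyb: float = 0.02
    frac_intergenic: float = 0.15
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    replicates: int = 3
    effect_table: dict = field(default_factory=dict)
    noise_sd: float = 0.2
    dye_bias: tuple[float, ...] = ()
    bg_level: float = 50.0
    bg_sd: float = 5.0
    seed: int = 0
    # extras beyond the core design
    frac_surrogate: float = 0.0   # fraction of intergenic probes driven into the surrogate branch
    array_offset_sd: float = 0.0  # per-array Mg shift, for exercising median normalization
    gdna_log2_mean: float = 10.0
    gdna_log2_sd: float = 1.0
    baseline_log2_mean: float = 2.0
    baseline_log2_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.probes_per_gene <= 0:
            raise ValueError("n_genes and probes_per_gene must be positive")
        if not 0 <= self.frac_crosshyb < 1 or not 0 <= self.frac_intergenic < 1:
            raise ValueError("probe class fractions must lie in [0, 1)")
        if self.frac_crosshyb + self.frac_intergenic >= 1:
            raise ValueError("crosshyb + intergenic fractions must stay below 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.replicates < 2:
            raise ValueError("need at least 2 replicates")
        if len(self.conditions) < 2:
            raise ValueError("need a reference plus at least one test condition")

    @property
    def reference(self) -> str:
        return self.conditions[0]

    def gene_ids(self) -> list[str]:
        width = max(4, len(str(self.n_genes)))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    def array_labels(self) -> list[str]:
        return [
            f"{cond}_r{rep}"
            for cond in self.conditions
            for rep in range(1, self.replicates + 1)
        ]


@dataclass
class SyntheticTruth:
    """Per-gene true log2 effect for every condition (reference = 0)."""

    effects: pd.DataFrame  # genes x conditions
    reference: str

    def __post_init__(self) -> None:
        if not (self.effects[self.reference] == 0).all():
            raise ValueError("reference-condition effects must all be zero")

    def de_flag(self, threshold: float) -> pd.Series:
        return self.effects.abs().max(axis=1) >= threshold


def _truth_from_config(config: SimulationConfig) -> SyntheticTruth:
    genes = config.gene_ids()
    effects = pd.DataFrame(0.0, index=genes, columns=list(config.conditions))
    effects.index.name = "gene_id"
    for gene, per_cond in config.effect_table.items():
        if gene not in effects.index:
            raise ValueError(f"effect_table names unknown gene {gene!r}")
        for cond, value in per_cond.items():
            if cond == config.reference:
                raise ValueError("effects on the reference condition are not allowed")
            if cond not in effects.columns:
                raise ValueError(f"effect_table names unknown condition {cond!r}")
            effects.loc[gene, cond] = float(value)
    return SyntheticTruth(effects, config.reference)


def generate_array_dataset(
    config: SimulationConfig,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, SyntheticTruth]:
    """Simulate one scan table per condition x replicate, plus annotation and truth."""
    rng = np.random.default_rng(config.seed)
    truth = _truth_from_config(config)
    genes = config.gene_ids()

    n_gene_probes = config.n_genes * config.probes_per_gene
    frac_kept = 1.0 - config.frac_intergenic
    n_total = int(round(n_gene_probes / frac_kept))
    n_intergenic = n_total - n_gene_probes
    n_crosshyb = int(round(config.frac_crosshyb * n_total))
    n_crosshyb = min(n_crosshyb, n_gene_probes)

    probe_ids = [f"P{i:06d}" for i in range(1, n_total + 1)]
    probe_gene = np.repeat(genes, config.probes_per_gene)
    classes = np.array([VALID] * n_gene_probes + [INTERGENIC] * n_intergenic)
    # flag a deterministic random subset of gene probes as cross-hybridizing
    if n_crosshyb:
        xh = rng.choice(n_gene_probes, size=n_crosshyb, replace=False)
        classes[xh] = CROSSHYB

    gene_ids_col = []
    for i in range(n_total):
        if i >= n_gene_probes:
            gene_ids_col.append("")
        elif classes[i] == CROSSHYB:
            other = genes[(genes.index(probe_gene[i]) + 1) % len(genes)]
            gene_ids_col.append(f"{probe_gene[i]};{other}")
        else:
            gene_ids_col.append(probe_gene[i])
    annotations = pd.DataFrame(
        {"probe_id": probe_ids, "class": classes, "gene_ids": gene_ids_col}
    )

    # probe-level quantities shared across arrays
    gdna_log2 = rng.normal(config.gdna_log2_mean, config.gdna_log2_sd, n_total)
    gene_baseline = rng.normal(
        config.baseline_log2_mean, config.baseline_log2_sd, config.n_genes
    )
    baseline = np.empty(n_total)
    baseline[:n_gene_probes] = np.repeat(gene_baseline, config.probes_per_gene)
    baseline[n_gene_probes:] = rng.normal(-2.0, 0.5, n_intergenic)

    surrogate_mask = np.zeros(n_total, dtype=bool)
    if config.frac_surrogate > 0 and n_intergenic:
        n_sur = int(round(config.frac_surrogate * n_intergenic))
        if n_sur:
            picks = rng.choice(n_intergenic, size=n_sur, replace=False)
            surrogate_mask[n_gene_probes + picks] = True

    # dye-bias curves must differ between arrays to survive in pairwise
    # log-ratios: each array scales the polynomial by a factor in [-1, 1]
    n_arrays = len(config.conditions) * config.replicates
    bias_factors = iter(np.linspace(-1.0, 1.0, n_arrays))

    gene_index = pd.Index(genes)
    scans: dict[str, pd.DataFrame] = {}
    for cond in config.conditions:
        cond_effect = truth.effects[cond].reindex(gene_index).to_numpy()
        probe_effect = np.zeros(n_total)
        probe_effect[:n_gene_probes] = np.repeat(cond_effect, config.probes_per_gene)
        for rep in range(1, config.replicates + 1):
            label = f"{cond}_r{rep}"
            noise = (
                rng.normal(0.0, config.noise_sd, n_total) if config.noise_sd > 0 else 0.0
            )
            offset = (
                rng.normal(0.0, config.array_offset_sd)
                if config.array_offset_sd > 0
                else 0.0
            )
            mg = baseline + probe_effect + noise + offset
            factor = next(bias_factors)
            if config.dye_bias:
                avg = gdna_log2 + mg / 2.0
                centered = avg - config.gdna_log2_mean
                bias = np.zeros(n_total)
                for power, coeff in enumerate(config.dye_bias):
                    bias += coeff * centered**power
                mg = mg + factor * bias
            cy5 = 2.0**gdna_log2
            cy3 = cy5 * 2.0**mg
            cy3 = np.where(surrogate_mask, 0.1 * config.bg_sd, cy3)
            scans[label] = pd.DataFrame(
                {
                    "ProbeName": probe_ids,
                    "gMeanSignal": cy3 + config.bg_level,
                    "gBGMedianSignal": np.full(n_total, config.bg_level),
                    "gBGPixSDev": np.full(n_total, config.bg_sd),
                    "rMeanSignal": cy5 + config.bg_level,
                    "rBGMedianSignal": np.full(n_total, config.bg_level),
                    "rBGPixSDev": np.full(n_total, config.bg_sd),
                },
                columns=SCAN_COLUMNS,
            )
    return scans, annotations, truth


def generate_qpcr_dataset(
    truth: SyntheticTruth,
    reference_gene: str,
    ct_base: float = 20.0,
    seed: int = 0,
    noise_sd: float = 0.0,
    n_bio: int = 2,
    n_tech: int = 3,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Ct table consistent with the truth: Ct = ct_base - effect + noise."""
    if reference_gene not in truth.effects.index:
        raise ValueError(f"reference gene {reference_gene!r} absent from truth")
    if (truth.effects.loc[reference_gene] != 0).any():
        raise ValueError("reference gene must have zero effect in every condition")
    rng = np.random.default_rng(seed)
    if genes is None:
        genes = list(truth.effects.index)
    if reference_gene not in genes:
        genes = list(genes) + [reference_gene]

    rows = []
    for gene in genes:
        for cond in truth.effects.columns:
            effect = float(truth.effects.loc[gene, cond])
            for bio in range(1, n_bio + 1):
                for tech in range(1, n_tech + 1):
                    noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                    rows.append(
                        {
                            "gene_id": gene,
                            "condition": cond,
                            "bio_rep": bio,
                            "tech_rep": tech,
                            "ct": ct_base - effect + noise,
                        }
                    )
    return pd.DataFrame(rows)


def write_dataset(
    outdir,
    scans: dict[str, pd.DataFrame],
    annotations: pd.DataFrame,
    truth: SyntheticTruth,
    config: SimulationConfig | None = None,
) -> None:
    """Write scans, annotation, truth (and config) as TSV / key=value text."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scan_dir = outdir / "scans"
    scan_dir.mkdir(exist_ok=True)
    for label, scan in scans.items():
        scan.to_csv(scan_dir / f"{label}.tsv", sep="\t", index=False)
    annotations.to_csv(outdir / "annotation.tsv", sep="\t", index=False)
    truth.effects.to_csv(outdir / "truth.tsv", sep="\t")
    if config is not None:
        with open(outdir / "config.txt", "w") as fh:
            for key, value in asdict(config).items():
                if key == "effect_table":
                    continue
                if isinstance(value, tuple):
                    value = ",".join(str(v) for v in value)
                fh.write(f"{key}={value}\n")
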