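"""End-to-end pipeline: scans -> weighted Mg matrix -> normalization ->
gene models -> selection cascade, with a run log of every parameter."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import diffexp, filters, normalize, probes

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "read_config_file"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, labelled with the stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    scan_dir: str
    annotation: str
    out_dir: str
    gene_annotation: str | None = None
    reference_condition: str = "MI16"
    loess_span: float = 0.3
    loess_iterations: int = 3
    loess_degree: int = 1
    alpha: float = 0.05
    sig_abs: float = 1.0
    candidate_abs: float = 2.0
    top_abs: float = 3.0
    conservation_min: float = 75.0
    p_source: str = "raw"  # raw | fdr
    normalize: bool = True
    seed: int = 0

    def loess_config(self) -> normalize.LoessConfig:
        return normalize.LoessConfig(
            span=self.loess_span,
            iterations=self.loess_iterations,
            degree=self.loess_degree,
        )

    def criteria(self) -> filters.FilterCriteria:
        return filters.FilterCriteria(
            alpha=self.alpha,
            sig_abs=self.sig_abs,
            candidate_abs=self.candidate_abs,
            top_abs=self.top_abs,
            conservation_min=self.conservation_min,
        )


_BOOL = {"true": True, "false": False, "1": True, "0": False}


def read_config_file(path) -> PipelineConfig:
    """Parse the flat ``key=value`` pipeline configuration dialect."""
    values: dict[str, object] = {}
    types = {f.name: f.type for f in PipelineConfig.__dataclass_fields__.values()}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if key not in PipelineConfig.__dataclass_fields__:
                raise ValueError(f"unknown configuration key {key!r}")
            t = types[key]
            if "int" in t and "float" not in t:
                values[key] = int(raw)
            elif "float" in t:
                values[key] = float(raw)
            elif "bool" in t:
                values[key] = _BOOL[raw.lower()]
            else:
                values[key] = raw
    return PipelineConfig(**values)  # type: ignore[arg-type]


def _stage(name: str):
    def wrap(func, *args, **kwargs):
        try:
            return func(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - re-labelled with stage name
            raise PipelineError(name, exc) from exc

    return wrap


def run_pipeline(config: PipelineConfig) -> pd.DataFrame:
    """Run every stage and write result TSVs plus ``run.log``; returns results."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        line = f"{time.strftime('%Y-%m-%dT%H:%M:%S')} {msg}"
        log_lines.append(line)
        logger.info(msg)

    for key, value in asdict(config).items():
        log(f"param {key}={value}")

    scan_dir = Path(config.scan_dir)
    if not scan_dir.is_dir():
        raise PipelineError("probe_processing", FileNotFoundError(f"scan dir not found: {scan_dir}"))
    annotation_path = Path(config.annotation)
    if not annotation_path.is_file():
        raise PipelineError(
            "probe_processing", FileNotFoundError(f"annotation file not found: {annotation_path}")
        )

    def load_and_build():
        scans = {
            p.stem: pd.read_csv(p, sep="\t") for p in sorted(scan_dir.glob("*.tsv"))
        }
        if not scans:
            raise FileNotFoundError(f"no scan TSVs in {scan_dir}")
        annotations = pd.read_csv(annotation_path, sep="\t", keep_default_na=False)
        weights = probes.assign_weights(annotations)
        counts = probes.weight_counts(weights)
        log(f"probes valid={counts['valid']} downweighted={counts['invalid']}")
        return probes.build_matrix(scans, annotations, weights), annotations

    matrix, annotations = _stage("probe_processing")(load_and_build)

    if config.normalize:
        def do_normalize():
            norm = normalize.cyclic_loess_normalize(matrix, config.loess_config())
            return normalize.median_normalize(norm)

        matrix = _stage("normalization")(do_normalize)
        matrix.to_tsv(out_dir / "normalized.tsv")
        log("normalization applied (cyclic loess + median)")
    else:
        log("normalization skipped by configuration")

    def do_diffexp():
        genes = diffexp.summarize_genes(matrix, annotations)
        design = diffexp.DesignInfo.from_labels(
            genes.values.columns, reference=config.reference_condition
        )
        fit = diffexp.fit_gene_model(genes, design)
        return diffexp.moderate_statistics(fit)

    result = _stage("diffexp")(do_diffexp)
    results_path = out_dir / "results.tsv"
    result.table.to_csv(results_path, sep="\t")
    log(
        f"diffexp genes={len(result.table)} df_prior={result.df_prior:.4g} "
        f"s0={result.s0:.4g}"
    )

    def do_filters():
        criteria = config.criteria()
        reliable = filters.select_reliable(result.table, criteria, config.p_source)
        log(f"filter reliable alpha={criteria.alpha} p_source={config.p_source} "
            f"kept={len(reliable)}")
        mc_cols = [c for c in result.table.columns if c.startswith("Mc_")]
        table = result.table[mc_cols].copy()
        table.columns = filters.MC_COLUMNS[: len(mc_cols)]

        report = pd.DataFrame(index=result.table.index)
        report.index.name = "gene_id"
        report["reliable"] = report.index.isin(reliable)
        if config.gene_annotation:
            gene_ann = pd.read_csv(config.gene_annotation, sep="\t", index_col="gene_id")
            candidates = filters.candidate_filter(table, gene_ann, criteria)
            report["candidate"] = report.index.isin(candidates)
            log(f"filter candidate abs>={criteria.candidate_abs} "
                f"conservation>{criteria.conservation_min} kept={len(candidates)}")
        top = filters.top_filter(table, criteria)
        report["top"] = report.index.isin(top)
        log(f"filter top abs>={criteria.top_abs} kept={len(top)}")
        for col in table.columns:
            suffix = col.removeprefix("mc_")
            fc = table[col].map(lambda v: filters.fold_change(v, criteria.sig_abs))
            report[f"direction_{suffix}"] = [f.direction for f in fc]
            report[f"fold_{suffix}"] = [filters.round_fold(f.magnitude) for f in fc]
        return report

    report = _stage("filters")(do_filters)
    report_path = out_dir / "filter_report.tsv"
    with open(report_path, "w") as fh:
        crit = config.criteria()
        fh.write(
            f"# alpha={crit.alpha} sig_abs={crit.sig_abs} "
            f"candidate_abs={crit.candidate_abs} top_abs={crit.top_abs} "
            f"conservation_min={crit.conservation_min} p_source={config.p_source}\n"
        )
        report.to_csv(fh, sep="\t")
    log(f"seed {config.seed}")

    with open(out_dir / "run.log", "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return result.table
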