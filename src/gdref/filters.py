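"""Gene-selection cascade and derived summaries.

Implements the conservative multi-contrast reliability filter, fold-change
conversion with the mixed rounding convention used for reporting, the
unknown-function candidate cascade (conservation + divergence tiers),
sign-consistency across the later stages, and transcript-protein
concordance classes.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "FilterCriteria",
    "FoldChange",
    "select_reliable",
    "fold_change",
    "round_fold",
    "max_fold_change",
    "candidate_filter",
    "top_filter",
    "mii_consistency",
    "proteome_concordance",
    "category_summary",
]

logger = logging.getLogger(__name__)

UP_MII = "up-in-MII"
UP_MI = "up-in-MI"
FLAT = "flat"

MC_COLUMNS = ["mc_24", "mc_48", "mc_72"]


@dataclass(frozen=True)
class FilterCriteria:
    alpha: float = 0.05
    sig_abs: float = 1.0
    candidate_abs: float = 2.0
    top_abs: float = 3.0
    conservation_min: float = 75.0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not self.sig_abs <= self.candidate_abs <= self.top_abs:
            raise ValueError("need sig_abs <= candidate_abs <= top_abs")
        if not 0 <= self.conservation_min <= 100:
            raise ValueError("conservation_min must be a percentage")


class FoldChange(NamedTuple):
    direction: str
    magnitude: float


def _mc_columns(table: pd.DataFrame) -> list[str]:
    cols = [c for c in MC_COLUMNS if c in table.columns]
    if not cols:
        cols = [c for c in table.columns if c.startswith("mc_")]
    if not cols:
        raise ValueError("no mc_* abundance columns in table")
    return cols


def _p_columns(results: pd.DataFrame, source: str) -> list[str]:
    prefix = {"raw": "p_", "fdr": "fdr_"}[source]
    return [c for c in results.columns if c.startswith(prefix)]


def select_reliable(
    results: pd.DataFrame,
    criteria: FilterCriteria | None = None,
    p_source: str = "raw",
) -> list[str]:
    """Keep genes significant (p < alpha) in every contrast.

    ``results`` is a moderated-statistics table indexed by gene with
    ``p_*`` (and optionally ``fdr_*``) columns; ``p_source`` picks which
    feeds the filter.
    """
    criteria = criteria or FilterCriteria()
    cols = _p_columns(results, p_source)
    if not cols:
        raise ValueError(f"no {p_source!r} p-value columns in results")
    block = results[cols]
    bad = block.index[block.isna().any(axis=1)].tolist()
    if bad:
        raise ValueError(f"missing contrast p-values for genes: {bad[:10]}")
    keep = (block < criteria.alpha).all(axis=1)
    return block.index[keep].tolist()


def fold_change(
    mc: float, sig_abs: float = 1.0, rounding: str | None = None
) -> FoldChange:
    """Direction and linear fold magnitude of one log2 abundance value."""
    if not math.isfinite(mc):
        raise ValueError("mc must be finite")
    magnitude = 2.0 ** abs(mc)
    if rounding is not None:
        magnitude = round_fold(magnitude, rounding)
    if abs(mc) < sig_abs:
        direction = FLAT
    elif mc > 0:
        direction = UP_MII
    else:
        direction = UP_MI
    return FoldChange(direction, magnitude)


def round_fold(magnitude: float, mode: str = "auto") -> float:
    """Mixed reporting precision: integers from 5-fold up, one decimal below."""
    if mode == "integer":
        return float(round(magnitude))
    if mode == "decimal":
        return round(magnitude, 1)
    if mode == "auto":
        return float(round(magnitude)) if magnitude >= 5 else round(magnitude, 1)
    raise ValueError(f"unknown rounding mode {mode!r}")


def max_fold_change(
    genes, table: pd.DataFrame, rounding: str = "auto"
) -> float:
    """Largest linear fold change over the listed genes and all time points."""
    genes = list(genes)
    missing = [g for g in genes if g not in table.index]
    if missing:
        raise KeyError(f"genes absent from table: {missing}")
    mc = table.loc[genes, MC_COLUMNS].to_numpy(dtype=float)
    magnitude = float(2.0 ** np.abs(mc).max())
    return round_fold(magnitude, rounding)


def candidate_filter(
    table: pd.DataFrame,
    annotations: pd.DataFrame,
    criteria: FilterCriteria | None = None,
) -> list[str]:
    """Unknown-function genes, conserved in the genus, diverging >= 4-fold.

    ``annotations`` must be indexed by gene with boolean ``known_function``
    and numeric ``conservation`` columns covering every gene in ``table``.
    """
    criteria = criteria or FilterCriteria()
    uncovered = [g for g in table.index if g not in annotations.index]
    if uncovered:
        raise KeyError(f"annotations missing for genes: {uncovered[:10]}")
    ann = annotations.loc[table.index]
    max_abs = table[_mc_columns(table)].abs().max(axis=1)
    keep = (
        ~ann["known_function"].astype(bool)
        & (ann["conservation"] > criteria.conservation_min)
        & (max_abs >= criteria.candidate_abs)
    )
    return table.index[keep].tolist()


def top_filter(table: pd.DataFrame, criteria: FilterCriteria | None = None) -> list[str]:
    """Genes whose largest |log2 abundance| reaches the top tier threshold.

    The comparison is >= on the (one-decimal) printed values: a printed
    maximum of exactly 3.0 is a member of the >8-fold tier.
    """
    criteria = criteria or FilterCriteria()
    max_abs = table[_mc_columns(table)].abs().max(axis=1)
    return table.index[max_abs >= criteria.top_abs].tolist()


def mii_consistency(table: pd.DataFrame) -> float:
    """Fraction of genes with one sign across all three MII contrasts.

    Zeros are neutral: a gene counts as consistent when its non-zero
    values share a sign (or when all values are zero).
    """
    if table.empty:
        raise ValueError("empty table")
    mc = table[MC_COLUMNS].to_numpy(dtype=float)
    if np.isnan(mc).any():
        raise ValueError("missing contrast values")
    pos = (mc > 0).any(axis=1)
    neg = (mc < 0).any(axis=1)
    consistent = ~(pos & neg)
    return float(consistent.mean())


def proteome_concordance(
    transcript_mc: pd.Series, protein_ratio: pd.Series, sig_abs: float = 1.0
) -> tuple[pd.Series, dict[str, int]]:
    """Classify genes by agreement of transcript and protein log2 ratios.

    Both flat -> ``no-variation``; same non-flat direction -> ``similar``;
    anything else -> ``different``. Returns per-gene classes and counts.
    """
    genes = transcript_mc.index
    missing = genes.difference(protein_ratio.index).tolist()
    if missing:
        raise KeyError(f"protein ratios missing for genes: {missing[:10]}")
    protein = protein_ratio.loc[genes]

    def _cls(v: float) -> int:
        if v >= sig_abs:
            return 1
        if v <= -sig_abs:
            return -1
        return 0

    t = transcript_mc.map(_cls)
    p = protein.map(_cls)
    labels = np.where(
        (t == 0) & (p == 0),
        "no-variation",
        np.where((t == p) & (t != 0), "similar", "different"),
    )
    classes = pd.Series(labels, index=genes, name="class")
    return classes, dict(Counter(classes))


def category_summary(
    table: pd.DataFrame, annotations: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Partition the per-gene Mc triplets into functional categories.

    Genes absent from ``annotations`` (indexed by gene, with a
    ``category`` column) fall into ``"unknown"`` with a warning. Within a
    category, rows are ordered by the 72 h value for plotting.
    """
    if table.empty:
        return {}
    categories = {}
    for gene in table.index:
        if gene in annotations.index:
            categories[gene] = str(annotations.loc[gene, "category"])
        else:
            logger.warning("gene %s has no category annotation; using 'unknown'", gene)
            categories[gene] = "unknown"
    cat = pd.Series(categories)
    out = {}
    for name, block in table[MC_COLUMNS].groupby(cat):
        out[name] = block.sort_values("mc_72", ascending=False)
    return out
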