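"""Packaged reference tables: printed per-gene log2 abundance triplets.

Four small fixtures ship with the package: the qRT-PCR primer table, the
well-characterized genes with the greatest MI/MII differences, the
conserved unknown-function top tier, and the putative secondary-metabolite
cluster genes. Abundance tables are indexed by gene with ``mc_24``,
``mc_48``, ``mc_72`` columns holding the printed one-decimal values.
"""

from __future__ import annotations

from importlib import resources
from typing import NamedTuple

import pandas as pd

__all__ = ["PaperTables", "load_paper_tables"]


class PaperTables(NamedTuple):
    primers: pd.DataFrame        # 12 primers targeting 6 genes
    characterized: pd.DataFrame  # well-characterized genes (abundance triplets)
    unknown_top: pd.DataFrame    # conserved unknown-function top tier (53 genes)
    secondary: pd.DataFrame      # putative secondary-metabolite clusters


def _read(name: str, index_col: str | None = None) -> pd.DataFrame:
    ref = resources.files("gdref.data").joinpath(name)
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    if index_col:
        df = df.set_index(index_col)
    return df


def load_paper_tables() -> PaperTables:
    """Load the packaged printed tables."""
    return PaperTables(
        primers=_read("table1_primers.tsv"),
        characterized=_read("table2_characterized.tsv", index_col="gene_id"),
        unknown_top=_read("table3_unknown.tsv", index_col="gene_id"),
        secondary=_read("table4_secondary.tsv", index_col="gene_id"),
    )
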