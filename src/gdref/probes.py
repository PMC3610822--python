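"""Probe-level processing: background correction, log-ratios, validity weights.

Raw per-probe pixel statistics (foreground mean, background median,
background pixel SD for each channel) are converted into a weighted
probes-by-arrays matrix of ``Mg`` values — the log2 ratio of the Cy3
sample-cDNA channel over the Cy5 genomic-DNA reference channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VALID",
    "CROSSHYB",
    "INTERGENIC",
    "INVALID_WEIGHT",
    "SCAN_COLUMNS",
    "ExpressionMatrix",
    "correct_background",
    "compute_mg",
    "assign_weights",
    "build_matrix",
]

#: annotation class labels
VALID = "valid"
CROSSHYB = "crosshyb"
INTERGENIC = "intergenic"

#: weight given to cross-hybridizing / intergenic probes
INVALID_WEIGHT = 1e-6

#: FeatureExtraction-style scan columns (g = Cy3 cDNA, r = Cy5 gDNA)
SCAN_COLUMNS = [
    "ProbeName",
    "gMeanSignal",
    "gBGMedianSignal",
    "gBGPixSDev",
    "rMeanSignal",
    "rBGMedianSignal",
    "rBGPixSDev",
]


@dataclass
class ExpressionMatrix:
    """Probe- or gene-level log2 abundance matrix with aligned row weights.

    Parameters
    ----------
    values
        Rows are probes (or genes), columns are array labels.
    weights
        One positive weight per row, index-aligned with ``values``.
    """

    values: pd.DataFrame
    weights: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.weights is None:
            self.weights = pd.Series(1.0, index=self.values.index)
        self.weights = self.weights.reindex(self.values.index)
        if self.weights.isna().any():
            missing = self.weights.index[self.weights.isna()].tolist()
            raise ValueError(f"weights missing for rows: {missing[:10]}")
        if (self.weights <= 0).any():
            raise ValueError("row weights must be strictly positive")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing cells")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_arrays(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.weights.copy())

    # -- round-trippable TSV dialect -------------------------------------
    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.insert(0, "weight", self.weights)
        out.to_csv(path, sep="\t", index_label=self.values.index.name or "id")

    @classmethod
    def read_tsv(cls, path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.index.name == "id":
            df.index.name = None
        weights = df.pop("weight")
        return cls(df, weights)


def correct_background(fg_mean, bg_median, bg_pixel_sd):
    """Net intensity with the surrogate rule.

    Returns ``fg_mean - bg_median`` when that difference exceeds the
    background pixel SD; otherwise the background pixel SD itself stands
    in as a surrogate intensity, keeping the result strictly positive.
    Accepts scalars or aligned arrays.
    """
    fg_mean = np.asarray(fg_mean, dtype=float)
    bg_median = np.asarray(bg_median, dtype=float)
    bg_pixel_sd = np.asarray(bg_pixel_sd, dtype=float)
    if np.any(bg_pixel_sd <= 0):
        raise ValueError("bg_pixel_sd must be strictly positive")
    diff = fg_mean - bg_median
    net = np.where(diff > bg_pixel_sd, diff, bg_pixel_sd)
    if net.ndim == 0:
        return float(net)
    return net


def compute_mg(cy3_net, cy5_net):
    """log2 of the Cy3 (cDNA) intensity over the Cy5 (gDNA) intensity."""
    cy3_net = np.asarray(cy3_net, dtype=float)
    cy5_net = np.asarray(cy5_net, dtype=float)
    if np.any(cy3_net <= 0) or np.any(cy5_net <= 0):
        raise ValueError("net intensities must be strictly positive")
    mg = np.log2(cy3_net / cy5_net)
    if mg.ndim == 0:
        return float(mg)
    return mg


def assign_weights(annotations: pd.DataFrame) -> pd.Series:
    """Map each probe to its validity weight.

    Cross-hybridizing and intergenic probes get ``INVALID_WEIGHT``; all
    other probes get weight 1. Input must have columns ``probe_id`` and
    ``class``; each probe must appear exactly once.
    """
    if annotations.empty:
        return pd.Series(dtype=float, name="weight")
    probes = annotations["probe_id"]
    if probes.duplicated().any():
        dups = probes[probes.duplicated()].tolist()
        raise ValueError(f"duplicate probes in annotation table: {dups[:10]}")
    invalid = annotations["class"].isin([CROSSHYB, INTERGENIC]).to_numpy()
    weights = pd.Series(
        np.where(invalid, INVALID_WEIGHT, 1.0), index=probes.to_numpy(), name="weight"
    )
    weights.index.name = "probe_id"
    return weights


def weight_counts(weights: pd.Series) -> dict:
    """Bookkeeping: how many probes are valid (weight 1) vs down-weighted."""
    valid = int((weights == 1.0).sum())
    return {"valid": valid, "invalid": int(len(weights) - valid), "total": int(len(weights))}


def build_matrix(
    scans: dict[str, pd.DataFrame],
    annotations: pd.DataFrame,
    weights: pd.Series | None = None,
) -> ExpressionMatrix:
    """Assemble the probes-by-arrays Mg matrix from raw scan tables.

    ``scans`` maps array label to a FeatureExtraction-style table (see
    ``SCAN_COLUMNS``). All arrays must share an identical probe set.
    """
    if not scans:
        raise ValueError("no scans supplied")
    if weights is None:
        weights = assign_weights(annotations)

    labels = list(scans)
    ref_probes = pd.Index(scans[labels[0]]["ProbeName"])
    for label in labels[1:]:
        probes = pd.Index(scans[label]["ProbeName"])
        if not ref_probes.sort_values().equals(probes.sort_values()):
            offending = ref_probes.symmetric_difference(probes).tolist()
            raise ValueError(
                f"probe sets differ between arrays {labels[0]!r} and {label!r}: "
                f"{offending[:10]}"
            )

    columns = {}
    for label in labels:
        scan = scans[label].set_index("ProbeName").loc[ref_probes]
        cy3 = correct_background(
            scan["gMeanSignal"], scan["gBGMedianSignal"], scan["gBGPixSDev"]
        )
        cy5 = correct_background(
            scan["rMeanSignal"], scan["rBGMedianSignal"], scan["rBGPixSDev"]
        )
        columns[label] = compute_mg(cy3, cy5)
    values = pd.DataFrame(columns, index=ref_probes)
    values.index.name = "probe_id"
    return ExpressionMatrix(values, weights.reindex(ref_probes))
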