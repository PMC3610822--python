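"""Gene summarization, per-gene linear models, moderated statistics, FDR.

Genes are the unit of testing: valid probes of the same gene are averaged
(with the 1 / 1e-6 validity weights) before a one-way group-means model is
fitted per gene. Contrasts are each non-reference condition minus the
reference. Residual variances are shrunk toward a common prior estimated
by method of moments on the log variances, giving moderated t-statistics
with augmented degrees of freedom.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .probes import INTERGENIC, ExpressionMatrix

__all__ = [
    "DesignInfo",
    "GeneFit",
    "ContrastResult",
    "summarize_genes",
    "fit_gene_model",
    "moderate_statistics",
    "adjust_fdr",
]

logger = logging.getLogger(__name__)

_MAX_DF_PRIOR = 1e6


@dataclass(frozen=True)
class DesignInfo:
    """Array label -> (condition, replicate index), plus the reference."""

    assignments: dict[str, tuple[str, int]]
    reference: str = "MI16"

    def __post_init__(self) -> None:
        conditions = self.condition_map()
        counts = pd.Series(list(conditions.values())).value_counts()
        if self.reference not in counts.index:
            raise ValueError(f"reference condition {self.reference!r} has no arrays")
        few = counts[counts < 2]
        if not few.empty:
            raise ValueError(
                f"conditions with fewer than 2 replicates: {few.index.tolist()}"
            )

    @classmethod
    def from_labels(cls, labels, reference: str = "MI16") -> "DesignInfo":
        """Parse labels of the form ``<condition>_r<replicate>``."""
        assignments = {}
        for label in labels:
            cond, _, rep = label.rpartition("_r")
            if not cond or not rep.isdigit():
                raise ValueError(f"cannot parse condition from array label {label!r}")
            assignments[label] = (cond, int(rep))
        return cls(assignments, reference)

    def condition_map(self) -> dict[str, str]:
        return {label: cond for label, (cond, _) in self.assignments.items()}

    def conditions(self) -> list[str]:
        seen: list[str] = []
        for cond, _ in self.assignments.values():
            if cond not in seen:
                seen.append(cond)
        return seen

    def contrasts(self) -> list[str]:
        return [c for c in self.conditions() if c != self.reference]


def contrast_suffix(condition: str) -> str:
    """Short column suffix for a contrast condition (``MII24`` -> ``24``)."""
    digits = "".join(ch for ch in condition if ch.isdigit())
    return digits if digits else condition


@dataclass
class GeneFit:
    """One-way OLS fits for all genes at once."""

    coef: pd.DataFrame          # genes x conditions: per-condition means
    mc: pd.DataFrame            # genes x contrasts: condition mean - reference mean
    sigma2: pd.Series           # residual variance per gene
    df_resid: float
    n_per_condition: pd.Series  # arrays per condition
    reference: str


@dataclass
class ContrastResult:
    """Moderated contrast statistics, plus the moderation hyperparameters."""

    table: pd.DataFrame
    df_prior: float
    s0: float
    df_resid: float
    contrasts: list[str] = field(default_factory=list)


def summarize_genes(
    matrix: ExpressionMatrix, annotations: pd.DataFrame
) -> ExpressionMatrix:
    """Weighted per-gene average of probe Mg values.

    Cross-hybridizing probes keep their first listed gene for bookkeeping
    but contribute only their 1e-6 weight; intergenic probes map to no
    gene. Genes whose probes are all down-weighted are dropped (logged).
    """
    ann = annotations.set_index("probe_id")
    ann = ann.loc[matrix.values.index]

    gene_of = {}
    for probe, row in ann.iterrows():
        if row["class"] == INTERGENIC:
            continue
        genes = str(row["gene_ids"]).split(";")
        gene_of[probe] = genes[0]

    probe_idx = [p for p in matrix.values.index if p in gene_of]
    genes = pd.Series({p: gene_of[p] for p in probe_idx})
    vals = matrix.values.loc[probe_idx]
    w = matrix.weights.loc[probe_idx]

    wsum = w.groupby(genes).sum()
    weighted = vals.mul(w, axis=0).groupby(genes).sum().div(wsum, axis=0)

    # a gene is kept only if at least one of its probes carries full weight
    has_valid = (
        pd.Series(w.to_numpy() == 1.0, index=w.index).groupby(genes).any()
    )
    dropped = has_valid.index[~has_valid].tolist()
    if dropped:
        logger.warning(
            "dropping %d genes with no valid probes: %s%s",
            len(dropped),
            dropped[:10],
            "..." if len(dropped) > 10 else "",
        )
    kept = weighted.loc[has_valid[has_valid].index]
    kept.index.name = "gene_id"
    return ExpressionMatrix(kept.sort_index(), pd.Series(1.0, index=kept.sort_index().index))


def fit_gene_model(matrix: ExpressionMatrix, design: DesignInfo) -> GeneFit:
    """Ordinary least squares with one coefficient per condition."""
    cond_map = design.condition_map()
    missing = [c for c in matrix.values.columns if c not in cond_map]
    if missing:
        raise ValueError(f"design does not cover arrays: {missing}")
    cond = pd.Series({c: cond_map[c] for c in matrix.values.columns})

    means = matrix.values.T.groupby(cond).mean().T
    counts = cond.value_counts()
    n_arrays = matrix.n_arrays
    n_conditions = len(counts)
    df_resid = n_arrays - n_conditions
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")

    fitted = means[cond.to_numpy()]
    fitted.columns = matrix.values.columns
    resid = matrix.values - fitted
    sigma2 = (resid**2).sum(axis=1) / df_resid

    contrasts = design.contrasts()
    mc = means[contrasts].sub(means[design.reference], axis=0)
    return GeneFit(
        coef=means,
        mc=mc,
        sigma2=sigma2,
        df_resid=float(df_resid),
        n_per_condition=counts,
        reference=design.reference,
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def estimate_prior(sigma2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of (df_prior, s0^2) on log residual variances.

    Matches the scaled-F moments of the classical empirical-Bayes
    treatment: the mean of the corrected log variances estimates log s0^2
    and their excess variance over trigamma(df/2) estimates the prior df.
    """
    positive = sigma2[sigma2 > 0]
    if len(positive) == 0:
        return np.inf, 0.0
    z = np.log(positive)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    if len(e) < 2:
        return _MAX_DF_PRIOR, float(np.exp(emean))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        df_prior = _MAX_DF_PRIOR
        s0_sq = float(np.exp(emean))
    else:
        df_prior = 2.0 * _trigamma_inverse(evar)
        df_prior = min(df_prior, _MAX_DF_PRIOR)
        s0_sq = float(
            np.exp(emean + special.digamma(df_prior / 2.0) - np.log(df_prior / 2.0))
        )
    return df_prior, s0_sq


def moderate_statistics(
    fit: GeneFit,
    df_prior: float | None = None,
    s0_sq: float | None = None,
    min_genes: int = 10,
) -> ContrastResult:
    """Empirical-Bayes moderated t statistics for every contrast.

    ``df_prior`` / ``s0_sq`` may be forced (e.g. 0 to recover ordinary t);
    by default they are estimated from the spread of residual variances.
    """
    sigma2 = fit.sigma2.to_numpy()
    n_genes = len(sigma2)
    if df_prior is None:
        if n_genes < min_genes:
            raise ValueError(
                f"need >= {min_genes} genes to estimate moderation hyperparameters"
            )
        if np.all(sigma2 == 0):
            warnings.warn(
                "all residual variances are zero; falling back to ordinary t",
                RuntimeWarning,
                stacklevel=2,
            )
            df_prior, s0_sq = 0.0, 0.0
        else:
            df_prior, s0_sq = estimate_prior(sigma2, fit.df_resid)
    if s0_sq is None:
        s0_sq = 0.0

    d = fit.df_resid
    if np.isinf(df_prior) or df_prior >= _MAX_DF_PRIOR:
        df_prior = _MAX_DF_PRIOR
    if df_prior > 0:
        s2_post = (df_prior * s0_sq + d * sigma2) / (df_prior + d)
    else:
        s2_post = sigma2.copy()
    df_total = min(d + df_prior, _MAX_DF_PRIOR)

    n_ref = fit.n_per_condition[fit.reference]
    table = pd.DataFrame(index=fit.mc.index)
    table.index.name = "gene_id"
    contrasts = list(fit.mc.columns)
    suffixes = [contrast_suffix(c) for c in contrasts]

    for cond, suf in zip(contrasts, suffixes):
        table[f"Mc_{suf}"] = fit.mc[cond]
    for cond, suf in zip(contrasts, suffixes):
        v_c = 1.0 / fit.n_per_condition[cond] + 1.0 / n_ref
        se = np.sqrt(s2_post * v_c)
        mc = fit.mc[cond].to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, mc / se, np.where(mc == 0, 0.0, np.inf * np.sign(mc)))
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
        table[f"t_{suf}"] = t
        table[f"p_{suf}"] = p
    for suf in suffixes:
        table[f"fdr_{suf}"] = adjust_fdr(table[f"p_{suf}"].to_numpy())

    # interleave to the published column order: Mc_*, t_*, p_*, fdr_*
    cols = (
        [f"Mc_{s}" for s in suffixes]
        + [f"t_{s}" for s in suffixes]
        + [f"p_{s}" for s in suffixes]
        + [f"fdr_{s}" for s in suffixes]
    )
    return ContrastResult(
        table=table[cols],
        df_prior=float(df_prior),
        s0=float(np.sqrt(s0_sq)),
        df_resid=d,
        contrasts=suffixes,
    )


def adjust_fdr(p_raw) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment with monotonicity enforcement."""
    p = np.asarray(p_raw, dtype=float)
    if p.ndim != 1:
        raise ValueError("p-values must be one-dimensional")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out
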