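"""Relative quantification by the ddCt method and array/qPCR concordance.

Technical replicate wells are averaged within each biological replicate
first; biological replicates are then averaged, and the dispersion
reported is the SD of the per-biological-replicate dCt values. The
amplification efficiency is fixed at 2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["delta_delta_ct", "platform_concordance"]

CT_COLUMNS = ["gene_id", "condition", "bio_rep", "tech_rep", "ct"]


def _bio_means(table: pd.DataFrame, gene: str) -> pd.DataFrame:
    sub = table[table["gene_id"] == gene]
    if sub.empty:
        raise ValueError(f"gene {gene!r} absent from Ct table")
    # technical wells first, then one mean Ct per (condition, bio_rep)
    return sub.groupby(["condition", "bio_rep"])["ct"].mean().unstack("condition")


def delta_delta_ct(
    table: pd.DataFrame,
    target: str,
    reference: str,
    calibrator_condition: str,
) -> pd.DataFrame:
    """Per-condition relative expression of ``target`` vs the reference gene.

    dCt(cond) = mean Ct_target(cond) - mean Ct_reference(cond);
    ddCt = dCt(cond) - dCt(calibrator); relative expression = 2^(-ddCt).
    Returns one row per condition with ``delta_ct``, ``delta_delta_ct``,
    ``rel_expr``, ``log2_rel_expr`` and ``dispersion`` columns.
    """
    target_ct = _bio_means(table, target)
    ref_ct = _bio_means(table, reference)

    conditions = list(target_ct.columns)
    missing_ref = [c for c in conditions if c not in ref_ct.columns]
    if missing_ref:
        raise ValueError(
            f"reference gene {reference!r} not measured in conditions: {missing_ref}"
        )
    if calibrator_condition not in conditions:
        raise ValueError(
            f"calibrator condition {calibrator_condition!r} not measured for {target!r}"
        )

    # per-biological-replicate dCt where reps pair up; means otherwise
    dct_bio = target_ct - ref_ct[conditions]
    dct = pd.Series(
        {c: target_ct[c].mean() - ref_ct[c].mean() for c in conditions}
    )
    ddct = dct - dct[calibrator_condition]
    dispersion = dct_bio.std(ddof=1)

    out = pd.DataFrame(
        {
            "gene_id": target,
            "condition": conditions,
            "delta_ct": dct.to_numpy(),
            "delta_delta_ct": ddct.to_numpy(),
            "rel_expr": 2.0 ** (-ddct.to_numpy()),
            "log2_rel_expr": -ddct.to_numpy(),
            "dispersion": dispersion.reindex(conditions).to_numpy(),
        }
    )
    return out


def platform_concordance(array_mc, qpcr_log2) -> tuple[float, float, float]:
    """Least-squares line of qPCR log2 values on array Mc values.

    Returns (slope, intercept, correlation). Requires >= 3 paired points.
    """
    x = np.asarray(array_mc, dtype=float)
    y = np.asarray(qpcr_log2, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired vectors must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 paired points")
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue)
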