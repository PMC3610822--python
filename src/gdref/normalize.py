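"""Between-array normalization: weighted cyclic loess, then median scaling.

The loess here is a plain locally-weighted polynomial regression with
tricube distance weights multiplied by the per-probe validity weights, so
down-weighted (cross-hybridizing / intergenic) probes have essentially no
influence on the fitted trends.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .probes import ExpressionMatrix

__all__ = [
    "LoessConfig",
    "loess_fit",
    "cyclic_loess_normalize",
    "median_normalize",
    "weighted_median",
]

# above this many points the loess is evaluated on an anchor grid and
# interpolated; below it every point gets its own local fit
_EXACT_LIMIT = 2000
_N_ANCHORS = 200


@dataclass(frozen=True)
class LoessConfig:
    span: float = 0.3
    iterations: int = 3
    degree: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.span <= 1:
            raise ValueError("span must be in (0, 1]")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.degree < 0:
            raise ValueError("degree must be >= 0")


def _local_fit(x0, xw, yw, ww, degree):
    """Weighted polynomial fit over one window, evaluated at x0."""
    d = np.abs(xw - x0)
    h = d.max()
    if h <= 0:
        return float(np.average(yw, weights=ww))
    tri = (1.0 - (d / h) ** 3) ** 3
    w = tri * ww
    sw = w.sum()
    if sw <= 0:
        # all tricube weight on the window edge; fall back to probe weights
        w = ww
        sw = w.sum()
    if degree == 0:
        return float((w @ yw) / sw)
    xc = xw - x0
    if degree == 1:
        # closed-form WLS intercept at x0
        swx = w @ xc
        swy = w @ yw
        swxx = w @ (xc * xc)
        swxy = w @ (xc * yw)
        denom = sw * swxx - swx * swx
        if denom <= 1e-12 * sw * swxx or swxx == 0:
            return float(swy / sw)
        return float((swxx * swy - swx * swxy) / denom)
    # higher degrees: Vandermonde WLS; tiny systems, solved directly
    X = np.vander(xc, degree + 1, increasing=True)
    Xw = X * w[:, None]
    beta, *_ = np.linalg.lstsq(Xw.T @ X, Xw.T @ yw, rcond=None)
    return float(beta[0])


def _window_starts(targets, xs, k):
    """Start index of the k-nearest-neighbour window for each sorted target."""
    n = len(xs)
    starts = np.empty(len(targets), dtype=np.intp)
    lo = 0
    for i, x0 in enumerate(targets):
        # slide the window [lo, lo+k) to the k nearest neighbours of x0
        while lo + k < n and x0 - xs[lo] > xs[lo + k] - x0:
            lo += 1
        starts[i] = lo
    return starts


def _fit_at_targets(targets, xs, ys, ws, k, degree):
    """Local fits at each target; windows are k nearest neighbours in sorted x.

    Degree 0/1 fits are evaluated for all targets at once on stacked
    windows; higher degrees fall back to a per-target solve.
    """
    starts = _window_starts(targets, xs, k)
    if degree > 1:
        out = np.empty(len(targets))
        for i, (x0, lo) in enumerate(zip(targets, starts)):
            sl = slice(lo, lo + k)
            out[i] = _local_fit(x0, xs[sl], ys[sl], ws[sl], degree)
        return out

    idx = starts[:, None] + np.arange(k)[None, :]
    xw = xs[idx]
    yw = ys[idx]
    ww = ws[idx]
    x0 = np.asarray(targets)[:, None]
    d = np.abs(xw - x0)
    h = d.max(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        tri = np.where(h > 0, (1.0 - (d / np.where(h > 0, h, 1.0)) ** 3) ** 3, 1.0)
    w = tri * ww
    sw = w.sum(axis=1)
    # degenerate tricube mass (all weight on the window edge): probe weights only
    bad = sw <= 0
    if bad.any():
        w[bad] = ww[bad]
        sw = w.sum(axis=1)
    if degree == 0:
        return (w * yw).sum(axis=1) / sw
    xc = xw - x0
    swx = (w * xc).sum(axis=1)
    swy = (w * yw).sum(axis=1)
    swxx = (w * xc * xc).sum(axis=1)
    swxy = (w * xc * yw).sum(axis=1)
    denom = sw * swxx - swx * swx
    mean = swy / sw
    with np.errstate(invalid="ignore", divide="ignore"):
        beta0 = (swxx * swy - swx * swxy) / denom
    return np.where(denom > 1e-12 * np.maximum(sw * swxx, 1e-300), beta0, mean)


def loess_fit(x, y, weights=None, config: LoessConfig | None = None) -> np.ndarray:
    """Locally weighted polynomial regression evaluated at every x.

    The window for each point contains the ``span`` fraction of nearest
    neighbours; tricube distance weights are multiplied by ``weights``.
    """
    if config is None:
        config = LoessConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n or n < 2:
        raise ValueError("x and y must have equal length >= 2")
    if weights is None:
        weights = np.ones(n)
    weights = np.asarray(weights, dtype=float)
    if len(weights) != n:
        raise ValueError("weights must align with x")
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    if not np.any(weights > 0):
        raise ValueError("all weights are zero")

    order = np.argsort(x, kind="stable")
    xs, ys, ws = x[order], y[order], weights[order]
    k = max(config.degree + 1, int(np.ceil(config.span * n)))
    k = min(k, n)

    if n <= _EXACT_LIMIT:
        fitted_sorted = _fit_at_targets(xs, xs, ys, ws, k, config.degree)
        fitted = np.empty(n)
        fitted[order] = fitted_sorted
        return fitted

    # large input: fit on quantile-spaced anchors, then interpolate
    anchors = np.unique(np.quantile(xs, np.linspace(0, 1, _N_ANCHORS)))
    anchor_fit = _fit_at_targets(anchors, xs, ys, ws, k, config.degree)
    return np.interp(x, anchors, anchor_fit)


def cyclic_loess_normalize(
    matrix: ExpressionMatrix, config: LoessConfig | None = None
) -> ExpressionMatrix:
    """Remove intensity-dependent trends between every pair of arrays.

    For each iteration and each unordered array pair (j, k), the loess
    trend of M = Mg_j - Mg_k on A = (Mg_j + Mg_k) / 2 is split half/half
    between the two arrays. Pairs are visited in a canonical label order,
    so the result does not depend on the input column order.
    """
    if config is None:
        config = LoessConfig()
    if matrix.n_arrays < 2:
        raise ValueError("cyclic loess needs at least 2 arrays")
    out = matrix.copy()
    vals = out.values
    w = out.weights.to_numpy()
    labels = sorted(vals.columns)
    for _ in range(config.iterations):
        for a, b in itertools.combinations(labels, 2):
            va = vals[a].to_numpy()
            vb = vals[b].to_numpy()
            m = va - vb
            avg = (va + vb) / 2.0
            trend = loess_fit(avg, m, w, config)
            vals[a] = va - trend / 2.0
            vals[b] = vb + trend / 2.0
    return out


def weighted_median(values, weights) -> float:
    """Weighted median: smallest value whose cumulative weight reaches half."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    cum = np.cumsum(w)
    half = 0.5 * cum[-1]
    idx = int(np.searchsorted(cum, half))
    if np.isclose(cum[idx], half) and idx + 1 < len(v):
        return 0.5 * (v[idx] + v[idx + 1])
    return float(v[idx])


def median_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Shift every array so its weighted median equals the global one.

    The global target is the median of the per-array weighted medians
    computed before any shifting, preserving the absolute-abundance scale
    that the gDNA reference carries.
    """
    if matrix.n_rows == 0 or matrix.n_arrays == 0:
        raise ValueError("empty matrix")
    out = matrix.copy()
    w = out.weights.to_numpy()
    medians = {c: weighted_median(out.values[c].to_numpy(), w) for c in out.values.columns}
    target = float(np.median(list(medians.values())))
    for c in out.values.columns:
        out.values[c] = out.values[c] + (target - medians[c])
    return out
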