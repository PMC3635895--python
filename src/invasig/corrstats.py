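"""Vectorized pairwise-complete Pearson correlation with t-based P values."""
from __future__ import annotations

import numpy as np
from scipy import stats


def pearson_rows(X: np.ndarray, y: np.ndarray):
    """Correlate every row of ``X`` (p x n) with ``y`` (n,).

    Missing entries (NaN) in either operand are dropped pairwise per row.

    Returns
    -------
    r, p, n_used : ndarray
        Correlation, two-sided P value from the t distribution with
        ``n_used - 2`` df, and the pairwise-complete count per row.
        Rows with fewer than 3 complete pairs or zero variance yield NaN.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    valid = ~np.isnan(X) & ~np.isnan(y)[None, :]
    n = valid.sum(axis=1).astype(float)

    X0 = np.where(valid, X, 0.0)
    Y0 = np.where(valid, y[None, :], 0.0)
    sx = X0.sum(axis=1)
    sy = Y0.sum(axis=1)
    sxx = (X0 * X0).sum(axis=1)
    syy = (Y0 * Y0).sum(axis=1)
    sxy = (X0 * Y0).sum(axis=1)

    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / n
        vx = sxx - sx * sx / n
        vy = syy - sy * sy / n
        r = cov / np.sqrt(vx * vy)
    bad = (n < 3) | ~np.isfinite(r)
    r = np.where(bad, np.nan, np.clip(r, -1.0, 1.0))

    df = n - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(df / (1.0 - r * r))
    p = np.where(
        np.isnan(r),
        np.nan,
        np.where(np.isclose(np.abs(r), 1.0), 0.0, 2.0 * stats.t.sf(np.abs(t), df)),
    )
    return r, p, n.astype(int)


def pearson_single(x: np.ndarray, y: np.ndarray):
    """Pairwise-complete Pearson r, two-sided P, n for two vectors."""
    r, p, n = pearson_rows(np.asarray(x, dtype=float)[None, :], y)
    return float(r[0]), float(p[0]), int(n[0])
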