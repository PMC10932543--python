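"""Small shared numerics: vectorized Pearson correlation with p-values."""

from __future__ import annotations

import numpy as np
from scipy import stats


def pearson_rows(X: np.ndarray, y: np.ndarray):
    """Pearson r and two-sided p of each row of ``X`` against vector ``y``.

    Rows (or a ``y``) with zero variance yield r = NaN, p = NaN; the
    p-value uses the exact t-distribution with n-2 degrees of freedom,
    matching ``scipy.stats.pearsonr``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    if X.shape[-1] != n:
        raise ValueError("shape mismatch between X rows and y")
    if n < 3:
        raise ValueError("need at least 3 observations for a correlation p-value")
    Xc = X - X.mean(axis=-1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=-1))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ yc) / (sx * sy)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    bad = ~np.isfinite(r)
    r = np.where(bad, np.nan, r)
    p = np.where(bad, np.nan, p)
    return r, p
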