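"""Shared statistical primitives: Spearman correlation, BH-FDR, Fisher's
z-transform combination of correlations.

Spearman is computed as Pearson on mid-ranks (average ranks for ties) with a
two-sided p-value from the large-sample t approximation
``t = Rs * sqrt((n-2) / (1 - Rs^2))`` on ``n-2`` degrees of freedom — the
same approximation every screening-scale co-expression analysis uses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


class ConstantInputError(ValueError):
    """Raised when a correlation is undefined because a vector is constant."""


def _midranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def spearman(x, y, min_n: int = 10) -> tuple[float, float, int]:
    """Spearman Rs with mid-rank ties and t-approximation p-value.

    Missing values are removed pairwise; fewer than ``min_n`` complete pairs
    raises ``ValueError`` and a constant vector raises
    :class:`ConstantInputError` (callers skip and record the reason).

    Returns ``(Rs, p_two_sided, n_complete)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < min_n:
        raise ValueError(f"only {n} complete pairs (< {min_n})")
    rx, ry = _midranks(x), _midranks(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        raise ConstantInputError("constant vector: Spearman undefined")
    rs = float(np.mean((rx - rx.mean()) * (ry - ry.mean())) / (sx * sy))
    rs = max(-1.0, min(1.0, rs))
    p = _spearman_p(rs, n)
    return rs, p, n

def _spearman_p(rs: float, n: int) -> float:
    if abs(rs) >= 1.0:
        return 0.0
    t = rs * np.sqrt((n - 2) / (1.0 - rs * rs))
    return float(2.0 * sps.t.sf(abs(t), df=n - 2))


def spearman_matrix(X: pd.DataFrame, Y: pd.DataFrame, min_n: int = 10):
    """All-pairs Spearman between rows of ``X`` and rows of ``Y``.

    Columns are sample IDs and must match. The fast path ranks every row once
    and computes the full correlation matrix by BLAS; rows with missing values
    fall back to pairwise-complete :func:`spearman`. Pairs that are skipped
    (too few complete pairs or a constant vector) get NaN in every output.

    Returns ``(rs, p, n)`` DataFrames indexed by (X rows) x (Y rows).
    """
    common = X.columns.intersection(Y.columns)
    if len(common) < min_n:
        raise ValueError(f"only {len(common)} shared samples (< {min_n})")
    Xc, Yc = X[common], Y[common]
    nx, ny, ns = len(Xc), len(Yc), len(common)

    rs = np.full((nx, ny), np.nan)
    pm = np.full((nx, ny), np.nan)
    nm = np.full((nx, ny), ns, dtype=int)

    x_nan = Xc.isna().any(axis=1).to_numpy()
    y_nan = Yc.isna().any(axis=1).to_numpy()

    def _zranks(df: pd.DataFrame, bad: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        vals = df.to_numpy(dtype=float)
        ranks = np.apply_along_axis(_midranks, 1, vals)
        mu = ranks.mean(axis=1, keepdims=True)
        sd = ranks.std(axis=1, keepdims=True)
        const = (sd[:, 0] == 0) | bad
        sd[sd == 0] = 1.0
        z = (ranks - mu) / sd
        return z, const

    zx, const_x = _zranks(Xc, x_nan)
    zy, const_y = _zranks(Yc, y_nan)
    good_x = ~x_nan & ~const_x
    good_y = ~y_nan & ~const_y
    if good_x.any() and good_y.any():
        block = zx[good_x] @ zy[good_y].T / ns
        np.clip(block, -1.0, 1.0, out=block)
        rs[np.ix_(good_x, good_y)] = block
        with np.errstate(divide="ignore", invalid="ignore"):
            t = block * np.sqrt((ns - 2) / np.maximum(1.0 - block * block, 1e-300))
        pm[np.ix_(good_x, good_y)] = 2.0 * sps.t.sf(np.abs(t), df=ns - 2)
        pm[np.ix_(good_x, good_y)] = np.where(
            np.abs(block) >= 1.0, 0.0, pm[np.ix_(good_x, good_y)]
        )

    # pairwise-complete fallback for rows with missing values
    for i in np.nonzero(x_nan)[0]:
        for j in range(ny):
            try:
                r, p, n = spearman(Xc.iloc[i], Yc.iloc[j], min_n=min_n)
            except ValueError:
                continue
            rs[i, j], pm[i, j], nm[i, j] = r, p, n
    if y_nan.any():
        for j in np.nonzero(y_nan)[0]:
            for i in np.nonzero(~x_nan)[0]:
                try:
                    r, p, n = spearman(Xc.iloc[i], Yc.iloc[j], min_n=min_n)
                except ValueError:
                    continue
                rs[i, j], pm[i, j], nm[i, j] = r, p, n

    idx, cols = Xc.index, Yc.index
    return (pd.DataFrame(rs, idx, cols), pd.DataFrame(pm, idx, cols),
            pd.DataFrame(nm, idx, cols))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_combine(groups) -> tuple[float, float]:
    """Combine per-group Spearman correlations via Fisher's z-transform.

    ``groups`` is a sequence of ``(Rs_g, n_g)``. Each z = atanh(Rs) has
    variance 1/(n-3); the combined correlation is tanh of the (n-3)-weighted
    mean z and the two-sided p comes from ``zbar * sqrt(sum(n-3))`` against
    the standard normal.

    Returns ``(Rs_prime, p_prime)``.
    """
    groups = list(groups)
    if not groups:
        raise ValueError("no groups to combine")
    zs, ws = [], []
    for rs_g, n_g in groups:
        if n_g < 4:
            raise ValueError(f"group size {n_g} < 4: z variance undefined")
        if abs(rs_g) >= 1.0:
            raise ValueError("|Rs| = 1 gives infinite Fisher z")
        zs.append(np.arctanh(rs_g))
        ws.append(n_g - 3)
    zs, ws = np.asarray(zs), np.asarray(ws, dtype=float)
    zbar = float(np.sum(ws * zs) / np.sum(ws))
    rs_prime = float(np.tanh(zbar))
    z_stat = zbar * np.sqrt(np.sum(ws))
    p_prime = float(2.0 * sps.norm.sf(abs(z_stat)))
    return rs_prime, p_prime
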