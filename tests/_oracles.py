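"""Independent reference implementations used to check the package.

Everything here is deliberately naive — per-voxel scans, explicit rank
tables, textbook formulas — and shares no code with the implementation
under test.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps


def brute_force_layer_labels(
    lesion: np.ndarray,
    gm: np.ndarray,
    hemi_ok: np.ndarray,
    voxel_mm: tuple[float, float, float],
    n_layers: int = 10,
    thickness: float = 2.0,
) -> np.ndarray:
    """Classify every voxel into its distance band by exhaustive scan.

    Returns an int array: 0 = not in any layer, k = layer k.  Distance is
    the minimum Euclidean distance (mm) from the voxel center to any
    lesion voxel center.
    """
    les_idx = np.argwhere(lesion)
    les_mm = les_idx * np.asarray(voxel_mm)
    out = np.zeros(lesion.shape, dtype=int)
    for idx in np.argwhere(gm & hemi_ok & ~lesion):
        d = np.sqrt(((les_mm - idx * np.asarray(voxel_mm)) ** 2).sum(axis=1)).min()
        if d <= n_layers * thickness:
            k = int(np.ceil(d / thickness))
            out[tuple(idx)] = max(k, 1)
    return out


def kendall_w_rank_table(series: np.ndarray) -> float:
    """Kendall's W from an explicit rank table (K series x t timepoints).

    Mid-ranks over time per series; tie correction subtracted in the
    denominator.  Pure-python accumulation.
    """
    k, t = series.shape
    ranks = np.array([sps.rankdata(row) for row in series])
    rank_sums = ranks.sum(axis=0)
    s = float(((rank_sums - rank_sums.mean()) ** 2).sum())
    tie = 0.0
    for row in series:
        _, counts = np.unique(row, return_counts=True)
        tie += float((counts**3 - counts).sum())
    denom = k**2 * (t**3 - t) - k * tie
    return 12.0 * s / denom


def ols_residuals_normal_equations(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Residuals via solve(X'X, X'y); y is (t,), x is (t, p)."""
    beta = np.linalg.solve(x.T @ x, x.T @ y)
    return y - x @ beta


def paired_t_closed_form(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    n = len(d)
    t = d.mean() / (d.std(ddof=1) / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return float(t), float(p)


def two_sample_t_pooled(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2.0 * sps.t.sf(abs(t), na + nb - 2)
    return float(t), float(p)


def pearson_r_formula(x: np.ndarray, y: np.ndarray) -> float:
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))


def chi2_2x2_no_correction(table: np.ndarray) -> float:
    (a, b), (c, d) = np.asarray(table, float)
    n = a + b + c + d
    return float(n * (a * d - b * c) ** 2 /
                 ((a + b) * (c + d) * (a + c) * (b + d)))


def friston24_direct(params: np.ndarray) -> np.ndarray:
    """Direct 24-column expansion: current, lagged, squares, lagged squares."""
    t = params.shape[0]
    cols = []
    for j in range(6):
        cols.append(params[:, j])
    for j in range(6):
        lag = np.zeros(t)
        lag[1:] = params[:-1, j]
        cols.append(lag)
    for j in range(6):
        cols.append(params[:, j] ** 2)
    for j in range(6):
        lag = np.zeros(t)
        lag[1:] = params[:-1, j]
        cols.append(lag**2)
    return np.column_stack(cols)
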