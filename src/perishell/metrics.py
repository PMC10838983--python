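"""Voxelwise resting-state metrics: ALFF and regional homogeneity (ReHo).

ALFF is the band-amplitude ratio: the sum of discrete-Fourier amplitude
over the low-frequency band (default 0.01-0.1 Hz) divided by the sum over
the full band (0-0.25 Hz], with the DC bin excluded from both sums.  Being
a ratio of a sub-sum to its total, the raw value lies in [0, 1].

ReHo is Kendall's coefficient of concordance W of a voxel's time series
with its 26 nearest neighbours (the 27-voxel cube), computed from
mid-ranks with the standard tie correction:

    W = 12 * S / (K^2 (t^3 - t) - K * sum_j T_j)

where S is the sum of squared deviations of the per-timepoint rank sums
from their mean, K the number of in-mask series in the neighbourhood, and
T_j = sum over tie groups of (g^3 - g) for series j.  Neighbourhoods
truncated by the analysis mask use the available K; isolated voxels
(K = 1) are undefined and masked out.

Both metrics are standardized per subject by division by their global
in-mask mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .volumes import BoldSeries, LabeledVolume, require_alignment

__all__ = ["MetricMap", "alff", "reho", "standardize", "kendall_w"]

log = logging.getLogger(__name__)


@dataclass
class MetricMap:
    """A voxelwise scalar map with its analysis mask.

    ``values`` is zero outside ``mask``; ``standardized`` records whether
    the map has been divided by its global in-mask mean (after which the
    in-mask mean is 1 by construction).
    """

    values: np.ndarray
    metric: str  # "ALFF" or "ReHo"
    mask: LabeledVolume
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.shape != self.mask.shape:
            raise ValueError("metric values and mask shapes differ")

    @property
    def affine(self) -> np.ndarray:
        return self.mask.affine

    def in_mask(self) -> np.ndarray:
        return self.values[self.mask.as_bool()]

    def to_volume(self) -> LabeledVolume:
        return self.mask.with_data(self.values)


def _band_indices(freqs: np.ndarray, low: float, high: float) -> np.ndarray:
    return (freqs >= low - 1e-12) & (freqs <= high + 1e-12) & (freqs > 0)


def alff(
    series: BoldSeries,
    mask: LabeledVolume,
    band: tuple[float, float] = (0.01, 0.1),
    full_band: tuple[float, float] = (0.0, 0.25),
    spectrum: str = "amplitude",
) -> MetricMap:
    """Amplitude of low-frequency fluctuations as a band-amplitude ratio.

    Per voxel the one-sided amplitude spectrum (2/t x |DFT|) is summed over
    the low band and divided by the sum over the full band; the DC bin is
    excluded from both.  The series should be detrended and
    nuisance-cleaned but NOT bandpassed — on a bandpassed series the ratio
    degenerates to ~1.

    ``spectrum="power"`` sums squared amplitudes instead, for sensitivity
    analyses; the ratio stays in [0, 1] either way.

    All-zero voxel time series yield ALFF 0 (count logged).
    """
    if spectrum not in ("amplitude", "power"):
        raise ValueError(f"unknown spectrum mode {spectrum!r}")
    require_alignment(series, mask)
    m = mask.as_bool()
    if not m.any():
        raise ValueError("analysis mask is empty")
    nyquist = 1.0 / (2.0 * series.tr)
    if nyquist + 1e-9 < full_band[1]:
        raise ValueError(
            f"full band extends to {full_band[1]} Hz but Nyquist is {nyquist:.4f} Hz"
        )
    t = series.n_timepoints
    y = series.data[m]  # (nvox, t)
    amp = (2.0 / t) * np.abs(np.fft.rfft(y, axis=1))
    if spectrum == "power":
        amp = amp**2
    freqs = np.fft.rfftfreq(t, d=series.tr)
    num = amp[:, _band_indices(freqs, *band)].sum(axis=1)
    den = amp[:, _band_indices(freqs, *full_band)].sum(axis=1)
    flat = np.zeros_like(den)
    ok = den > 0
    flat[ok] = num[ok] / den[ok]
    n_zero = int((~ok).sum())
    if n_zero:
        log.warning("alff: %d all-zero voxel time series set to 0", n_zero)
    values = np.zeros(series.spatial_shape, dtype=np.float32)
    values[m] = flat
    return MetricMap(values, "ALFF", mask.with_data(mask.data.copy()))


def _rank_columns(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mid-ranks per column of a (t, n) array, plus tie correction per column.

    Fast path: double argsort for columns without ties; columns with ties
    fall back to mid-rank computation and accumulate T = sum(g^3 - g).
    """
    t, n = y.shape
    order = np.argsort(y, axis=0, kind="stable")
    ranks = np.empty((t, n), dtype=np.float64)
    np.put_along_axis(ranks, order, np.arange(1, t + 1, dtype=np.float64)[:, None], axis=0)
    srt = np.take_along_axis(y, order, axis=0)
    has_tie = (np.diff(srt, axis=0) == 0).any(axis=0)
    tie_term = np.zeros(n)
    if has_tie.any():
        idx = np.nonzero(has_tie)[0]
        for j in idx:
            r = sps.rankdata(y[:, j], method="average")
            ranks[:, j] = r
            _, counts = np.unique(y[:, j], return_counts=True)
            tie_term[j] = float((counts**3 - counts).sum())
    return ranks, tie_term


def kendall_w(series_table: np.ndarray) -> float:
    """Kendall's coefficient of concordance for a (K, t) table of series.

    Each row is ranked over time with mid-ranks; the tie-corrected W is
    returned.  This is the same estimator ReHo applies to each 27-voxel
    neighbourhood.
    """
    y = np.asarray(series_table, dtype=float)
    k, t = y.shape
    ranks, tie = _rank_columns(y.T)  # (t, K)
    rank_sums = ranks.sum(axis=1)
    s = float(((rank_sums - rank_sums.mean()) ** 2).sum())
    denom = k**2 * (t**3 - t) - k * float(tie.sum())
    if denom <= 0:
        return float("nan")
    return 12.0 * s / denom


def reho(
    series: BoldSeries,
    mask: LabeledVolume,
    neighborhood: int = 27,
) -> MetricMap:
    """Regional homogeneity: Kendall's W over each voxel's 27-voxel cube.

    The series should already be bandpassed.  Neighbourhoods are clipped to
    the analysis mask (K < 27 at mask edges) rather than zero-padded, which
    would manufacture spurious concordance.  Voxels left with K = 1 are
    undefined: their value is 0 and they are removed from the output mask.
    """
    require_alignment(series, mask)
    if neighborhood != 27:
        raise ValueError("only the 27-voxel cubic neighbourhood is supported")
    t = series.n_timepoints
    if t < 4:
        raise ValueError("ReHo needs at least 4 timepoints")
    m = mask.as_bool()
    if not m.any():
        raise ValueError("analysis mask is empty")

    y = series.data[m].T.astype(np.float64)  # (t, nvox)
    if (np.ptp(y, axis=0) == 0).any():
        log.warning("reho: constant in-mask time series present; mid-ranks used")
    ranks, tie = _rank_columns(y)

    shape = series.spatial_shape
    rank_vol = np.zeros(shape + (t,), dtype=np.float32)
    rank_vol[m] = ranks.T.astype(np.float32)
    mask_f = m.astype(np.float32)
    tie_vol = np.zeros(shape, dtype=np.float32)
    tie_vol[m] = tie.astype(np.float32)

    pad = [(1, 1), (1, 1), (1, 1)]
    rank_p = np.pad(rank_vol, pad + [(0, 0)])
    mask_p = np.pad(mask_f, pad)
    tie_p = np.pad(tie_vol, pad)

    nx, ny, nz = shape
    rank_sum = np.zeros_like(rank_vol)
    k_count = np.zeros(shape, dtype=np.float32)
    tie_sum = np.zeros(shape, dtype=np.float32)
    for dx in range(3):
        for dy in range(3):
            for dz in range(3):
                sl = (
                    slice(dx, dx + nx),
                    slice(dy, dy + ny),
                    slice(dz, dz + nz),
                )
                rank_sum += rank_p[sl]
                k_count += mask_p[sl]
                tie_sum += tie_p[sl]

    rs = rank_sum[m].astype(np.float64)  # (nvox, t)
    k = k_count[m].astype(np.float64)
    ts = tie_sum[m].astype(np.float64)
    s = ((rs - rs.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    denom = k**2 * (t**3 - t) - k * ts
    w = np.zeros_like(s)
    defined = (k >= 2) & (denom > 0)
    w[defined] = 12.0 * s[defined] / denom[defined]
    n_undef = int((~defined).sum())
    if n_undef:
        log.warning("reho: %d isolated (K=1) voxels masked out", n_undef)

    values = np.zeros(shape, dtype=np.float32)
    values[m] = w
    out_mask = np.zeros(shape, dtype=np.uint8)
    out_mask[m] = defined.astype(np.uint8)
    return MetricMap(values, "ReHo", mask.with_data(out_mask))


def standardize(metric_map: MetricMap) -> MetricMap:
    """Divide a metric map by its global in-mask mean.

    After standardization the in-mask mean is 1 and out-of-mask voxels are
    zero; the operation is idempotent.  A zero global mean is a domain
    error (it would mean an identically-zero map).
    """
    m = metric_map.mask.as_bool()
    if not m.any():
        raise ValueError("analysis mask is empty")
    gmean = float(metric_map.values[m].mean())
    if gmean <= 0:
        raise ValueError("global mean is not positive; cannot standardize")
    values = np.zeros_like(metric_map.values)
    values[m] = metric_map.values[m] / gmean
    return MetricMap(values, metric_map.metric, metric_map.mask, standardized=True)
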