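"""Resting-state preprocessing: volume discard, motion QC, nuisance
regression, detrending, bandpass filtering and spatial smoothing.

Stage order is fixed::

    discard -> motion QC -> nuisance regression -> detrend
            -> [ALFF branch: smoothed, NOT bandpassed]
            -> bandpass -> [ReHo branch]

The band-amplitude ratio that defines ALFF is degenerate (~1) on
bandpassed data, so the ALFF branch keeps the full spectrum of the
detrended, nuisance-cleaned series; regional homogeneity is computed on
the bandpassed series.  The temporal filter is an ideal (boxcar) FFT
bandpass.  Spatial smoothing uses a Gaussian kernel specified as FWHM in
mm (sigma = FWHM / (2 sqrt(2 ln 2))) with nearest-neighbour boundary
handling; by default the smoothed series feeds only the ALFF branch, since
pre-smoothing mechanically inflates local synchrony — ReHo maps are
smoothed after standardization instead (see :mod:`perishell.pipeline`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volumes import BoldSeries, LabeledVolume, MotionTrace, require_alignment

__all__ = [
    "PreprocConfig",
    "NuisanceMatrix",
    "qc_motion",
    "friston24_expand",
    "build_nuisance",
    "regress_nuisance",
    "detrend_linear",
    "bandpass",
    "smooth",
    "fwhm_to_sigma",
]

log = logging.getLogger(__name__)

FWHM_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


def fwhm_to_sigma(fwhm_mm: float) -> float:
    """Gaussian sigma (mm) for a kernel given as full width at half maximum."""
    return fwhm_mm / FWHM_SIGMA


@dataclass
class PreprocConfig:
    """Preprocessing contract.

    Defaults mirror standard practice for a TR=2 s acquisition: drop the
    first 10 volumes, exclude subjects moving more than 3 mm or 3 degrees,
    regress Friston-24 motion terms plus WM/CSF mean signals, bandpass
    0.01-0.1 Hz, smooth at 6 mm FWHM.
    """

    n_discard: int = 10
    motion_trans_max_mm: float = 3.0
    motion_rot_max_deg: float = 3.0
    band: tuple[float, float] = (0.01, 0.1)
    fwhm_mm: float = 6.0
    friston24: bool = True
    smooth_before_reho: bool = False
    standardize_gm_only: bool = False  # global mean over GM instead of whole brain

    def validate(self, tr: float, n_timepoints: int) -> None:
        low, high = self.band
        nyquist = 1.0 / (2.0 * tr)
        if not (0 <= low < high):
            raise ValueError(f"invalid band {self.band}")
        if high > nyquist + 1e-12:
            raise ValueError(
                f"band upper edge {high} Hz exceeds Nyquist {nyquist:.4f} Hz"
            )
        if self.n_discard >= n_timepoints:
            raise ValueError("n_discard must be smaller than the series length")
        if self.fwhm_mm < 0:
            raise ValueError("smoothing FWHM must be non-negative")


@dataclass
class NuisanceMatrix:
    """Per-timepoint nuisance regressors with column labels."""

    columns: np.ndarray  # (t, p)
    names: list[str]

    def __post_init__(self) -> None:
        self.columns = np.atleast_2d(np.asarray(self.columns, dtype=float))
        if self.columns.shape[1] != len(self.names):
            raise ValueError("column count does not match number of names")


def qc_motion(trace: MotionTrace, cfg: PreprocConfig) -> bool:
    """True (pass) unless any |translation| > 3 mm or |rotation| > 3 degrees.

    The inequalities are strict: a subject peaking at exactly 3.0 mm or
    3.0 degrees is retained.
    """
    if trace.n_timepoints == 0:
        raise ValueError("empty motion trace")
    max_t = float(np.abs(trace.translations).max())
    max_r = float(np.abs(trace.rotations).max())
    return not (max_t > cfg.motion_trans_max_mm or max_r > cfg.motion_rot_max_deg)


def friston24_expand(trace: MotionTrace) -> NuisanceMatrix:
    """Friston 24-parameter motion expansion: [R, R_{t-1}, R^2, R_{t-1}^2].

    R holds the six rigid-body parameters per timepoint; the lagged terms
    use 0 for the first row.
    """
    if trace.n_timepoints < 2:
        raise ValueError("need at least 2 timepoints for the lagged expansion")
    r = trace.as_matrix()
    r_lag = np.vstack([np.zeros((1, 6)), r[:-1]])
    cols = np.hstack([r, r_lag, r**2, r_lag**2])
    base = ["tx", "ty", "tz", "rx", "ry", "rz"]
    names = (
        base
        + [f"{b}_lag" for b in base]
        + [f"{b}_sq" for b in base]
        + [f"{b}_lag_sq" for b in base]
    )
    return NuisanceMatrix(cols, names)


def build_nuisance(
    trace: MotionTrace | None,
    series: BoldSeries | None = None,
    wm_mask: LabeledVolume | None = None,
    csf_mask: LabeledVolume | None = None,
    friston24: bool = True,
) -> NuisanceMatrix:
    """Assemble the nuisance design: 24 motion terms + WM and CSF mean signals.

    Tissue signals are plain mask means of the series (no PCA); either part
    may be omitted.
    """
    blocks: list[np.ndarray] = []
    names: list[str] = []
    if trace is not None:
        if friston24:
            m = friston24_expand(trace)
        else:
            m = NuisanceMatrix(trace.as_matrix(), ["tx", "ty", "tz", "rx", "ry", "rz"])
        blocks.append(m.columns)
        names.extend(m.names)
    if series is not None:
        for mask, label in ((wm_mask, "wm_mean"), (csf_mask, "csf_mean")):
            if mask is None:
                continue
            require_alignment(series, mask)
            sig = series.data[mask.as_bool()].mean(axis=0)
            blocks.append(sig[:, None])
            names.append(label)
    if not blocks:
        raise ValueError("no nuisance sources supplied")
    return NuisanceMatrix(np.hstack(blocks), names)


def _design_with_intercept(nuis: NuisanceMatrix, t: int) -> np.ndarray:
    if nuis.columns.shape[0] != t:
        raise ValueError(
            f"nuisance rows ({nuis.columns.shape[0]}) != series timepoints ({t})"
        )
    return np.hstack([np.ones((t, 1)), nuis.columns])


def _drop_collinear(x: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    """Greedily drop columns that add no rank (pivoted QR diagnostic)."""
    keep: list[int] = []
    for j in range(x.shape[1]):
        cand = x[:, keep + [j]]
        if np.linalg.matrix_rank(cand) > len(keep):
            keep.append(j)
        else:
            log.warning("dropping collinear nuisance column %r", names[j])
    return x[:, keep], [names[j] for j in keep]


def _masked_residuals(series: BoldSeries, x: np.ndarray, mask) -> BoldSeries:
    """OLS residuals of every (in-mask) voxel series against design ``x``."""
    if mask is None:
        y = series.data.reshape(-1, series.n_timepoints).T  # (t, nvox)
        resid = y - x @ (np.linalg.pinv(x) @ y)
        return series.with_data(
            resid.T.reshape(series.data.shape).astype(series.data.dtype, copy=False)
        )
    m = mask.as_bool() if hasattr(mask, "as_bool") else np.asarray(mask, dtype=bool)
    y = series.data[m].T  # (t, nvox_in_mask)
    # pinv in double for stability, residual matmuls in the series dtype
    pinv = np.linalg.pinv(x).astype(y.dtype, copy=False)
    xd = x.astype(y.dtype, copy=False)
    resid = y - xd @ (pinv @ y)
    out = series.data.copy()
    out[m] = resid.T.astype(series.data.dtype, copy=False)
    return series.with_data(out)


def regress_nuisance(
    series: BoldSeries, nuis: NuisanceMatrix, mask=None
) -> BoldSeries:
    """Voxelwise OLS residuals against [intercept | nuisance regressors].

    Residuals are orthogonal to every retained regressor; rank-deficient
    designs lose their collinear columns with a logged warning.  With a
    ``mask`` (boolean array or LabeledVolume) only in-mask voxels are
    regressed and the rest pass through unchanged.
    """
    t = series.n_timepoints
    x = _design_with_intercept(nuis, t)
    names = ["intercept"] + nuis.names
    if np.linalg.matrix_rank(x) < x.shape[1]:
        x, names = _drop_collinear(x, names)
    return _masked_residuals(series, x, mask)


def detrend_linear(series: BoldSeries, mask=None) -> BoldSeries:
    """Remove per-voxel linear trend (and mean) by least squares."""
    t = series.n_timepoints
    x = np.column_stack([np.ones(t), np.arange(t, dtype=float)])
    return _masked_residuals(series, x, mask)


def bandpass(series: BoldSeries, band: tuple[float, float]) -> BoldSeries:
    """Ideal FFT bandpass: keep Fourier bins with low <= f <= high, zero the rest.

    The DC bin is always removed, so the output is (numerically) zero-mean
    per voxel.  Applying the filter twice equals applying it once.
    """
    low, high = band
    nyquist = 1.0 / (2.0 * series.tr)
    if high > nyquist + 1e-12:
        raise ValueError(f"band upper edge {high} Hz exceeds Nyquist {nyquist:.4f} Hz")
    t = series.n_timepoints
    freqs = np.fft.rfftfreq(t, d=series.tr)
    keep = (freqs >= low - 1e-12) & (freqs <= high + 1e-12) & (freqs > 0)
    spec = np.fft.rfft(series.data, axis=3)
    spec[..., ~keep] = 0
    out = np.fft.irfft(spec, n=t, axis=3)
    return series.with_data(out.astype(series.data.dtype, copy=False))


def smooth(obj, fwhm_mm: float):
    """Gaussian spatial smoothing of a volume or series (FWHM in mm).

    Sigma per axis is converted to voxels using the voxel size; fwhm 0 is
    the identity.  Boundary mode is 'nearest', which preserves constant
    volumes exactly and conserves the total sum away from edges.
    """
    if fwhm_mm < 0:
        raise ValueError("smoothing FWHM must be non-negative")
    if fwhm_mm == 0:
        return obj
    sigma_vox = [fwhm_to_sigma(fwhm_mm) / v for v in obj.voxel_size]
    if isinstance(obj, BoldSeries):
        out = ndimage.gaussian_filter(
            obj.data, sigma=sigma_vox + [0.0], mode="nearest"
        )
        return obj.with_data(out.astype(obj.data.dtype, copy=False))
    if isinstance(obj, LabeledVolume):
        out = ndimage.gaussian_filter(
            obj.data.astype(np.float32), sigma=sigma_vox, mode="nearest"
        )
        return obj.with_data(out)
    raise TypeError(f"cannot smooth object of type {type(obj)!r}")


def discard_volumes(series: BoldSeries, n: int) -> BoldSeries:
    """Drop the first ``n`` volumes (scanner equilibration)."""
    if n < 0 or n >= series.n_timepoints:
        raise ValueError("n_discard must be in [0, t)")
    return series.with_data(series.data[..., n:])
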