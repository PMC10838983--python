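"""NIfTI volume and motion-table I/O with grid-consistency checks.

All per-subject inputs (lesion mask, gray-matter mask, hemisphere labels,
BOLD series, tissue masks) are assumed pre-aligned on one grid in a common
left-right symmetric space.  This module enforces that assumption: every
downstream operation first verifies that shapes, voxel sizes and affines
agree, so geometry errors surface at load time rather than as silently
shifted masks.

Conventions
-----------
* Internal indexing is 0-based with axis order (x, y, z) as stored.
* World orientation comes from the affine; the left-right axis is the
  storage axis whose world direction has the dominant +-x component.
* Masks are stored as unsigned 8-bit, scalar maps as 32-bit float.
* Motion tables are whitespace-delimited text with six columns
  (tx ty tz rx ry rz); translations in mm, rotations in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "LabeledVolume",
    "BoldSeries",
    "MotionTrace",
    "AlignmentError",
    "read_volume",
    "write_volume",
    "read_bold",
    "write_bold",
    "read_motion",
    "write_motion",
    "check_alignment",
    "left_right_axis",
]

#: tolerance for elementwise affine / voxel-size agreement
ALIGN_TOL = 1e-6


class AlignmentError(ValueError):
    """Two volumes that must share a grid do not."""


def _voxel_size(affine: np.ndarray) -> tuple[float, float, float]:
    return tuple(float(np.linalg.norm(affine[:3, i])) for i in range(3))


@dataclass
class LabeledVolume:
    """A 3D scalar or label grid with voxel-size metadata and affine.

    Parameters
    ----------
    data : ndarray, shape (x, y, z)
        Voxel values.  Binary masks hold only {0, 1}.
    affine : ndarray, shape (4, 4)
        Voxel-to-world map (mm).
    space_tag : str
        Free-text identifier of the common space the volume lives in.
    """

    data: np.ndarray
    affine: np.ndarray
    space_tag: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D data, got shape {self.data.shape}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel dimensions must be strictly positive")

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        """Voxel edge lengths in mm per storage axis."""
        return _voxel_size(self.affine)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def is_binary(self) -> bool:
        return bool(np.isin(self.data, (0, 1)).all())

    def as_bool(self) -> np.ndarray:
        return self.data.astype(bool)

    def with_data(self, data: np.ndarray) -> "LabeledVolume":
        """Same grid, new voxel values."""
        return LabeledVolume(data, self.affine.copy(), self.space_tag)


@dataclass
class BoldSeries:
    """A 4D (x, y, z, t) BOLD time-series grid with repetition time.

    ``tr`` is in seconds and must be positive; at least two timepoints
    are required.
    """

    data: np.ndarray
    affine: np.ndarray
    tr: float
    space_tag: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D data, got shape {self.data.shape}")
        if self.data.shape[3] < 2:
            raise ValueError("BOLD series needs at least 2 timepoints")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.tr <= 0:
            raise ValueError("repetition time must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        return _voxel_size(self.affine)

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def spatial_volume(self) -> LabeledVolume:
        """A zeroed LabeledVolume on this series' spatial grid."""
        return LabeledVolume(
            np.zeros(self.spatial_shape, dtype=np.uint8), self.affine, self.space_tag
        )

    def with_data(self, data: np.ndarray) -> "BoldSeries":
        return BoldSeries(data, self.affine.copy(), self.tr, self.space_tag)


@dataclass
class MotionTrace:
    """Per-timepoint rigid-body motion: translations (mm), rotations (deg)."""

    translations: np.ndarray  # (t, 3)
    rotations: np.ndarray  # (t, 3), degrees

    def __post_init__(self) -> None:
        self.translations = np.atleast_2d(np.asarray(self.translations, dtype=float))
        self.rotations = np.atleast_2d(np.asarray(self.rotations, dtype=float))
        if self.translations.shape != self.rotations.shape:
            raise ValueError("translations and rotations must have identical shape")
        if self.translations.shape[1] != 3:
            raise ValueError("expected 3 columns each for translations and rotations")

    @property
    def n_timepoints(self) -> int:
        return self.translations.shape[0]

    def as_matrix(self) -> np.ndarray:
        """(t, 6) array ordered tx ty tz rx ry rz."""
        return np.hstack([self.translations, self.rotations])

    def discard(self, n: int) -> "MotionTrace":
        return MotionTrace(self.translations[n:], self.rotations[n:])


def read_volume(path: str | Path) -> LabeledVolume:
    """Read a 3D NIfTI-1/NIfTI-2 file.

    Integer-coded label files are preserved exactly; a 4D file raises a
    shape error.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a 3D volume, got {data.ndim}D shape {data.shape}"
        )
    return LabeledVolume(data, img.affine)


def write_volume(vol: LabeledVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI; masks/labels as uint8-or-wider int, maps as float32."""
    data = vol.data
    if np.issubdtype(data.dtype, np.integer) or data.dtype == bool:
        out = data.astype(np.uint8 if data.max(initial=0) < 256 else np.int32)
    else:
        out = data.astype(np.float32)
    nib.save(nib.Nifti1Image(out, vol.affine), str(path))
    return Path(path)


def read_bold(path: str | Path, tr: float | None = None) -> BoldSeries:
    """Read a 4D NIfTI series; ``tr`` overrides the header pixdim[4] if given."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D series, got shape {data.shape}")
    if tr is None:
        tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 0.0
    if tr <= 0:
        raise ValueError(f"{path}: repetition time not in header; pass tr explicitly")
    return BoldSeries(data.astype(np.float32), img.affine, tr)


def write_bold(series: BoldSeries, path: str | Path) -> Path:
    img = nib.Nifti1Image(series.data.astype(np.float32), series.affine)
    zooms = list(img.header.get_zooms())
    zooms[3] = series.tr
    img.header.set_zooms(zooms)
    nib.save(img, str(path))
    return Path(path)


def read_motion(path: str | Path) -> MotionTrace:
    """Read a whitespace-delimited 6-column motion table (rotations in degrees)."""
    table = np.loadtxt(str(path), ndmin=2)
    if table.shape[1] != 6:
        raise ValueError(f"{path}: motion table must have 6 columns, got {table.shape[1]}")
    return MotionTrace(table[:, :3], table[:, 3:])


def write_motion(trace: MotionTrace, path: str | Path) -> Path:
    np.savetxt(str(path), trace.as_matrix(), fmt="%.6f")
    return Path(path)


def check_alignment(
    a: LabeledVolume | BoldSeries, b: LabeledVolume | BoldSeries, tol: float = ALIGN_TOL
) -> bool:
    """True iff the two grids agree: shape, voxel size and affine within ``tol``.

    Pure predicate — symmetric and reflexive; 4D inputs compare their
    spatial grid only.
    """
    shape_a = a.data.shape[:3]
    shape_b = b.data.shape[:3]
    if shape_a != shape_b:
        return False
    if not np.allclose(a.voxel_size, b.voxel_size, atol=tol, rtol=0):
        return False
    return bool(np.allclose(a.affine, b.affine, atol=tol, rtol=0))


def require_alignment(*vols: LabeledVolume | BoldSeries) -> None:
    """Raise :class:`AlignmentError` unless all volumes share one grid."""
    for v in vols[1:]:
        if not check_alignment(vols[0], v):
            raise AlignmentError(
                f"grids differ: shape {vols[0].data.shape[:3]} vs {v.data.shape[:3]}, "
                "or affine mismatch beyond tolerance"
            )


def left_right_axis(affine: np.ndarray) -> tuple[int, float]:
    """Identify the storage axis carrying the world left-right (x) direction.

    Returns ``(axis, sign)`` where ``sign`` is the sign of the world-x
    component along increasing index.  Raises if no storage axis has a
    dominant x component (strongly oblique affine).
    """
    affine = np.asarray(affine, dtype=float)
    cols = affine[:3, :3]
    norms = np.linalg.norm(cols, axis=0)
    xfrac = np.abs(cols[0]) / np.where(norms > 0, norms, np.inf)
    axis = int(np.argmax(xfrac))
    if xfrac[axis] < 0.9:
        raise ValueError(
            "no storage axis has a dominant world left-right component; "
            "reorient the volume before midline operations"
        )
    return axis, float(np.sign(cols[0, axis]))
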