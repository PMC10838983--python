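"""Synthetic cohorts: symmetric brain-like anatomy, one-hemisphere lesions,
and 4D BOLD series with controllable distance-dependent deficits.

The generator exists so every pipeline stage — mask geometry,
preprocessing, metrics, layer statistics, resection classification — can
be exercised end-to-end against known ground truth without any imaging
download.

Anatomy
-------
A midline-symmetric ellipsoidal shell of cortical gray matter (GM) with a
white-matter core and an interposed CSF shell, hemisphere labels split at
world x = 0, and a spherical lesion embedded in the GM of one hemisphere
with enough clearance that the full 20-mm perilesional band stays clear of
the midline.

Signal model
------------
Each brain voxel's series is

    x_v(t) = a_v * [ w_v * s_b(t) + sqrt(1 - w_v^2) * u_v(t) ]
             + sigma * eps_v(t) + slope_v * t + gamma * g(t)

where s_b is a low-frequency (0.01-0.1 Hz) signal shared within the
voxel's 3x3x3 block (a sum of random-phase sinusoids at the in-band DFT
frequencies), u_v an independent low-frequency signal of the same
construction, eps broadband white noise, and g(t) a global nuisance signal
that also dominates the WM and CSF compartments (so that WM/CSF mean
regression can remove it).  ALFF is controlled by the low-frequency
amplitude a_v, ReHo by the shared-signal mixing weight w_v.

Within ipsilateral GM at lesion distance d < D (the deficit extent),
a_v is multiplied by (1 - alff_deficit * profile(d)) and w_v by
(1 - reho_deficit * profile(d)); the contralateral homotopic GM receives
no deficit.  Between-subject variability enters as a smooth lognormal
modulation field on a_v, so layer means genuinely vary across subjects.

Determinism: one seed, one cohort.  Streams are split per subject with
``numpy.random.SeedSequence(seed).spawn``, so subject k's data do not
depend on how many subjects precede it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .layers import build_layers, lesion_distance_mm, LayerSet
from .volumes import BoldSeries, LabeledVolume, MotionTrace

__all__ = [
    "CohortSpec",
    "Anatomy",
    "SyntheticSubject",
    "SyntheticCohort",
    "make_anatomy",
    "make_bold",
    "make_resection_mask",
    "simulate_cohort",
]

HEMI_LEFT = 1  # world x < 0
HEMI_RIGHT = 2  # world x > 0 (lesion side)


@dataclass
class CohortSpec:
    """Study conditions for one synthetic group.

    Defaults follow the emulated acquisition: 2-s TR, 205 volumes of which
    the first 10 are discarded, a 2-mm isotropic grid shared by masks and
    series, an 8-mm-radius cortical lesion, and a step-profile 40% ALFF
    deficit extending 12 mm from the lesion (the analogue of abnormality
    through layer 6).
    """

    n_subjects: int = 15
    grid_shape: tuple[int, int, int] = (64, 64, 48)
    voxel_mm: float = 2.0
    tr_s: float = 2.0
    n_timepoints: int = 205
    lesion_radius_mm: float = 8.0
    deficit_extent_mm: float = 12.0
    alff_deficit_fraction: float = 0.4
    reho_deficit_fraction: float = 0.0
    deficit_profile: str = "step"  # or "linear-taper"
    between_subject_sd: float = 0.12
    noise_sd: float = 1.0
    lf_amplitude: float = 1.0
    shared_weight: float = 0.6
    global_nuisance_weight: float = 0.3
    resection_margin_mm: float = 12.0
    qc_fail_subjects: tuple[int, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        # YAML/JSON specs hand in lists; normalize to tuples
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        self.qc_fail_subjects = tuple(int(i) for i in self.qc_fail_subjects)

    def validate(self) -> None:
        if self.deficit_extent_mm > 20:
            raise ValueError("deficit extent must not exceed the 20-mm layer band")
        if not 0 <= self.alff_deficit_fraction < 1:
            raise ValueError("alff deficit fraction must lie in [0, 1)")
        if not 0 <= self.reho_deficit_fraction < 1:
            raise ValueError("reho deficit fraction must lie in [0, 1)")
        if self.deficit_profile not in ("step", "linear-taper"):
            raise ValueError(f"unknown deficit profile {self.deficit_profile!r}")
        if self.n_timepoints < 20:
            raise ValueError("need at least 20 timepoints")
        ax = 0.45 * self.grid_shape[0] * self.voxel_mm
        clearance = 0.9 * ax - self.lesion_radius_mm - max(20.0, self.deficit_extent_mm)
        if clearance <= 0:
            raise ValueError(
                "lesion plus perilesional band would reach the midline; "
                "use a larger grid or a smaller lesion"
            )

    @property
    def true_extent_layers(self) -> int:
        """Injected abnormal extent in 2-mm layers (ground truth)."""
        return int(round(self.deficit_extent_mm / 2.0))


@dataclass
class Anatomy:
    """Shared synthetic anatomy: tissue masks, hemisphere labels, lesion."""

    gm: LabeledVolume
    wm: LabeledVolume
    csf: LabeledVolume
    hemis: LabeledVolume
    lesion: LabeledVolume
    lesion_distance: np.ndarray  # mm, EDT from the lesion

    @property
    def brain(self) -> np.ndarray:
        return self.gm.as_bool() | self.wm.as_bool() | self.csf.as_bool()


def _symmetric_affine(shape: tuple[int, int, int], voxel: float) -> np.ndarray:
    """Affine centring the grid on the origin, symmetric about x = 0."""
    aff = np.diag([voxel, voxel, voxel, 1.0])
    aff[:3, 3] = [-(n - 1) / 2.0 * voxel for n in shape]
    return aff


def make_anatomy(spec: CohortSpec) -> Anatomy:
    """Build the midline-symmetric ellipsoidal-shell anatomy with a lesion.

    GM occupies the normalized-radius band (0.8, 1.0], CSF (0.65, 0.8],
    WM the core; the lesion is a sphere of ``lesion_radius_mm`` centred at
    0.9 of the +x semi-axis, intersected with GM so it is wholly cortical
    and wholly right-hemisphere.
    """
    spec.validate()
    shape = spec.grid_shape
    affine = _symmetric_affine(shape, spec.voxel_mm)
    coords = [
        (np.arange(n) - (n - 1) / 2.0) * spec.voxel_mm for n in shape
    ]
    x, y, z = np.meshgrid(*coords, indexing="ij")
    semi = (
        0.45 * shape[0] * spec.voxel_mm,
        0.45 * shape[1] * spec.voxel_mm,
        0.45 * shape[2] * spec.voxel_mm,
    )
    rho = np.sqrt((x / semi[0]) ** 2 + (y / semi[1]) ** 2 + (z / semi[2]) ** 2)
    gm = (rho > 0.8) & (rho <= 1.0)
    csf = (rho > 0.65) & (rho <= 0.8)
    wm = rho <= 0.65
    hemis = np.where(x < 0, HEMI_LEFT, HEMI_RIGHT).astype(np.uint8)
    hemis[~(gm | csf | wm)] = 0

    center = (0.9 * semi[0], 0.0, 0.0)
    dist2 = (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2
    lesion = (dist2 <= spec.lesion_radius_mm**2) & gm
    if not lesion.any():
        raise ValueError("lesion ended up empty; enlarge the grid or the radius")

    mk = lambda d: LabeledVolume(d.astype(np.uint8), affine, "synthetic-symmetric")
    lesion_vol = mk(lesion)
    return Anatomy(
        gm=mk(gm),
        wm=mk(wm),
        csf=mk(csf),
        hemis=LabeledVolume(hemis, affine, "synthetic-symmetric"),
        lesion=lesion_vol,
        lesion_distance=lesion_distance_mm(lesion_vol),
    )


def _deficit_profile(d: np.ndarray, extent: float, kind: str) -> np.ndarray:
    """profile(d) in [0, 1]: 1 at the lesion, 0 beyond the deficit extent."""
    if kind == "step":
        return (d < extent).astype(np.float32)
    taper = np.clip(1.0 - d / extent, 0.0, 1.0)
    return np.where(d < extent, taper, 0.0).astype(np.float32)


def _lowfreq_noise(
    rng: np.random.Generator, n_series: int, t: int, tr: float,
    band: tuple[float, float] = (0.01, 0.1),
) -> np.ndarray:
    """Unit-SD low-frequency series: random-phase sinusoids at in-band DFT bins."""
    freqs = np.fft.rfftfreq(t, d=tr)
    inband = (freqs >= band[0]) & (freqs <= band[1]) & (freqs > 0)
    nb = int(inband.sum())
    spec = np.zeros((n_series, len(freqs)), dtype=np.complex64)
    coef = rng.standard_normal((n_series, nb, 2), dtype=np.float32)
    spec[:, inband] = coef[..., 0] + 1j * coef[..., 1]
    x = np.fft.irfft(spec, n=t, axis=1).astype(np.float32)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _subject_modulation(
    rng: np.random.Generator, shape: tuple[int, int, int], voxel: float,
    sd: float, corr_mm: float = 12.0,
) -> np.ndarray:
    """Smooth lognormal amplitude-modulation field, unit median, sd on log scale."""
    if sd == 0:
        return np.ones(shape, dtype=np.float32)
    g = rng.standard_normal(shape, dtype=np.float32)
    g = ndimage.gaussian_filter(g, sigma=corr_mm / voxel, mode="nearest")
    s = g.std()
    if s > 0:
        g /= s
    return np.exp(sd * g).astype(np.float32)


def _motion_trace(
    rng: np.random.Generator, t: int, fail: bool
) -> MotionTrace:
    steps_t = rng.normal(0, 0.02, size=(t, 3))
    steps_r = rng.normal(0, 0.01, size=(t, 3))
    trans = np.clip(np.cumsum(steps_t, axis=0), -1.0, 1.0)
    rot = np.clip(np.cumsum(steps_r, axis=0), -0.5, 0.5)
    if fail:
        trans[t // 2, 1] = 3.5  # translation spike beyond the 3-mm limit
    return MotionTrace(trans, rot)


def make_bold(
    spec: CohortSpec,
    anatomy: Anatomy,
    rng: np.random.Generator,
    qc_fail: bool = False,
) -> tuple[BoldSeries, MotionTrace]:
    """One subject's 4D series plus motion trace under the cohort's conditions."""
    shape = spec.grid_shape
    t = spec.n_timepoints
    brain = anatomy.brain
    gm = anatomy.gm.as_bool()
    nvox = int(brain.sum())

    # deficit fields on the full grid
    d = anatomy.lesion_distance
    prof = _deficit_profile(d, spec.deficit_extent_mm, spec.deficit_profile)
    ipsi_gm = gm & (anatomy.hemis.data == HEMI_RIGHT)
    deficit_zone = np.where(ipsi_gm | anatomy.lesion.as_bool(), prof, 0.0)
    a_field = spec.lf_amplitude * (1.0 - spec.alff_deficit_fraction * deficit_zone)
    w_field = spec.shared_weight * (1.0 - spec.reho_deficit_fraction * deficit_zone)

    a_field = a_field * _subject_modulation(
        rng, shape, spec.voxel_mm, spec.between_subject_sd
    )

    # shared low-frequency signal per 3x3x3 block; the x-partition counts
    # blocks outward from the midline so the sharing structure (and hence
    # the post-smoothing amplitude pattern) is exactly mirror-symmetric
    nx = shape[0]
    hx = nx // 2
    ii, jj, kk = np.indices(shape)
    bx_idx = np.where(ii >= hx, (ii - hx) // 3, (hx - 1 - ii) // 3)
    side = (ii >= hx).astype(np.int64)
    nbx = int(np.ceil(hx / 3)) + int(np.ceil((nx - hx) / 3))
    bx = bx_idx * 2 + side
    by, bz = (int(np.ceil(n / 3)) for n in shape[1:])
    block_id = (bx * by + jj // 3) * bz + kk // 3
    n_blocks = nbx * by * bz
    s_block = _lowfreq_noise(rng, n_blocks, t, spec.tr_s)

    av = a_field[brain].astype(np.float32)[:, None]
    wv = np.clip(w_field[brain], 0.0, 1.0).astype(np.float32)[:, None]
    cv = np.sqrt(1.0 - wv**2)

    shared = s_block[block_id[brain]]
    indep = _lowfreq_noise(rng, nvox, t, spec.tr_s)
    eps = rng.standard_normal((nvox, t), dtype=np.float32)
    g_global = _lowfreq_noise(rng, 1, t, spec.tr_s, band=(0.005, 0.08))[0]
    slope = rng.normal(0, 0.005, size=(nvox, 1)).astype(np.float32)
    tt = np.arange(t, dtype=np.float32)[None, :]

    series_flat = (
        av * (wv * shared + cv * indep)
        + spec.noise_sd * eps
        + slope * tt
        + spec.global_nuisance_weight * g_global[None, :]
    )
    # WM/CSF compartments carry the global nuisance strongly so that mask
    # means recover it for regression
    tissue = (anatomy.wm.as_bool() | anatomy.csf.as_bool())[brain]
    series_flat[tissue] += 0.7 * g_global[None, :]

    data = np.zeros(shape + (t,), dtype=np.float32)
    data[brain] = series_flat
    series = BoldSeries(data, anatomy.gm.affine, spec.tr_s, "synthetic-symmetric")
    trace = _motion_trace(rng, t, qc_fail)
    return series, trace


def make_resection_mask(
    spec: CohortSpec, anatomy: Anatomy, margin_mm: float | None = None
) -> LabeledVolume:
    """Resection cavity: everything within ``margin_mm`` of the lesion, ipsilateral."""
    margin = spec.resection_margin_mm if margin_mm is None else margin_mm
    res = (anatomy.lesion_distance <= margin) & (
        anatomy.hemis.data == HEMI_RIGHT
    )
    res |= anatomy.lesion.as_bool()
    return anatomy.lesion.with_data(res.astype(np.uint8))


@dataclass
class SyntheticSubject:
    subject_id: str
    group: str
    bold: BoldSeries
    motion: MotionTrace
    resection: LabeledVolume
    qc_fail_injected: bool = False


@dataclass
class SyntheticCohort:
    """One simulated group: shared anatomy, per-subject series, ground truth."""

    spec: CohortSpec
    group: str
    anatomy: Anatomy
    subjects: list[SyntheticSubject]

    @property
    def ground_truth(self) -> dict:
        return {
            "true_extent_layers": self.spec.true_extent_layers,
            "alff_deficit_fraction": self.spec.alff_deficit_fraction,
            "reho_deficit_fraction": self.spec.reho_deficit_fraction,
            "deficit_extent_mm": self.spec.deficit_extent_mm,
            "seed": self.spec.seed,
        }

    def build_layers(self, **kw) -> LayerSet:
        return build_layers(self.anatomy.lesion, self.anatomy.gm, self.anatomy.hemis, **kw)


def expected_reho(weight: float) -> float:
    """Expected mean ReHo for a shared-signal mixing weight.

    There is no closed form for Kendall's W under the generator's signal
    model, so the mapping was calibrated empirically once under the
    default noise settings and frozen as a package data table; values are
    linearly interpolated.
    """
    import json
    from importlib import resources

    with resources.files("perishell").joinpath(
        "data/reho_weight_calibration.json"
    ).open() as fh:
        table = json.load(fh)["weight_to_mean_reho"]
    pairs = sorted((float(k), float(v)) for k, v in table.items())
    ws = np.array([p[0] for p in pairs])
    vals = np.array([p[1] for p in pairs])
    return float(np.interp(weight, ws, vals))


def simulate_subject(
    spec: CohortSpec, index: int, group: str = "patient", anatomy: Anatomy | None = None
) -> SyntheticSubject:
    """Generate subject ``index`` of the cohort, independent of cohort size.

    Per-subject RNG streams are spawned from one SeedSequence rooted at
    ``spec.seed``, so subject k's data never depend on how many subjects
    are generated around it.
    """
    spec.validate()
    if anatomy is None:
        anatomy = make_anatomy(spec)
    child = np.random.SeedSequence(spec.seed).spawn(index + 1)[index]
    rng = np.random.default_rng(child)
    fail = index in spec.qc_fail_subjects
    bold, motion = make_bold(spec, anatomy, rng, qc_fail=fail)
    return SyntheticSubject(
        subject_id=f"{group}-{index:03d}",
        group=group,
        bold=bold,
        motion=motion,
        resection=make_resection_mask(spec, anatomy),
        qc_fail_injected=fail,
    )


def simulate_cohort(
    spec: CohortSpec, group: str = "patient", anatomy: Anatomy | None = None
) -> SyntheticCohort:
    """Generate a full cohort deterministically from ``spec.seed``.

    Materializes every subject's 4D series in memory; for large cohorts
    prefer streaming one subject at a time via :func:`simulate_subject`.
    """
    spec.validate()
    if anatomy is None:
        anatomy = make_anatomy(spec)
    subjects = [
        simulate_subject(spec, i, group, anatomy) for i in range(spec.n_subjects)
    ]
    return SyntheticCohort(spec=spec, group=group, anatomy=anatomy, subjects=subjects)
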