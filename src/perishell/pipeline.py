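"""End-to-end orchestration: subject-level preprocessing and metric maps,
cohort-level layer statistics, and resection/outcome association.

The subject pipeline follows a fixed stage order::

    discard -> motion QC -> nuisance regression (Friston-24 + WM/CSF)
            -> linear detrend
            -> ALFF branch:  6-mm smoothing -> ALFF -> standardize
            -> ReHo branch:  0.01-0.1 Hz bandpass -> ReHo -> standardize
                             -> 6-mm smoothing within the mask

Subjects failing motion QC are marked excluded and not processed further;
a cohort run skips them and reports how many were dropped.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from .layers import LayerSet, build_layers
from .metrics import MetricMap, alff, reho, standardize
from .preprocess import (
    PreprocConfig,
    bandpass,
    build_nuisance,
    detrend_linear,
    discard_volumes,
    qc_motion,
    regress_nuisance,
    smooth,
)
from .resection import ResectionCase, classify_resection, outcome_association
from .simulate import CohortSpec, SyntheticSubject, make_anatomy, simulate_subject
from .stats import LayerProfile, PerilesionalLayerModel, PerilesionalLayerResults
from .volumes import BoldSeries, LabeledVolume, MotionTrace, require_alignment

log = logging.getLogger(__name__)

__all__ = [
    "SubjectInputs",
    "SubjectResult",
    "CohortResults",
    "run_subject",
    "run_cohort",
    "simulate_group_profiles",
    "RunManifest",
]


@dataclass
class SubjectInputs:
    """Aligned per-subject inputs for one pipeline run."""

    subject_id: str
    bold: BoldSeries
    motion: MotionTrace
    gm: LabeledVolume
    hemis: LabeledVolume
    lesion: LabeledVolume
    wm: LabeledVolume | None = None
    csf: LabeledVolume | None = None
    resection: LabeledVolume | None = None
    group: str = ""


@dataclass
class SubjectResult:
    subject_id: str
    status: str  # "ok" or "excluded:motion"
    profiles: dict[str, LayerProfile] = field(default_factory=dict)
    maps: dict[str, MetricMap] = field(default_factory=dict)


def _smooth_within_mask(metric_map: MetricMap, fwhm_mm: float) -> MetricMap:
    """Mask-normalized Gaussian smoothing of a metric map.

    Smoothing values and mask separately and taking their ratio prevents
    out-of-mask zeros from bleeding into edge voxels.
    """
    if fwhm_mm <= 0:
        return metric_map
    m = metric_map.mask.as_bool()
    vol = metric_map.mask.with_data(np.where(m, metric_map.values, 0.0).astype(np.float32))
    wgt = metric_map.mask.with_data(m.astype(np.float32))
    sv = smooth(vol, fwhm_mm).data
    sw = smooth(wgt, fwhm_mm).data
    out = np.zeros_like(sv)
    ok = sw > 1e-6
    out[ok] = sv[ok] / sw[ok]
    out[~m] = 0.0
    return MetricMap(out, metric_map.metric, metric_map.mask, metric_map.standardized)


def run_subject(
    inputs: SubjectInputs,
    layers: LayerSet,
    cfg: PreprocConfig | None = None,
    metrics: tuple[str, ...] = ("ALFF", "ReHo"),
    keep_maps: bool = False,
) -> SubjectResult:
    """Process one subject through preprocessing, metrics and layer means.

    Returns an excluded result (no profiles) when the motion trace breaks
    the 3 mm / 3 degree limits.
    """
    cfg = cfg or PreprocConfig()
    cfg.validate(inputs.bold.tr, inputs.bold.n_timepoints)
    require_alignment(inputs.bold, inputs.gm, inputs.hemis, inputs.lesion)

    if inputs.motion.n_timepoints != inputs.bold.n_timepoints:
        raise ValueError(
            f"motion trace has {inputs.motion.n_timepoints} rows but the "
            f"series has {inputs.bold.n_timepoints} volumes"
        )
    if not qc_motion(inputs.motion, cfg):
        log.info("subject %s excluded for head motion", inputs.subject_id)
        return SubjectResult(inputs.subject_id, "excluded:motion")

    brain = inputs.gm.as_bool() | inputs.lesion.as_bool()
    for extra in (inputs.wm, inputs.csf):
        if extra is not None:
            brain |= extra.as_bool()
    brain |= layers.union("ipsi") | layers.union("contra")
    mask = inputs.gm.with_data(brain.astype(np.uint8))

    series = discard_volumes(inputs.bold, cfg.n_discard)
    trace = inputs.motion.discard(cfg.n_discard)
    nuis = build_nuisance(
        trace, series, wm_mask=inputs.wm, csf_mask=inputs.csf, friston24=cfg.friston24
    )
    series = detrend_linear(regress_nuisance(series, nuis, mask=brain), mask=brain)

    def _standardize(mmap: MetricMap) -> MetricMap:
        if not cfg.standardize_gm_only:
            return standardize(mmap)
        g = inputs.gm.as_bool() & mmap.mask.as_bool()
        gmean = float(mmap.values[g].mean())
        if gmean <= 0:
            raise ValueError("GM global mean is not positive; cannot standardize")
        values = np.where(mmap.mask.as_bool(), mmap.values / gmean, 0.0)
        return MetricMap(values.astype(np.float32), mmap.metric, mmap.mask, True)

    result = SubjectResult(inputs.subject_id, "ok")
    if "ALFF" in metrics:
        alff_series = smooth(series, cfg.fwhm_mm)
        amap = _standardize(alff(alff_series, mask, band=cfg.band))
        result.profiles["ALFF"] = _profile(amap, layers, inputs)
        if keep_maps:
            result.maps["ALFF"] = amap
    if "ReHo" in metrics:
        reho_in = smooth(series, cfg.fwhm_mm) if cfg.smooth_before_reho else series
        rmap = _standardize(reho(bandpass(reho_in, cfg.band), mask))
        rmap = _smooth_within_mask(rmap, cfg.fwhm_mm)
        result.profiles["ReHo"] = _profile(rmap, layers, inputs)
        if keep_maps:
            result.maps["ReHo"] = rmap
    return result


def _profile(metric_map: MetricMap, layers: LayerSet, inputs: SubjectInputs) -> LayerProfile:
    from .stats import extract_profile

    return extract_profile(
        metric_map, layers, subject_id=inputs.subject_id, group=inputs.group
    )


@dataclass
class CohortResults:
    """Bundle of cohort-level outputs."""

    results: PerilesionalLayerResults
    subject_status: dict[str, str]
    resection_table: pd.DataFrame | None = None
    association: dict | None = None

    @property
    def n_excluded(self) -> int:
        return sum(1 for s in self.subject_status.values() if s != "ok")

    def extent_summary(self) -> dict:
        return self.results.extent_summary()


def run_cohort(
    subject_inputs: list[SubjectInputs],
    layers: LayerSet,
    cfg: PreprocConfig | None = None,
    metrics: tuple[str, ...] = ("ALFF", "ReHo"),
    seizure_free: dict[str, bool] | None = None,
    min_per_group: int = 3,
) -> CohortResults:
    """Run every subject, fit the layer model, and (when resection masks and
    outcomes are present) classify completeness and test its association
    with seizure freedom using the group-level abnormal ALFF extent."""
    cfg = cfg or PreprocConfig()
    profiles: list[LayerProfile] = []
    status: dict[str, str] = {}
    by_subject: dict[str, SubjectInputs] = {}
    for inp in subject_inputs:
        res = run_subject(inp, layers, cfg, metrics=metrics)
        status[inp.subject_id] = res.status
        by_subject[inp.subject_id] = inp
        profiles.extend(res.profiles.values())

    groups = {p.group for p in profiles}
    for g in groups:
        n = len({p.subject_id for p in profiles if p.group == g})
        if n < min_per_group:
            raise ValueError(f"group {g!r} has only {n} usable subjects (<{min_per_group})")

    model = PerilesionalLayerModel(profiles)
    fitted = model.fit()

    resection_table = None
    association = None
    if seizure_free is not None:
        rows = []
        cases, classes = [], []
        metric = "ALFF" if "ALFF" in metrics else metrics[0]
        for sid, inp in by_subject.items():
            if inp.resection is None or status[sid] != "ok" or sid not in seizure_free:
                continue
            extent = fitted.extent(metric, inp.group)
            case = ResectionCase(sid, inp.resection, extent, seizure_free[sid])
            cls = classify_resection(case, layers)
            cases.append(case)
            classes.append(cls)
            rows.append(
                dict(subject=sid, group=inp.group, extent=extent,
                     classification=cls, seizure_free=seizure_free[sid])
            )
        if rows:
            resection_table = pd.DataFrame(rows)
            assoc = outcome_association(cases, classes)
            association = dict(
                table=assoc.table.tolist(),
                statistic=assoc.statistic,
                p_value=assoc.p_value,
                method=assoc.method,
            )
    return CohortResults(fitted, status, resection_table, association)


def simulate_group_profiles(
    spec: CohortSpec,
    group: str = "patient",
    metrics: tuple[str, ...] = ("ALFF",),
    cfg: PreprocConfig | None = None,
    anatomy=None,
    layers: LayerSet | None = None,
) -> list[LayerProfile]:
    """Simulate one group and push every subject through the full pipeline.

    Streams subjects one at a time (one 4D series in memory at once) and
    reuses the shared anatomy and layer masks; returns the per-subject
    layer profiles of QC-passing subjects.
    """
    if anatomy is None:
        anatomy = make_anatomy(spec)
    if layers is None:
        layers = build_layers(anatomy.lesion, anatomy.gm, anatomy.hemis)
    cfg = cfg or PreprocConfig()
    profiles: list[LayerProfile] = []
    for i in range(spec.n_subjects):
        subj = simulate_subject(spec, i, group, anatomy)
        inputs = SubjectInputs(
            subject_id=subj.subject_id,
            bold=subj.bold,
            motion=subj.motion,
            gm=anatomy.gm,
            hemis=anatomy.hemis,
            lesion=anatomy.lesion,
            wm=anatomy.wm,
            csf=anatomy.csf,
            resection=subj.resection,
            group=group,
        )
        res = run_subject(inputs, layers, cfg, metrics=metrics)
        profiles.extend(res.profiles.values())
    return profiles


@dataclass
class RunManifest:
    """Reproducibility record for a pipeline run."""

    config: dict
    seed: int | None = None
    version: str = _version
    subject_status: dict[str, str] = field(default_factory=dict)
    files: dict[str, str] = field(default_factory=dict)  # path -> sha256

    def add_file(self, path: str | Path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.files[str(path)] = digest

    def write(self, path: str | Path) -> Path:
        payload = dict(
            version=self.version,
            seed=self.seed,
            config=self.config,
            subject_status=self.subject_status,
            files=self.files,
        )
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
        return Path(path)
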