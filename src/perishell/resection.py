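"""Resection-completeness classification and its association with outcome.

A subject's functional abnormality is summarized by the group-level
abnormal extent L (outermost contiguous significant layer, from
:mod:`perishell.stats`).  Resection is *complete* when every voxel of the
lesion together with layers 1..L lies inside the post-operative resection
mask, and *incomplete* when any abnormal voxel extends beyond the margins;
L = 0 reduces to a lesion-only check.  Across subjects, completeness is
cross-tabulated against seizure freedom (Engel class I) and tested with an
uncorrected chi-square, falling back to Fisher's exact test when any
expected cell count drops below 5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .layers import LayerSet
from .volumes import LabeledVolume, require_alignment

__all__ = [
    "ResectionCase",
    "AssociationResult",
    "classify_resection",
    "outcome_association",
]


@dataclass
class ResectionCase:
    """Per-subject resection data: mask, abnormal extent, seizure outcome."""

    subject_id: str
    resection_mask: LabeledVolume
    abnormal_extent_layers: int
    seizure_free: bool

    def __post_init__(self) -> None:
        if not 0 <= self.abnormal_extent_layers <= 10:
            raise ValueError("abnormal extent must be within 0..10 layers")


@dataclass
class AssociationResult:
    """2x2 association between completeness and seizure freedom."""

    table: np.ndarray  # rows: complete/incomplete; cols: seizure-free/not
    statistic: float
    p_value: float
    method: str  # "chi-square", "fisher-exact" or "undefined"

    @property
    def defined(self) -> bool:
        return self.method != "undefined"


def classify_resection(case: ResectionCase, layers: LayerSet) -> str:
    """"complete" iff lesion plus layers 1..L lie entirely inside the resection.

    Monotone in the resection mask: enlarging it can never turn a complete
    case incomplete.
    """
    require_alignment(case.resection_mask, layers.lesion)
    res = case.resection_mask.as_bool()
    if not res.any():
        raise ValueError("resection mask is empty")
    abnormal = layers.lesion.as_bool() | layers.union(
        "ipsi", through_layer=case.abnormal_extent_layers
    )
    return "complete" if bool((abnormal & ~res).sum() == 0) else "incomplete"


def outcome_association(
    cases: list[ResectionCase],
    classifications: list[str],
) -> AssociationResult:
    """Chi-square (no continuity correction) of completeness vs seizure freedom.

    ``classifications`` pairs with ``cases`` (output of
    :func:`classify_resection`).  When any expected cell count is below 5
    the Fisher exact test is reported instead; degenerate margins (all
    cases in one row or column) leave the association undefined.
    """
    if len(cases) != len(classifications):
        raise ValueError("cases and classifications must pair up")
    table = np.zeros((2, 2), dtype=int)
    for case, cls in zip(cases, classifications):
        i = 0 if cls == "complete" else 1
        j = 0 if case.seizure_free else 1
        table[i, j] += 1
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        return AssociationResult(table, float("nan"), float("nan"), "undefined")
    expected = sps.contingency.expected_freq(table)
    if (expected < 5).any():
        odds, p = sps.fisher_exact(table)
        return AssociationResult(table, float(odds), float(p), "fisher-exact")
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return AssociationResult(table, float(chi2), float(p), "chi-square")
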