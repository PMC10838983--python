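"""Layer-wise statistics: per-layer metric profiles, paired and two-sample
tests with Bonferroni correction, volume-metric correlation, and the
perilesional layer model / results pair.

The central comparison is, for each of the 10 layers, a two-sided paired
t-test of the ipsilateral layer mean against the contralateral homotopic
layer mean across subjects, with the family alpha of 0.05 divided by the
number of layers (0.05 / 10 = 0.005).  The extent of abnormality is
summarized as the outermost layer of the contiguous significant run
starting at layer 1.

:class:`PerilesionalLayerModel` packages a cohort of
:class:`LayerProfile` rows the way statsmodels packages endog/exog: build
the model from profiles (or a tidy DataFrame), call :meth:`fit`, and read
estimates, per-layer tests and extents off the returned
:class:`PerilesionalLayerResults`, whose ``summary()`` prints a compact
table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .layers import LayerSet
from .metrics import MetricMap
from .volumes import require_alignment

__all__ = [
    "LayerProfile",
    "LayerTestResult",
    "extract_profile",
    "paired_layer_test",
    "group_layer_test",
    "volume_metric_correlation",
    "significant_extent",
    "proportion_percent",
    "PerilesionalLayerModel",
    "PerilesionalLayerResults",
]

DEFAULT_FAMILY_ALPHA = 0.05


def proportion_percent(count: int, total: int, ndigits: int = 1) -> float:
    """Percentage of ``count`` out of ``total`` rounded to ``ndigits``."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, ndigits)


@dataclass
class LayerProfile:
    """Per-subject vector of layer means for one metric.

    ``ipsi_means[k]`` / ``contra_means[k]`` hold the mean of the
    standardized metric map over layer k+1; layers with no voxels are
    recorded in ``empty_layers`` (1-based indices) and carry NaN means.
    """

    subject_id: str
    metric: str
    ipsi_means: np.ndarray
    contra_means: np.ndarray
    group: str = ""
    empty_layers: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        self.ipsi_means = np.asarray(self.ipsi_means, dtype=float)
        self.contra_means = np.asarray(self.contra_means, dtype=float)
        if self.ipsi_means.shape != self.contra_means.shape:
            raise ValueError("ipsi and contra mean vectors differ in length")

    @property
    def n_layers(self) -> int:
        return len(self.ipsi_means)


@dataclass
class LayerTestResult:
    """One layer's test: t statistic, raw p, corrected alpha, significance."""

    layer: int
    t_stat: float
    p_raw: float
    alpha_corrected: float
    significant: bool
    n_subjects: int
    note: str = ""


def extract_profile(
    metric_map: MetricMap,
    layers: LayerSet,
    subject_id: str = "",
    group: str = "",
) -> LayerProfile:
    """Mean of a standardized metric map over each ipsi and contra layer.

    Layer masks are further intersected with the map's own analysis mask,
    so voxels the metric left undefined (e.g. isolated ReHo voxels) do not
    enter the means.  Empty layers yield NaN and are flagged.
    """
    require_alignment(metric_map.mask, layers.lesion)
    valid = metric_map.mask.as_bool()
    empty: set[int] = set()

    def _means(masks: list[np.ndarray]) -> np.ndarray:
        out = np.full(len(masks), np.nan)
        for i, m in enumerate(masks):
            mm = m & valid
            if mm.any():
                out[i] = float(metric_map.values[mm].mean())
            else:
                empty.add(i + 1)
        return out

    ipsi = _means(layers.ipsi_layers)
    contra = _means(layers.contra_layers)
    return LayerProfile(
        subject_id=subject_id,
        metric=metric_map.metric,
        ipsi_means=ipsi,
        contra_means=contra,
        group=group,
        empty_layers=frozenset(empty),
    )


def _finite_pairs(profiles: list[LayerProfile], layer: int) -> tuple[np.ndarray, np.ndarray]:
    k = layer - 1
    ipsi = np.array([p.ipsi_means[k] for p in profiles])
    contra = np.array([p.contra_means[k] for p in profiles])
    ok = np.isfinite(ipsi) & np.isfinite(contra)
    return ipsi[ok], contra[ok]


def paired_layer_test(
    profiles: list[LayerProfile],
    layer: int,
    family_alpha: float = DEFAULT_FAMILY_ALPHA,
    n_comparisons: int = 10,
) -> LayerTestResult:
    """Two-sided paired t-test of ipsi vs contra layer means at one layer.

    Subjects with an empty layer on either side are excluded pairwise.
    Significance uses the Bonferroni-corrected threshold
    family_alpha / n_comparisons (0.005 at defaults), with strict
    inequality p < alpha.  Zero variance of the differences leaves t
    undefined and the layer non-significant, with a note.
    """
    ipsi, contra = _finite_pairs(profiles, layer)
    n = len(ipsi)
    alpha = family_alpha / n_comparisons
    if n < 3:
        return LayerTestResult(layer, math.nan, math.nan, alpha, False, n, "n < 3")
    diff = ipsi - contra
    if np.allclose(diff.std(ddof=1), 0):
        note = "zero-variance differences; t undefined"
        p = 1.0 if np.allclose(diff, 0) else math.nan
        return LayerTestResult(layer, math.nan if diff.mean() else 0.0, p, alpha, False, n, note)
    t_stat, p = sps.ttest_rel(ipsi, contra)
    return LayerTestResult(layer, float(t_stat), float(p), alpha, bool(p < alpha), n)


def group_layer_test(
    profiles_a: list[LayerProfile],
    profiles_b: list[LayerProfile],
    layer: int,
    family_alpha: float = DEFAULT_FAMILY_ALPHA,
    n_comparisons: int = 10,
    welch: bool = False,
) -> LayerTestResult:
    """Two-sided two-sample t-test on ipsilateral layer means between groups.

    Student's pooled-variance form by default (``welch=True`` switches to
    the unequal-variance test); Bonferroni threshold as in
    :func:`paired_layer_test`.
    """
    k = layer - 1
    a = np.array([p.ipsi_means[k] for p in profiles_a])
    b = np.array([p.ipsi_means[k] for p in profiles_b])
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    alpha = family_alpha / n_comparisons
    n = len(a) + len(b)
    if min(len(a), len(b)) < 3:
        return LayerTestResult(layer, math.nan, math.nan, alpha, False, n, "group n < 3")
    if np.allclose(np.concatenate([a - a.mean(), b - b.mean()]), 0):
        if np.allclose(a.mean(), b.mean()):
            return LayerTestResult(layer, 0.0, 1.0, alpha, False, n, "zero variance")
        return LayerTestResult(
            layer, math.inf, 0.0, alpha, True, n, "zero variance, separated groups"
        )
    t_stat, p = sps.ttest_ind(a, b, equal_var=not welch)
    return LayerTestResult(layer, float(t_stat), float(p), alpha, bool(p < alpha), n)


def volume_metric_correlation(
    profiles: list[LayerProfile], log_volumes: list[float] | np.ndarray, layer: int
) -> tuple[float, float]:
    """Pearson correlation of ipsilateral layer means with log lesion volumes.

    Returns (r, two-sided p); constant inputs leave r undefined (NaN).
    """
    k = layer - 1
    x = np.asarray(log_volumes, dtype=float)
    y = np.array([p.ipsi_means[k] for p in profiles])
    if len(x) != len(y):
        raise ValueError("volumes and profiles must be paired")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 4:
        raise ValueError("need at least 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan, math.nan
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def significant_extent(results: list[LayerTestResult]) -> int:
    """Outermost layer of the contiguous significant run starting at layer 1.

    Returns 0 when layer 1 itself is not significant.  Non-contiguous
    patterns (e.g. T, F, T) are truncated at the first gap; the full
    pattern remains available on the individual results.
    """
    ordered = sorted(results, key=lambda r: r.layer)
    extent = 0
    for r in ordered:
        if r.layer != extent + 1 or not r.significant:
            break
        extent = r.layer
    return extent


class PerilesionalLayerModel:
    """Layer-profile cohort model, statsmodels-style.

    Parameters
    ----------
    profiles : list of LayerProfile
        One row per subject x metric.
    log_volumes : mapping subject_id -> log10 normalized lesion volume, optional
        Enables the volume-metric correlation battery.

    Use :meth:`from_dataframe` for a tidy table with columns
    ``subject, group, metric, layer, ipsi_mean, contra_mean``.
    """

    def __init__(
        self,
        profiles: list[LayerProfile],
        log_volumes: dict[str, float] | None = None,
        family_alpha: float = DEFAULT_FAMILY_ALPHA,
    ):
        if not profiles:
            raise ValueError("no profiles supplied")
        self.profiles = list(profiles)
        self.log_volumes = dict(log_volumes) if log_volumes else None
        self.family_alpha = family_alpha
        self.n_layers = profiles[0].n_layers
        if any(p.n_layers != self.n_layers for p in profiles):
            raise ValueError("profiles disagree on the number of layers")
        self.metrics = sorted({p.metric for p in profiles})
        self.groups = sorted({p.group for p in profiles})

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, log_volumes: dict[str, float] | None = None, **kw
    ) -> "PerilesionalLayerModel":
        required = {"subject", "group", "metric", "layer", "ipsi_mean", "contra_mean"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        profiles = []
        for (subj, grp, metric), sub in df.groupby(["subject", "group", "metric"]):
            sub = sub.sort_values("layer")
            profiles.append(
                LayerProfile(
                    subject_id=str(subj),
                    metric=str(metric),
                    ipsi_means=sub["ipsi_mean"].to_numpy(),
                    contra_means=sub["contra_mean"].to_numpy(),
                    group=str(grp),
                    empty_layers=frozenset(
                        int(l) for l, v in zip(sub["layer"], sub["ipsi_mean"]) if not np.isfinite(v)
                    ),
                )
            )
        return cls(profiles, log_volumes=log_volumes, **kw)

    def subset(self, metric: str | None = None, group: str | None = None) -> list[LayerProfile]:
        out = self.profiles
        if metric is not None:
            out = [p for p in out if p.metric == metric]
        if group is not None:
            out = [p for p in out if p.group == group]
        return out

    def fit(self, welch: bool = False) -> "PerilesionalLayerResults":
        """Run the full layer-wise battery; returns a results object."""
        paired: dict[tuple[str, str], list[LayerTestResult]] = {}
        extents: dict[tuple[str, str], int] = {}
        for metric in self.metrics:
            for group in self.groups:
                profs = self.subset(metric, group)
                res = [
                    paired_layer_test(profs, k, self.family_alpha, self.n_layers)
                    for k in range(1, self.n_layers + 1)
                ]
                paired[(metric, group)] = res
                extents[(metric, group)] = significant_extent(res)

        between: dict[tuple[str, str, str], list[LayerTestResult]] = {}
        for metric in self.metrics:
            for i, ga in enumerate(self.groups):
                for gb in self.groups[i + 1 :]:
                    pa, pb = self.subset(metric, ga), self.subset(metric, gb)
                    between[(metric, ga, gb)] = [
                        group_layer_test(pa, pb, k, self.family_alpha, self.n_layers, welch)
                        for k in range(1, self.n_layers + 1)
                    ]

        correlations: dict[tuple[str, str, int], tuple[float, float]] = {}
        if self.log_volumes:
            for metric in self.metrics:
                for group in self.groups:
                    profs = [p for p in self.subset(metric, group) if p.subject_id in self.log_volumes]
                    vols = [self.log_volumes[p.subject_id] for p in profs]
                    if len(profs) < 4:
                        continue
                    for k in range(1, self.n_layers + 1):
                        try:
                            correlations[(metric, group, k)] = volume_metric_correlation(
                                profs, vols, k
                            )
                        except ValueError:
                            pass

        return PerilesionalLayerResults(self, paired, between, extents, correlations)


class PerilesionalLayerResults:
    """Fitted layer-wise statistics with tidy accessors and a summary table."""

    def __init__(self, model, paired, between, extents, correlations):
        self.model = model
        self.paired_tests = paired
        self.between_tests = between
        self.extents = extents
        self.correlations = correlations

    def paired_frame(self) -> pd.DataFrame:
        """Tidy per-layer paired-test table (metric, group, layer, n, t, p, ...)."""
        rows = []
        for (metric, group), results in self.paired_tests.items():
            for r in results:
                rows.append(
                    dict(
                        metric=metric,
                        group=group,
                        layer=r.layer,
                        n=r.n_subjects,
                        t=r.t_stat,
                        p=r.p_raw,
                        alpha_corrected=r.alpha_corrected,
                        significant=r.significant,
                    )
                )
        return pd.DataFrame(rows)

    def between_frame(self) -> pd.DataFrame:
        rows = []
        for (metric, ga, gb), results in self.between_tests.items():
            for r in results:
                rows.append(
                    dict(
                        metric=metric,
                        group_a=ga,
                        group_b=gb,
                        layer=r.layer,
                        n=r.n_subjects,
                        t=r.t_stat,
                        p=r.p_raw,
                        alpha_corrected=r.alpha_corrected,
                        significant=r.significant,
                    )
                )
        return pd.DataFrame(rows)

    def extent(self, metric: str, group: str) -> int:
        return self.extents[(metric, group)]

    def extent_summary(self) -> dict[str, dict[str, int]]:
        out: dict[str, dict[str, int]] = {}
        for (metric, group), ext in self.extents.items():
            out.setdefault(metric, {})[group] = ext
        return out

    def summary(self) -> str:
        """Readable per-metric/group table of layer tests and extents."""
        lines = ["Perilesional layer-wise statistics"]
        lines.append(
            f"  layers: {self.model.n_layers}, family alpha {self.model.family_alpha}, "
            f"per-layer alpha {self.model.family_alpha / self.model.n_layers:g}"
        )
        for (metric, group), results in sorted(self.paired_tests.items()):
            ext = self.extents[(metric, group)]
            lines.append(f"\n{metric} | group {group or '(all)'} | abnormal extent: "
                         f"layers 1-{ext}" if ext else
                         f"\n{metric} | group {group or '(all)'} | abnormal extent: none")
            lines.append("  layer     n        t        p   sig")
            for r in results:
                t = "nan" if not np.isfinite(r.t_stat) else f"{r.t_stat:8.3f}"
                p = "nan" if not np.isfinite(r.p_raw) else f"{r.p_raw:8.5f}"
                lines.append(
                    f"  {r.layer:5d} {r.n_subjects:5d} {t:>8s} {p:>8s}   {'*' if r.significant else ''}"
                )
        return "\n".join(lines)

    def plot_profiles(self, metric: str, group: str | None = None, ax=None):
        """Layer-profile plot (ipsi vs contra mean +- SEM) for one metric."""
        from .plotting import plot_layer_profiles

        return plot_layer_profiles(
            self.model.subset(metric, group), metric=metric, ax=ax,
            extent=self.extents.get((metric, group or "")),
        )
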