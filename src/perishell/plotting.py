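"""Layer-profile figures: ipsilateral vs contralateral means across the
ten perilesional shells, with the abnormal extent shaded."""

from __future__ import annotations

import numpy as np

from .stats import LayerProfile

__all__ = ["plot_layer_profiles"]


def plot_layer_profiles(
    profiles: list[LayerProfile],
    metric: str = "",
    ax=None,
    extent: int | None = None,
):
    """Mean +- SEM of ipsi and contra layer means across subjects.

    Returns the matplotlib axes; creates a figure when ``ax`` is None.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    if not profiles:
        raise ValueError("no profiles to plot")
    n_layers = profiles[0].n_layers
    layers = np.arange(1, n_layers + 1)
    ipsi = np.array([p.ipsi_means for p in profiles])
    contra = np.array([p.contra_means for p in profiles])
    n = ipsi.shape[0]
    for data, label, color in ((ipsi, "ipsilateral", "tab:red"),
                               (contra, "contralateral homotopic", "tab:blue")):
        mean = np.nanmean(data, axis=0)
        sem = np.nanstd(data, axis=0, ddof=1) / np.sqrt(n)
        ax.errorbar(layers, mean, yerr=sem, marker="o", capsize=3,
                    label=label, color=color)
    if extent:
        ax.axvspan(0.5, extent + 0.5, color="0.85", zorder=0,
                   label=f"abnormal extent (layers 1-{extent})")
    ax.set_xlabel("perilesional GM layer (2 mm each)")
    ax.set_ylabel(f"standardized {metric or profiles[0].metric}")
    ax.set_xticks(layers)
    ax.legend(frameon=False, fontsize=8)
    return ax
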