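"""Optional matplotlib figures (estimated-vs-measured, delta-AUC boxes).

matplotlib is imported lazily so the core library and CLI work without it.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np


def plot_estimated_vs_measured(reports: Mapping[str, "ValidationReport"], ax=None):
    """Scatter of estimated vs measured AUC per stratum with fit lines."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    lims = [np.inf, -np.inf]
    for stratum, rep in reports.items():
        if rep.measured is None:
            continue
        ax.scatter(rep.measured, rep.estimated, s=18, alpha=0.7,
                   label=f"{stratum} (R$^2$={rep.r2:.2f})")
        xs = np.linspace(rep.measured.min(), rep.measured.max(), 2)
        ax.plot(xs, rep.fit_slope * xs + rep.fit_intercept, lw=1)
        lims[0] = min(lims[0], rep.measured.min(), rep.estimated.min())
        lims[1] = max(lims[1], rep.measured.max(), rep.estimated.max())
    ax.plot(lims, lims, "k:", lw=1, label="identity")
    ax.set_xlabel("measured AUC$_{0-12}$ (ug h/mL)")
    ax.set_ylabel("estimated AUC$_{0-12}$ (ug h/mL)")
    ax.legend(fontsize=8)
    return ax


def plot_delta_comparison(delta_section: dict, ax=None):
    """Bar summary of the Method A vs Method B |dAUC| medians."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    labels = ["Method A", "Method B"]
    medians = [delta_section["method_a"]["median"],
               delta_section["method_b"]["median"]]
    tops = [delta_section["method_a"]["max"], delta_section["method_b"]["max"]]
    ax.bar(labels, medians, color=["#888", "#4477aa"])
    ax.errorbar(labels, medians, yerr=[[0, 0], np.subtract(tops, medians)],
                fmt="none", ecolor="k", capsize=4)
    ax.set_ylabel("|estimated - measured| AUC$_{0-12}$ (ug h/mL)")
    ax.set_title(f"Wilcoxon p = {delta_section['wilcoxon_p']:.3g}")
    return ax
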