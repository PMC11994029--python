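"""Diagnostic plots: RGR by treatment with the RGR = 1 stability
threshold, and the single- vs co-invasion scatter with its 1-1 line."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_rgr_by_treatment", "plot_single_vs_co"]


def plot_rgr_by_treatment(rgr_table, calls=None, ax=None):
    """Replicate RGRs per treatment, grouped by focal species, with the
    RGR = 1 invasion-criterion threshold drawn."""
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 4))
    order = (
        rgr_table.drop_duplicates("treatment_id")
        .sort_values(["focal", "treatment_id"])["treatment_id"]
        .tolist()
    )
    pos = {tid: i for i, tid in enumerate(order)}
    x = rgr_table["treatment_id"].map(pos)
    ax.scatter(x, rgr_table["rgr"], s=12, alpha=0.6, color="tab:blue")
    if calls is not None:
        cx = calls["treatment_id"].map(pos)
        colors = np.where(calls["stable"], "tab:green", "tab:red")
        ax.scatter(cx, calls["mean_rgr"], s=30, marker="_", color=colors)
    ax.axhline(1.0, color="black", lw=1, ls="--")
    ax.set_xlabel("treatment (grouped by focal species)")
    ax.set_ylabel("relative invader growth rate")
    ax.set_xticks([])
    return ax


def plot_single_vs_co(means, ax=None):
    """Mean co-invasion RGR against mean single-invasion RGR per species,
    with the 1-1 line a perfectly predictive single assay would follow."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    for species, grp in means.groupby("species"):
        ax.scatter(grp["mean_rgr_single"], grp["mean_rgr_co"], label=species, s=20)
    lo = min(means["mean_rgr_single"].min(), means["mean_rgr_co"].min())
    hi = max(means["mean_rgr_single"].max(), means["mean_rgr_co"].max())
    ax.plot([lo, hi], [lo, hi], color="black", lw=1, ls="--", label="1–1")
    ax.set_xlabel("mean RGR, single invasion")
    ax.set_ylabel("mean RGR, co-invasion")
    ax.legend(fontsize=8)
    return ax
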