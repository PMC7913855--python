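"""Minimal plotting helpers (dendrogram and estimated-vs-recorded traces).

matplotlib is imported lazily so the analysis pipeline has no hard plotting
dependency.
"""

from __future__ import annotations

import numpy as np


def plot_dendrogram(linkage_tree: np.ndarray, cut_distance: float | None = None, ax=None):
    """Dendrogram of the pooled-synergy merge tree (heights in degrees)."""
    import matplotlib.pyplot as plt
    from scipy.cluster import hierarchy

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 4))
    hierarchy.dendrogram(linkage_tree, ax=ax, no_labels=True, color_threshold=cut_distance)
    if cut_distance is not None:
        ax.axhline(cut_distance, ls=":", c="k", lw=1)
    ax.set_ylabel("inter-synergy angle (deg)")
    ax.set_xlabel("pooled components")
    return ax


def plot_traces(trace_df, dofs=None, axes=None):
    """Estimated vs recorded angle traces from an ``export_traces`` table."""
    import matplotlib.pyplot as plt

    dofs = dofs or sorted(trace_df["dof"].unique())
    if axes is None:
        _, axes = plt.subplots(len(dofs), 1, sharex=True, figsize=(8, 2 * len(dofs)))
        axes = np.atleast_1d(axes)
    for ax, dof in zip(axes, dofs):
        sub = trace_df[trace_df["dof"] == dof]
        ax.plot(sub["frame"], sub["recorded"], label="recorded", lw=1)
        ax.plot(sub["frame"], sub["estimated"], label="estimated", lw=1, ls="--")
        ax.set_ylabel(f"{dof} (deg)")
    axes[0].legend(loc="upper right", fontsize="small")
    axes[-1].set_xlabel("frame")
    return axes
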