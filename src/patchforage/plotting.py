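"""Minimal plotting helpers for tracks and preference curves."""
from __future__ import annotations

import numpy as np

STATE_COLORS = {"F": "tab:green", "B": "tab:orange", "O": "tab:blue"}


def plot_track(track, labels=None, ax=None):
    """Centroid trajectory over the well and patch outline, coloured by state."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    well = track.arena.well.exterior.xy
    patch = track.arena.patch.exterior.xy
    ax.plot(*well, color="0.6", lw=1)
    ax.plot(*patch, color="0.3", lw=1)
    xy = track.centroid
    if labels is None:
        ax.plot(xy[:, 0], xy[:, 1], lw=0.5, color="tab:blue")
    else:
        labels = np.asarray(labels)
        for state, color in STATE_COLORS.items():
            m = labels == state
            ax.scatter(xy[m, 0], xy[m, 1], s=1, color=color, label=state)
        ax.legend(markerscale=6, fontsize=8)
    ax.set_aspect("equal")
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    ax.set_title(track.worm_id)
    return ax


def plot_preference_curve(curve, model=None, ax=None):
    """Mean preference index vs elongated-food OD, with model expectation."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    od = np.asarray(curve["od"], float)
    mean = np.asarray(curve["mean"], float)
    if {"ci_low", "ci_high"}.issubset(curve.columns):
        yerr = np.vstack([mean - curve["ci_low"], curve["ci_high"] - mean])
        ax.errorbar(od, mean, yerr=yerr, fmt="o", capsize=3)
    else:
        ax.plot(od, mean, "o")
    if model is not None:
        grid = np.linspace(od.min(), od.max(), 200)
        ax.plot(grid, [model.expected_preference(1.0, g) for g in grid],
                color="0.4", lw=1, label=f"model d={model.d:.3g}")
        ax.legend(fontsize=8)
    ax.axhline(0.0, color="0.8", lw=1)
    ax.set_xlabel("elongated food OD")
    ax.set_ylabel("preference index I")
    return ax
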