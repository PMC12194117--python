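"""Diagnostic plots for trial records and fitted effects."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_effects", "plot_trajectories", "plot_decomposition_raster"]


def plot_effects(results, ax=None):
    """Forest plot of every effect estimate with its 95% CI."""
    import matplotlib.pyplot as plt

    eff = results.effects
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 0.35 * len(eff) + 1))
    y = np.arange(len(eff))[::-1]
    ax.hlines(y, eff["ci_low"], eff["ci_high"], color="0.4")
    ax.plot(eff["estimate"], y, "o", color="tab:blue")
    ax.axvline(0, color="0.8", lw=1, zorder=0)
    ax.set_yticks(y)
    ax.set_yticklabels(eff["label"], fontsize=8)
    ax.set_xlabel("estimate (95% CI)")
    return ax


def plot_trajectories(trials, ax=None, max_trials=40):
    """Aligned hand paths (start at origin, endpoint on +Y), one line each."""
    import matplotlib.pyplot as plt

    from .metrics import align_and_rotate

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    for tr in trials[:max_trials]:
        tr.detect_onset()
        aligned = align_and_rotate(tr.hand.pos[tr.onset_index:])
        ax.plot(aligned.xy[:, 0], aligned.xy[:, 1], lw=0.7, alpha=0.6)
    ax.axvline(0, color="0.85", lw=1, zorder=0)
    ax.set_xlabel("perpendicular deviation (m)")
    ax.set_ylabel("along-axis progress (m)")
    ax.set_aspect("equal")
    return ax


def plot_decomposition_raster(trials, ax=None, **raster_kw):
    """Binary decomposition raster, one row per trial (normalized time)."""
    import matplotlib.pyplot as plt

    from .metrics import decomposition_raster

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    rows = [decomposition_raster(tr, **raster_kw) for tr in trials]
    ax.imshow(np.array(rows), aspect="auto", cmap="Greys",
              interpolation="nearest", extent=(0, 1, len(rows), 0))
    ax.set_xlabel("normalized movement time")
    ax.set_ylabel("trial")
    return ax
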