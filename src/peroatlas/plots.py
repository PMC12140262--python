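"""Raster and stage-boxplot figures."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .features import STAGE_ORDER, raster_matrix

__all__ = ["plot_raster", "plot_stage_boxes"]


def plot_raster(binned_one_animal, ax=None, cmap="inferno"):
    """Raster of 20-min binned minima: one column per day (noon-to-noon),
    row 0 (= 12:00) at the bottom so the active phase is centred; missing
    bins render white."""
    mat, days = raster_matrix(binned_one_animal)
    if ax is None:
        _, ax = plt.subplots(figsize=(0.18 * len(days) + 2, 4))
    masked = np.ma.masked_invalid(mat)
    cm = plt.get_cmap(cmap).copy()
    cm.set_bad("white")
    im = ax.imshow(masked, aspect="auto", origin="lower", cmap=cm,
                   interpolation="nearest")
    ax.set_xlabel("day")
    ax.set_ylabel("time of day (rows from 12:00)")
    ax.set_yticks([0, 18, 36, 54, 71])
    ax.set_yticklabels(["12:00", "18:00", "00:00", "06:00", "11:40"])
    plt.colorbar(im, ax=ax, label="20-min min temp (°C)")
    return ax


def plot_stage_boxes(daily, response="min", letters=None, ax=None):
    """Boxplots of daily extrema by reproductive stage with optional
    compact-letter annotations."""
    col = {"min": "daily_min", "max": "daily_max"}[response]
    stages = [s.value for s in STAGE_ORDER
              if s.value in set(daily["stage"])]
    data = [daily.loc[daily["stage"] == s, col].to_numpy() for s in stages]
    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * len(stages) + 1, 4))
    ax.boxplot(data, tick_labels=[s.replace("_", "\n").lower() for s in stages])
    if letters:
        for i, s in enumerate(stages, start=1):
            top = data[i - 1].max() if data[i - 1].size else 0
            ax.text(i, top + 0.06, letters.get(s, ""), ha="center",
                    fontsize=11, fontstyle="italic")
    ax.set_ylabel(f"daily {response} temperature (°C)")
    return ax
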