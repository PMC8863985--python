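"""Figures for tract profiles and development maps (matplotlib)."""

from __future__ import annotations

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .profiles import TractProfile

__all__ = ["plot_profiles_by_timepoint", "plot_development_map",
           "plot_slope_vs_newborn"]

_TP_STYLE = {"0m": ":", "3m": "--", "6m": "-"}


def plot_profiles_by_timepoint(profiles: dict[str, TractProfile],
                               ax: plt.Axes | None = None,
                               title: str | None = None) -> plt.Axes:
    """Profile lines per timepoint (dotted newborn, dashed 3 m, solid 6 m)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    for tp, prof in sorted(profiles.items()):
        nodes = np.arange(1, prof.n_nodes + 1)
        ls = _TP_STYLE.get(tp, "-")
        ax.plot(nodes, prof.value_mean, ls, label=tp)
        band = 1.96 * np.nan_to_num(prof.value_se)
        ax.fill_between(nodes, prof.value_mean - band, prof.value_mean + band,
                        alpha=0.2, linewidth=0)
    ax.set_xlabel("node")
    ax.set_ylabel(next(iter(profiles.values())).metric)
    ax.set_title(title or next(iter(profiles.values())).bundle)
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_development_map(dev_map: pd.DataFrame, value: str = "slope",
                         ax=None) -> plt.Axes:
    """3D scatter of node positions (|x|, y, z) coloured by a map column."""
    if ax is None:
        fig = plt.figure(figsize=(5, 4))
        ax = fig.add_subplot(projection="3d")
    sc = ax.scatter(dev_map["x_abs"], dev_map["y"], dev_map["z"],
                    c=dev_map[value], s=8, cmap="inferno")
    ax.set_xlabel("|x| (mm)")
    ax.set_ylabel("y (mm)")
    ax.set_zlabel("z (mm)")
    plt.colorbar(sc, ax=ax, shrink=0.7, label=value)
    return ax


def plot_slope_vs_newborn(dev: pd.DataFrame, ax: plt.Axes | None = None,
                          newborn_col: str = "newborn_mean",
                          slope_col: str = "slope") -> plt.Axes:
    """Across-bundle scatter of development rate against newborn value."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    ax.errorbar(dev[newborn_col], dev[slope_col],
                yerr=dev.get("slope_se"), fmt="o", ms=4, capsize=2)
    ax.set_xlabel("newborn value")
    ax.set_ylabel("development rate (/day)")
    return ax
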