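"""Plot helpers: calibration, decision curves, impact feature maps."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_calibration", "plot_decision_curve", "plot_feature_map"]


def plot_calibration(table, ax=None, label=None):
    """Reliability diagram from a calibration bin table."""
    if ax is None:
        _, ax = plt.subplots()
    ax.plot([0, 1], [0, 1], "k--", lw=0.8, label="ideal")
    ax.plot(table["bin_mean_pred"], table["bin_mean_obs"], "o-", label=label)
    ax.set_xlabel("mean predicted probability")
    ax.set_ylabel("observed outcome fraction")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    if label:
        ax.legend()
    return ax


def plot_decision_curve(table, ax=None, label="model"):
    """Net-benefit curves: model vs treat-all vs treat-none."""
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(table["threshold"], table["net_benefit"], label=label)
    ax.plot(table["threshold"], table["treat_all"], ":", label="treat all")
    ax.plot(table["threshold"], table["treat_none"], "k-", lw=0.8,
            label="treat none")
    ax.set_xlabel("threshold probability")
    ax.set_ylabel("net benefit")
    ax.legend()
    return ax


def plot_feature_map(values, high, ax=None):
    """Render an impact grid: red above 0.5, blue at or below, white background."""
    if ax is None:
        _, ax = plt.subplots()
    rgb = np.ones(values.shape + (3,))
    filled = ~np.isnan(values)
    inten = np.zeros_like(values)
    inten[filled] = np.abs(values[filled] - 0.5) * 2
    red = filled & high
    blue = filled & ~high
    rgb[red] = np.stack([np.ones(red.sum()), 1 - inten[red],
                         1 - inten[red]], axis=1)
    rgb[blue] = np.stack([1 - inten[blue], 1 - inten[blue],
                          np.ones(blue.sum())], axis=1)
    ax.imshow(rgb, interpolation="nearest")
    ax.set_xticks([])
    ax.set_yticks([])
    return ax
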