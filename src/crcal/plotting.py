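"""Presentation-only plotting helpers (calibration curve panels)."""

from __future__ import annotations

import numpy as np


def plot_calibration(result, ax=None, show_density: bool = True, label=None):
    """Plot a calibration curve with the diagonal and a prediction density.

    ``result`` is a :class:`~crcal.calibration.CalibrationResult`.  Returns
    the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    ax.plot(result.curve_predicted, result.curve_observed, label=label or "calibration")
    lim = max(result.curve_predicted.max(), result.curve_observed.max()) * 1.05
    ax.plot([0, lim], [0, lim], ls="--", color="grey", lw=1, label="perfect")
    if show_density:
        from scipy.stats import gaussian_kde

        dens_ax = ax.twinx()
        pred = result.predicted
        if np.unique(pred).size > 1:
            kde = gaussian_kde(pred)
            xs = np.linspace(pred.min(), pred.max(), 200)
            dens_ax.fill_between(xs, kde(xs), alpha=0.15, color="tab:orange")
        dens_ax.set_yticks([])
        dens_ax.set_ylabel("density of predicted risk")
    ax.set_xlabel(f"predicted risk at t0={result.horizon_t0:g}")
    ax.set_ylabel("observed (smoothed) risk")
    ax.legend(loc="upper left")
    return ax


def plot_mean_curve(curve_frame, ax=None, label=None):
    """Plot an aggregated study curve (mean with percentile band)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    g = curve_frame
    (line,) = ax.plot(g["predicted"], g["mean"], label=label or "mean curve")
    ax.fill_between(g["predicted"], g["lo"], g["hi"], alpha=0.2, color=line.get_color())
    lim = float(np.nanmax([g["predicted"].max(), g["hi"].max()])) * 1.05
    ax.plot([0, lim], [0, lim], ls="--", color="grey", lw=1)
    ax.set_xlabel("predicted risk")
    ax.set_ylabel("observed (smoothed) risk")
    ax.legend(loc="upper left")
    return ax
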