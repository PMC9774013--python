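"""Presentation plots: trend overlays, forecasts, MAE-vs-horizon curves and
per-origin absolute-error matrices.  PNG/SVG output only; nothing here is
consumed programmatically."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

__all__ = [
    "plot_series_with_trend",
    "plot_forecast",
    "plot_mae",
    "plot_error_matrix",
]

#: family colour convention used throughout: Clayton green, Frank blue,
#: Gumbel red.
FAMILY_COLORS = {"clayton": "tab:green", "frank": "tab:blue", "gumbel": "tab:red"}


def _save(fig, path):
    fig.tight_layout()
    fig.savefig(path, dpi=130)
    plt.close(fig)


def plot_series_with_trend(series_values, trend_values, path, title="HR and SSA trend"):
    fig, ax = plt.subplots(figsize=(9, 3.5))
    ax.plot(series_values, color="black", lw=0.6, label="HR (bpm)")
    n = len(series_values)
    ax.plot(
        np.arange(n - len(trend_values), n), trend_values,
        color="tab:blue", lw=1.2, label="SSA reconstruction",
    )
    ax.set_xlabel("epoch (s)")
    ax.set_ylabel("bpm")
    ax.set_title(title)
    ax.legend(loc="best", fontsize=8)
    _save(fig, path)


def plot_forecast(history_tail, forecast_values, path, actual=None):
    fig, ax = plt.subplots(figsize=(7, 3.5))
    n = len(history_tail)
    ax.plot(np.arange(-n, 0), history_tail, color="black", lw=0.8, label="observed")
    h = len(forecast_values)
    ax.plot(np.arange(1, h + 1), forecast_values, color="tab:orange", lw=1.4, label="forecast")
    if actual is not None:
        ax.plot(np.arange(1, len(actual) + 1), actual, color="gray", lw=0.8, ls="--", label="actual")
    ax.axvline(0, color="gray", lw=0.6)
    ax.set_xlabel("epochs from origin")
    ax.set_ylabel("bpm")
    ax.legend(loc="best", fontsize=8)
    _save(fig, path)


def plot_mae(tables, path, title="Mean absolute error per forecast step"):
    """Plot one or several HorizonErrorTable curves.

    ``tables`` is either a single table or a mapping label -> table; labels
    matching a copula family name pick up the family colour convention.
    """
    if not isinstance(tables, dict):
        tables = {"hybrid": tables}
    fig, ax = plt.subplots(figsize=(6.5, 4))
    for label, tab in tables.items():
        color = FAMILY_COLORS.get(str(label).lower())
        ax.plot(tab.steps, tab.mae, marker="o", ms=3, label=str(label), color=color)
    ax.set_xlabel("prediction step (epochs ahead)")
    ax.set_ylabel("MAE (bpm)")
    ax.set_title(title)
    ax.legend(loc="best", fontsize=8)
    _save(fig, path)


def plot_error_matrix(abs_errors, path, title="Absolute prediction error (bpm)"):
    fig, ax = plt.subplots(figsize=(7, 4))
    im = ax.imshow(
        np.asarray(abs_errors).T, aspect="auto", origin="lower",
        interpolation="nearest", cmap="viridis",
    )
    ax.set_xlabel("prediction origin")
    ax.set_ylabel("step ahead")
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label="|error| (bpm)")
    _save(fig, path)
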