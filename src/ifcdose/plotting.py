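"""Minimal figures: dose-response fits with 95% bands, per-bin RMSE bars,
and the triage confusion matrix."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_dose_response", "plot_rmse_bars", "plot_confusion"]


def _ax(ax):
    if ax is None:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_dose_response(doses, y, fit, ax=None, ylabel="endpoint"):
    """Scatter of sample endpoints vs dose with the fitted curve and its 95%
    confidence band (works for linear and saturating fits)."""
    ax = _ax(ax)
    grid = np.linspace(0, float(np.max(doses)), 200)
    lo, hi = fit.confidence_band(grid)
    ax.plot(doses, y, "o", ms=4, alpha=0.6)
    ax.plot(grid, fit.predict(grid), "k-")
    ax.plot(grid, lo, "k:", lw=1)
    ax.plot(grid, hi, "k:", lw=1)
    ax.set_xlabel("dose (Gy)")
    ax.set_ylabel(ylabel)
    return ax


def plot_rmse_bars(tables: dict, ax=None):
    """Grouped per-dose-bin RMSE bars, one group per estimation method."""
    ax = _ax(ax)
    width = 0.8 / max(1, len(tables))
    for j, (name, tbl) in enumerate(tables.items()):
        x = np.arange(len(tbl)) + j * width
        ax.bar(x, tbl["rmse"], width=width, label=name)
        ax.set_xticks(np.arange(len(tbl)) + 0.4 - width / 2)
        ax.set_xticklabels([f"{lo:g}-{hi:g}" for lo, hi in zip(tbl["bin_low"], tbl["bin_high"])])
    ax.set_xlabel("true dose bin (Gy)")
    ax.set_ylabel("RMSE (Gy)")
    ax.legend()
    return ax


def plot_confusion(report, ax=None):
    """2x2 triage confusion matrix (rows: true negative/positive)."""
    ax = _ax(ax)
    mat = np.array([[report.tn, report.fp], [report.fn, report.tp]])
    ax.imshow(mat, cmap="Blues")
    for (i, j), v in np.ndenumerate(mat):
        ax.text(j, i, str(v), ha="center", va="center")
    ax.set_xticks([0, 1], ["pred neg", "pred pos"])
    ax.set_yticks([0, 1], ["true neg", "true pos"])
    ax.set_title(f"triage at {report.threshold_gy:g} Gy (accuracy {report.accuracy:.0%})")
    return ax
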