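"""Matplotlib views of error summaries and coverage curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["plot_error_summary", "plot_rmse", "plot_coverage"]


def _ax(ax):
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    return ax


def plot_error_summary(summary, ax=None):
    """Dosewise bias with a ±sigma ribbon."""
    ax = _ax(ax)
    d = summary.grid.doses
    ax.axhline(0.0, color="0.7", lw=0.8)
    ax.fill_between(d, summary.mu - summary.sigma, summary.mu + summary.sigma,
                    alpha=0.3, label=r"$\mu \pm \sigma$")
    ax.plot(d, summary.mu, lw=1.5, label=r"bias $\mu$")
    ax.set_xlabel("Dose (% Rx)")
    ax.set_ylabel("Prediction error (% OAR volume)")
    ax.legend(frameon=False)
    return ax


def plot_rmse(summary, ax=None):
    """RMSE_pred alongside its bias and variation components."""
    import numpy as np
    ax = _ax(ax)
    d = summary.grid.doses
    ax.plot(d, summary.rmse, lw=1.8, label=r"RMSE$_{pred}$")
    ax.plot(d, np.abs(summary.mu), lw=1.0, ls="--", label=r"$|\mu|$")
    ax.plot(d, summary.sigma, lw=1.0, ls=":", label=r"$\sigma$")
    ax.set_xlabel("Dose (% Rx)")
    ax.set_ylabel("% OAR volume")
    ax.legend(frameon=False)
    return ax


def plot_coverage(curves: dict, ax=None, show_references: bool = True):
    """Smoothed prediction-success curves per band kind.

    Reference lines mark the Gaussian expectations: 68.27% for a ±sigma-like
    band and 50% for an interquartile band.
    """
    ax = _ax(ax)
    for kind, curve in curves.items():
        ax.plot(curve.grid.doses, 100.0 * curve.smoothed, lw=1.5, label=kind)
    if show_references:
        ax.axhline(68.27, color="0.6", ls="--", lw=0.8)
        ax.axhline(50.0, color="0.6", ls=":", lw=0.8)
    ax.set_ylim(0, 102)
    ax.set_xlabel("Dose (% Rx)")
    ax.set_ylabel("Prediction success (% of plans)")
    ax.legend(frameon=False)
    return ax
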