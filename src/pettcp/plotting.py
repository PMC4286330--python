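"""Figures: LL heatmap, calibration histogram with sigmoid overlay, scatter."""

from __future__ import annotations

import numpy as np


def _get_ax(ax):
    if ax is not None:
        return ax
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_ll_surface(surface, results=None, ax=None, ci_level: float = 0.90):
    """Heatmap of LL(suvr50, gamma50); optionally the MLE and the CI contour."""
    ax = _get_ax(ax)
    im = ax.imshow(
        surface.ll.T,
        origin="lower",
        aspect="auto",
        extent=(surface.suvr50[0], surface.suvr50[-1], surface.gamma50[0], surface.gamma50[-1]),
        cmap="viridis",
    )
    ax.figure.colorbar(im, ax=ax, label="log-likelihood")
    if results is not None:
        from .model import delta_loglik

        ax.contour(
            surface.suvr50,
            surface.gamma50,
            surface.ll.T,
            levels=[results.max_ll - delta_loglik(ci_level)],
            colors="white",
            linewidths=1.0,
        )
        ax.plot(results.params.suvr50, results.params.gamma50, "r+", markersize=10)
    ax.set_xlabel(r"SUV$_{R50}$")
    ax.set_ylabel(r"$\gamma_{50}$")
    ax.set_title("Log-likelihood surface")
    return ax


def plot_calibration(bins, results, ax=None):
    """Binned observed recurrence fractions with Wilson bars and the model curve."""
    ax = _get_ax(ax)
    plotted = bins[bins["n"] > 0]
    yerr = np.vstack(
        [
            plotted["observed_trp"] - plotted["ci_lo"],
            plotted["ci_hi"] - plotted["observed_trp"],
        ]
    )
    ax.errorbar(
        plotted["midpoint"],
        plotted["observed_trp"],
        yerr=np.clip(yerr, 0, None),
        fmt="s",
        color="k",
        capsize=4,
        label="observed (Wilson 95%)",
    )
    hi = max(1.0, float(plotted["midpoint"].max()) + 0.2)
    xs = np.linspace(0.0, hi, 300)
    ax.plot(xs, results.predict_trp(xs), "b-", label="model TRP")
    ax.set_xlabel(r"$\langle \mathrm{SUV}_R \rangle$")
    ax.set_ylabel("tumor recurrence probability")
    ax.set_ylim(-0.05, 1.05)
    ax.legend()
    return ax


def plot_pre_vs_diff(table, ax=None):
    """Scatter of mean pre-treatment SUV vs mean SUV decrease, by outcome."""
    ax = _get_ax(ax)
    for r_val, label, marker in ((0, "responders", "o"), (1, "nonresponders", "^")):
        sub = table[table["R"] == r_val]
        ax.scatter(sub["mean_pre"], sub["mean_diff"], marker=marker, label=label, alpha=0.7)
    ax.set_xlabel(r"$\langle \mathrm{SUV}_{before} \rangle$")
    ax.set_ylabel(r"$\langle \mathrm{SUV}_{before} \rangle - \langle \mathrm{SUV}_{after} \rangle$")
    ax.legend()
    return ax
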