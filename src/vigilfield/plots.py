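"""Figure helpers: scatter-with-slope panels and binned lapse curves."""
from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .analysis import AssociationResult, LapseModelResult  # noqa: E402

__all__ = ["plot_association", "plot_lapse_curves"]


def plot_association(result: AssociationResult, table, out_path=None):
    """Panel grid: error vs each biomarker (and composite) with GM slope."""
    names = [a.name for a in result.per_biomarker] + ["composite"]
    ncol = 4
    nrow = int(np.ceil(len(names) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 3.2 * nrow), squeeze=False)
    y = table["error_db"].to_numpy(dtype=float)
    from .biomarkers import composite_scores

    for ax, name in zip(axes.ravel(), names):
        assoc = result.composite if name == "composite" else result[name]
        if name == "composite":
            x = composite_scores(result.composite_model, table).to_numpy()
        else:
            x = table[name].to_numpy(dtype=float)
        ax.scatter(x, y, s=18, alpha=0.7)
        xs = np.linspace(np.nanmin(x), np.nanmax(x), 50)
        ax.plot(xs, assoc.intercept + assoc.slope * xs, "k-", lw=1.5)
        ax.set_title(f"{name}\nr={assoc.r:.2f}, p={assoc.p:.3g}", fontsize=9)
        ax.set_ylabel("|ΔMS| (dB)")
    for ax in axes.ravel()[len(names):]:
        ax.set_visible(False)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=120)
        plt.close(fig)
    return fig


def plot_lapse_curves(results: dict[str, LapseModelResult], out_path=None):
    """Binned hit rate (with Wilson CIs) and logistic curve per biomarker."""
    names = list(results)
    ncol = 3
    nrow = int(np.ceil(len(names) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 3.2 * nrow), squeeze=False)
    for ax, name in zip(axes.ravel(), names):
        res = results[name]
        bins = res.bins
        centers = np.sqrt(bins["edge_lo"] * bins["edge_hi"])
        yerr = np.clip(
            [bins["hit_rate"] - bins["ci_lo"], bins["ci_hi"] - bins["hit_rate"]], 0, None
        )
        ax.errorbar(centers, bins["hit_rate"], yerr=yerr, fmt="o", capsize=3)
        if res.slope is not None:
            xs = np.geomspace(bins["edge_lo"].iloc[0], bins["edge_hi"].iloc[-1], 100)
            p = 1.0 / (1.0 + np.exp(-(res.intercept + res.slope * xs)))
            ax.plot(xs, p, "k-", lw=1.5)
            ax.set_title(f"{name}\np={res.p_value:.2g}", fontsize=9)
        else:
            ax.set_title(f"{name}\n(separation)", fontsize=9)
        ax.set_xscale("log")
        ax.set_ylim(0, 1.05)
        ax.set_ylabel("P(hit)")
    for ax in axes.ravel()[len(names):]:
        ax.set_visible(False)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=120)
        plt.close(fig)
    return fig
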