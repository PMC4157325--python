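"""Figure export: density curves with jackknife envelopes, and choice
surfaces with the P = 0.25 threshold contour."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .conditional_probability import DensityCurve, tasp_on_bins

__all__ = ["plot_density_curves", "plot_choice_surface"]


def plot_density_curves(curve: DensityCurve, path=None, title: str = "") -> plt.Figure:
    """Observed leave/arrive probabilities versus feeder density.

    Layout: observed points with per-bin sample sizes, the jackknife
    envelope band when present, the TASP line, and dashed reference lines
    at the random-choice level (0.25).
    """
    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharex=True)
    mid = curve.bin_mid
    tasp = tasp_on_bins(curve.bin_edges)
    for ax, which, tasp_y in ((axes[0], "leave", tasp.p_leave),
                              (axes[1], "arrive", tasp.p_arrive)):
        y = getattr(curve, f"p_{which}")
        n = getattr(curve, f"n_{which}")
        if curve.envelope:
            lo = curve.envelope[f"{which}_low"]
            hi = curve.envelope[f"{which}_high"]
            ax.fill_between(mid, lo, hi, color="0.8", label="jackknife envelope")
        ax.plot(mid, tasp_y, "k-", label="TASP")
        ax.axhline(0.25, ls="--", color="0.5", lw=0.8)
        ax.axvline(0.25, ls="--", color="0.5", lw=0.8)
        ax.plot(mid, y, "o", color="C0", label="observed")
        for x, yy, nn in zip(mid, y, n):
            if np.isfinite(yy) and nn > 0:
                ax.annotate(str(int(nn)), (x, 1.02), ha="center", fontsize=6,
                            annotation_clip=False)
        ax.set_xlabel(r"density $\rho$")
        ax.set_ylabel(f"P({which} | " + r"$\rho$)")
        ax.set_xlim(-0.05, 1.05)
        ax.set_ylim(-0.02, 1.02)
    axes[0].legend(fontsize=7)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_choice_surface(surface: dict, path=None, title: str = "") -> plt.Figure:
    """Probability of choosing a feeder over (conspecifics, heterospecifics)
    at that feeder, with the P = 0.25 contour marked in black."""
    fig, ax = plt.subplots(figsize=(5, 4))
    mesh = ax.pcolormesh(surface["h_axis"], surface["c_axis"], surface["surface"],
                         shading="nearest", cmap="viridis")
    fig.colorbar(mesh, ax=ax, label="P(choose x)")
    for seg in surface["contour"]:
        ax.plot(seg[:, 0], seg[:, 1], "k-", lw=1.5)
    ax.set_xlabel("heterospecifics at x")
    ax.set_ylabel("conspecifics at x")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
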